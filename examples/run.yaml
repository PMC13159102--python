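# Desk-scale two-phase run: 25 s of motor-driven bundling, then condensate
# complexes are added and followed to 100 s.  All lengths in µm, times in s.
arena_radius: 6.5
dt: 0.01
t_bundle: 25.0
t_total: 100.0
snapshot_interval: 25.0

n_filaments: 18
filament_length: 5.0
filament_segment_length: 2.5

n_hset: 60
hset_unbinding_rate: 0.1
hset_binding_range: 0.1
hset_link_stiffness: 40.0

n_complexes: 18
complex_adhesive_range: 0.1
complex_adhesive_stiffness: 20.0

seed: 0
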