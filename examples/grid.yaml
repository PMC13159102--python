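# Sweep axes (cartesian product).  Cell seeds are base seed + cell index.
hset_unbinding_rate: [0.02, 0.0632, 0.2, 0.632, 2.0]
n_hset: [15, 60]
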