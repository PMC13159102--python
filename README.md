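# centroclust

Agent-based simulation of minus-end-directed, motor-driven clustering of
condensate complexes on microtubule networks, together with the
quantification pipelines used around such experiments: FRAP recovery
fitting, kymograph/track motility analysis, and condensate image
quantification. Everything runs on synthetic data generated by the package
itself — no external data are required.

## Components

| Module | Purpose |
| --- | --- |
| `centroclust.sim` | 2-D overdamped Brownian-dynamics simulator: semiflexible filaments, bivalent minus-end-directed motor couplers, condensate complexes with motor / adhesive / lattice hands; two-phase protocol (bundling, then complex addition) and parameter sweeps |
| `centroclust.clustering` | Pairwise-distance clustering statistic (percentage of complexes with a neighbor < threshold), fold change between the post-addition and final snapshots, sweep heatmaps |
| `centroclust.motility` | Track segmentation into processive / diffusive / static events, event velocities and run distances, event-rate normalization (events per µm per min), track summaries |
| `centroclust.frap` | Double normalization (background + unbleached reference) and single-exponential recovery fitting: rate, half-time, mobile/immobile fractions |
| `centroclust.droplets` | Droplet detection (threshold + 8-connected components), size/density statistics, partition coefficient, phase-diagram classification |
| `centroclust.synth` | Seeded generators for every fixture: FRAP traces, particle tracks, droplet images, point sets — each with a ground-truth table |

## CLI

```bash
# one simulation run
centroclust run --config examples/run.yaml --seed 1 --out out/run1

# parameter sweep (cartesian product of the grid axes)
centroclust sweep --config examples/run.yaml --grid examples/grid.yaml --out out/sweep

# clustering statistics and heatmap over a sweep directory
centroclust analyze cluster --in out/sweep --threshold 1.0

# track, FRAP and droplet-image analyses (CSV/TIFF inputs)
centroclust analyze motility --tracks tracks.csv --noise-floor 0.1
centroclust analyze frap --traces frap_traces.csv
centroclust analyze droplets --images imgs/ --pixel-size 0.1

# synthetic fixtures with ground truth
centroclust make-fixtures --kind tracks --spec spec.json --out fixtures/
```

Simulation configs are YAML/JSON mappings of `SimConfig` fields (unknown
keys are rejected); see `examples/run.yaml`. All parameter defaults are
documented stand-ins (`src/centroclust/sim/config.py`) and every run echoes
its full configuration into the output directory.

## Conventions and units

Lengths µm, times s, forces pN, stiffness pN/µm, viscosity pN·s/µm².
Filament vertex 0 is the minus end; motor heads walk toward abscissa 0.
Track positions are measured from the minus end, so reported velocities are
positive toward it. All randomness flows from explicit seeds; identical
(config, seed) pairs reproduce bit-identical records.
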