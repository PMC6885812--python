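# neurocult

Analysis pipeline for neuron-glial culture assays:

- **Calcium-imaging event detection** — the derivative-threshold rule: each
  per-cell fluorescence trace (relative units, 0–255, 4 Hz) is smoothed by
  pairwise averaging, differentiated by pairwise differences, and
  oscillations are called where the derivative exceeds
  `k × SD(derivative)` (detection accuracy coefficient `k = 0.45`).
  Positive excursions open events, negative excursions close them.
- **Trace extraction and viability counting** — ROI label images over
  multi-page TIFF stacks; per-cell traces are ROI pixel means per frame;
  viability is the ratio of dead-stain to total-stain nucleus counts
  (8-connected components with an area filter).
- **Network activity metrics** — percentage of working cells, oscillation
  frequency (per min), mean oscillation duration, raster diagrams, and a
  binned synchrony caller.
- **Mitochondrial respirometry** — V4 (glutamate/malate), V3 (ADP), V4
  (succinate) state summaries, the respiratory control index V3/V4
  (per-replicate ratio, then averaged), percent-change and fold-decrease
  reporting.
- **ddCt gene expression** — reference-gene normalization, calibrator-group
  ΔΔCt, fold change `2^(−ΔΔCt)` with SEM.
- **Group statistics** — mean ± SEM, one-way ANOVA, Dunnett many-to-one
  post hoc comparisons (Monte-Carlo max-|t| null, exact pooled *t* for a
  single comparison), percent-of-control ratios, and an empirical type-I
  error harness.
- **Synthetic data** — seeded generators for per-cell traces (Poisson
  transients + jittered network events, difference-of-exponentials
  kinetics), rendered image stacks, respirometry replicate tables, and Ct
  tables, all with ground truth, so the whole pipeline is testable without
  any recordings.

## CLI

Everything is reachable through the `neurocult` entry point:

```sh
# synthetic data (config files are JSON)
neurocult simulate traces --config sim.json --seed 1 --out sim/
neurocult simulate stack --config sim.json --rois rois.tif --out sim/
neurocult simulate respirometry --config resp.json --out data/
neurocult simulate ct --config ct.json --out data/

# imaging
neurocult extract --stack stack.tif --rois rois.tif --rate 4 --out traces.csv
neurocult viability --dead pi.tif --total bb.tif --out viability.csv

# calcium activity
neurocult detect --traces traces.csv --k 0.45 --out events.csv
neurocult metrics --events events.csv --n-cells 50 --length 300 --out summary.csv
neurocult raster --events events.csv --length 300 --out raster.csv --png raster.png
neurocult sync --events events.csv --length 300 --bin 1.0 --threshold 0.3

# respirometry, expression, statistics
neurocult respire --table states.csv --reference-group Sham
neurocult ddct --table ct.csv --reference-gene Oaz1 --calibrator Sham
neurocult stats --table values.csv --control Sham --alpha 0.05
```

Trace CSVs have a `time_s` column plus one `cell_<id>` column per cell;
event CSVs carry `cell_id, onset_frame, offset_frame, onset_s, offset_s,
duration_s`; Ct tables carry `sample, group, gene, Ct`; respirometry
tables carry `group, replicate, V4_gm, V3, V4_succ`.

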