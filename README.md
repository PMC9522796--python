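# tgcalcium

Analysis of spontaneous calcium activity in intact neonatal sensory
ganglia, built around 1 Hz GCaMP6s time-lapse recordings of the
trigeminal ganglion imaged ex vivo.

During the first postnatal week, sensory neurons fire spontaneously
without any stimulus. In an ex vivo ganglion preparation this shows up
as sparse calcium transients in a minority of somata (roughly 12% per
5-min imaging block), with a small subset of neuron pairs firing
together far more often than chance — and those correlated pairs sit
close to each other in the tissue. Because medium- and large-diameter
somata are strongly over-represented among the firing neurons, this
activity points at the mechanosensory lineage. `tgcalcium` implements
the full quantitative chain behind those observations:

1. **Synthetic sessions with ground truth** (`tgcalcium.synthetic`) — a
   generator that renders movies with the same statistical structure as
   the recordings: a mosaic of circular somata drawn from a
   small/medium/large diameter mixture, Poisson-timed transients with
   GCaMP6s kinetics in a configurable fraction of neurons, planted
   spatially proximal correlated pairs, monoexponential photobleaching,
   Gaussian read noise, optional rigid jitter, and an optional terminal
   high-potassium (depolarization) epoch. Every movie comes with a
   complete `GroundTruth`, so every stage of the analysis can be scored
   against known answers.
2. **Preprocessing** (`tgcalcium.preprocess`) — bleach correction by a
   global exponential fit, rigid motion correction by phase
   correlation, and frame quality control that flags (never deletes)
   bad frames.
3. **ROI detection and nuclei counting** (`tgcalcium.roi`) — watershed
   segmentation of firing somata from a per-pixel activity projection,
   trace extraction, activity-based refinement, and rolling-ball +
   watershed counting of nuclei in still images.
4. **ΔF/F₀ and transient detection** (`tgcalcium.events`) — a sliding
   60-frame baseline, the mean + SD firing threshold (10 × SEM for the
   high-K viability rule), and peak detection with rise/fall criteria
   (20% rise within 30 frames, 15% fall within 25 frames, relative to a
   two-sided exponential-moving-average trendline). Amplitudes are read
   from the raw ΔF/F₀ at the peak.
5. **Correlation analysis** (`tgcalcium.correlation`) — Pearson
   correlation of thresholded signals for every ROI pair, the r > 0.5
   correlated-pair rule, centroid distances, and a two-tailed
   Mann–Whitney U comparison (exact enumeration for small groups) of
   correlated vs non-correlated pair distances.
6. **Population summaries** (`tgcalcium.population`) — soma-size
   classes (SD < 20 µm, MD 20–25 µm, LD > 25 µm), percent-active,
   subtype composition, the subtype active-fraction estimator, and
   group statistics (ANOVA + Tukey, Kruskal–Wallis, Mann–Whitney,
   paired t).
7. **Pipeline + CLI** (`tgcalcium.pipeline`, `tgcalcium` command) — a
   single-config driver whose CSV/JSON outputs are byte-identical on
   rerun and carry the config hash + seed in a header comment.

## Worked example

Simulate a half-size field (330 × 330 µm, 80 neurons, 15% active, 3
planted correlated pairs, 10 min at 1 Hz) and run the full pipeline:

```python
from tgcalcium import run_pipeline

config = {
    "seed": 1,
    "simulate": {"pixels_per_side": 165, "field_size_um": 330.0,
                 "n_neurons": 80, "n_frames": 600, "frac_active": 0.15,
                 "n_correlated_pairs": 3},
    "write_ground_truth": True,
}
summary = run_pipeline(config, "results")
print("ROIs kept:          ", summary["stages"]["roi"]["n_rois"])
print("events detected:    ", summary["stages"]["events"]["n_events"])
print("active per block:   ", summary["stages"]["events"]["active_per_block"])
print("percent active:     ", summary["pct_active"])
print("correlated pairs %: ", summary["fraction_correlated_pct"])
dc = summary["distance_comparison"]
print("median distance (um), correlated vs not: "
      f"{dc['median_correlated_um']:.0f} vs {dc['median_non_correlated_um']:.0f} "
      f"(Mann-Whitney p = {dc['p_value']:.2g})")
```

Output (exactly reproducible; the run takes a few seconds):

```
ROIs kept:           12
events detected:     77
active per block:    [11, 12]
percent active:      14.375
correlated pairs %:  3.0303
median distance (um), correlated vs not: 81 vs 142 (Mann-Whitney p = 0.21)
```

All 12 planted firing neurons are recovered (the generator drew 12
active of 80; 14.4% estimated vs 15% configured), the planted pairs
drive the correlated fraction, and the correlated pairs are the closer
ones — at this small scale the distance comparison is directionally
right but not significant; the full-size session (300 neurons, 10
pairs) reaches p ≈ 1e-5 (see `tests/test_acceptance.py`).

`results/` now contains `rois.csv`, `traces.csv`, `events.csv`,
`raster.csv`, `pairs.csv`, `matrix.csv`, `subtype_composition.csv`,
`summary.json`, and `ground_truth/` — each CSV starts with a
`# config_sha256=... seed=...` comment, and a rerun with the same
config is byte-identical.

The same chain is available from the shell:

```bash
tgcalcium simulate --seed 1 --out session --n-neurons 80 --pixels 165
tgcalcium detect-rois session/movie.tif --out rois.csv
tgcalcium extract-traces session/movie.tif --rois rois.csv --out traces.csv
tgcalcium detect-events traces.csv --out events.csv
tgcalcium config init --out config.yaml && tgcalcium run config.yaml --out results
```

The subtype active-fraction estimator works directly on printed
percentages — with 12.3% of all neurons firing and the small-diameter
class making up 17.1% of firing vs 67.3% of all neurons:

```python
>>> from tgcalcium import estimate_subtype_activity
>>> round(estimate_subtype_activity(12.3, 17.1, 67.3))   # small-diameter
3
>>> round(estimate_subtype_activity(12.3, 39.5, 27.3))   # medium-diameter
18
```

## Methods

See `docs/methods.md` for the analysis conventions (baselines,
thresholds, peak criteria, size classes, statistics) and the design
decisions behind the synthetic generator and the ROI detector.
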