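# Methods

Conventions and design decisions behind `tgcalcium`. All defaults below
are the library defaults; every one is overridable through the function
arguments or the pipeline config.

## Imaging model and synthetic sessions

The target recording is a 1 Hz, 10-min (600-frame) epifluorescence
time-lapse of a flattened neonatal sensory ganglion expressing GCaMP6s,
covering a 660 × 660 µm field at 2 µm/px (330 × 330 px). The synthetic
generator (`tgcalcium.synthetic.SimConfig`, `simulate_movie`) renders
movies with that geometry and returns a complete `GroundTruth` so every
analysis stage can be scored:

- **Somata.** 300 non-overlapping circular somata per field. Diameters
  are drawn from a three-class mixture — small (SD, < 20 µm), medium
  (MD, 20–25 µm), large (LD, > 25 µm) — with class weights matching the
  measured composition of a fully depolarized (high-K⁺) locus, uniform
  within each class interval. Sampling class first makes the realized
  class shares converge to the weights exactly.
- **Activity.** A configurable fraction of neurons (default 12%) is
  active; each active neuron receives Poisson-timed transients at
  0.4 events/min. A transient is the difference-of-exponentials kernel
  `transient_kernel` (rise τ = 0.2 s, decay τ = 2.0 s, normalized to
  unit continuous peak) scaled to 0.8 ΔF/F. Note that at 1 Hz the
  sampled maximum of this kernel is 0.843 × the continuous peak,
  because the true peak time (≈ 0.48 s after onset) falls between
  frames; tests that plant kernels compare against the *sampled*
  maximum, not the nominal amplitude.
- **Correlated pairs.** 10 neuron pairs are planted with near-identical
  onset times (±1 frame jitter) at centroid distances confined to
  40–150 µm, reproducing the spatial-proximity structure of correlated
  loci.
- **Nuisance.** Monoexponential photobleaching (τ = 600 s), Gaussian
  read noise (SD 16 on a soma baseline of 100 over background 100,
  i.e. SNR 5), optional rigid frame jitter, and an optional terminal
  high-K⁺ epoch that raises every soma (the viability control).
  The background level of 100 keeps the noise floor away from zero;
  with a near-zero background, clipping at the detector floor skews
  the noise distribution and biases the bleach fit.
- `simulate_nuclei_image` renders still nuclear-label images with a
  known count, including deliberately touching pairs, for the
  nuclei-counting criterion.

## Preprocessing

- **Bleach correction** (`bleach_correct`): fit `a·exp(−t/τ) + c` to
  the frame-mean trace and divide each frame by the fitted curve
  normalized to its first value. Global (per-frame scalar) correction
  is appropriate because bleaching is dominated by illumination, not by
  per-cell indicator dynamics; it preserves relative transient
  amplitudes.
- **Motion correction** (`motion_correct`): rigid translation per frame
  by phase cross-correlation against the mean (or first) frame. The
  shift table reports the *frame's displacement*: a frame translated by
  (dy, dx) = (2, −1) is reported as (2, −1) and shifted back by the
  negative. Shifts above 25% of the frame size are implausible for this
  preparation and indicate a registration failure; such frames are
  flagged `kept = False` and left unshifted rather than "corrected"
  with garbage.
- **Quality control** (`drop_bad_frames`): frames whose mean intensity
  jumps > 50% relative to the previous frame, or whose registered shift
  exceeds 5 px, are *flagged*, never deleted — deleting frames would
  desynchronize frame indices from wall-clock time and from the block
  structure. Flagged frames are excluded from the ROI activity image
  and linearly interpolated in extracted traces. If more than 20% of
  frames are flagged the movie is rejected (`MovieQualityError`).

## ROI detection

`detect_rois` segments the somata of *firing* neurons (silent neurons
are invisible in a functional indicator and are not segmentable):

1. **Activity image.** Default statistic is `peak`: the temporal
   maximum of the boxcar-denoised (3 frames), per-pixel
   median-subtracted, spatially smoothed (σ = 3 µm) movie. This is a
   deliberate deviation from the classic standard-deviation projection:
   at 0.4 events/min many neurons fire once or twice in 10 min, and a
   single 0.8 ΔF/F transient barely moves a 600-frame standard
   deviation but towers over the denoised noise envelope in a maximum
   projection. On the reference synthetic session the `std` projection
   recovers 33% of active neurons with ~65 false positives; `peak`
   recovers 97% with 0 false positives. `stat="std"` remains available.
2. **Seeding and watershed.** Foreground = pixels above the 98th
   percentile of the activity image. Seeds are h-maxima with
   h = 4 × (1.4826 × MAD) of the image: a secondary maximum inside one
   soma must dip ~4 noise SDs to seed its own region, while distinct
   neurons are separated by deep background valleys and keep separate
   seeds. Watershed on the inverted activity image, masked to the
   foreground.
3. **Size filter.** Segments outside an equivalent diameter of
   8–45 µm (soma-diameter range plus segmentation slack) are dropped.
4. **Merge rule.** Adjacent segments whose raw traces correlate at
   r > 0.95 are over-segmentations of one soma and are merged
   (union-find). Genuinely correlated *distinct* neurons do not touch
   and correlate well below 0.95 on raw (noise-bearing) traces.
5. **Refinement** (`refine_rois`): an ROI is kept iff its ΔF/F₀ trace
   yields ≥ 1 detected transient. This is the principal false-positive
   control — noise blobs that survive segmentation do not produce
   transients passing the rise/fall criteria.

`extract_traces` averages raw intensity over each ROI mask; flagged
frames are linearly interpolated. `count_nuclei` (still images)
subtracts a rolling-ball background (radius 100 px), Otsu-thresholds,
and splits touching nuclei by distance-transform watershed.

## ΔF/F₀ and transient detection

- **Baseline.** F₀ is the sliding mean of the raw trace over a trailing
  60-frame (1-min) window; ΔF/F₀ = (F − F₀)/F₀. A trailing window
  tracks slow drifts without letting a transient inflate its own
  baseline ahead of time.
- **Firing threshold.** `mean_plus_sd` (default): mean + 1 SD of the
  ΔF/F₀ trace — the spontaneous-activity rule. `ten_sem`: 10 × SEM,
  used by `high_k_response` to score viability during the terminal
  depolarization epoch. A property of the mean + SD rule worth knowing:
  on a trace with zero or one transient the threshold sits ≈ 1 SD above
  zero, so roughly one spurious noise crossing per few hundred quiet
  frames that also happens to satisfy the rise/fall criteria is
  expected behavior of the *rule*, not a detector defect.
- **Peak detection** (`detect_peaks`). Candidate peaks are local maxima
  of the Savitzky–Golay-smoothed (window 7, order 3) ΔF/F₀ that exceed
  the firing threshold. Each candidate must, relative to a two-sided
  exponential-moving-average trendline (α = 0.05), have risen by ≥ 20%
  of its height within the preceding 30 frames and fall by ≥ 15% within
  the following 25 frames. Detection is scale-invariant.
- **Amplitude from the raw trace.** Event *detection* runs on the
  smoothed trace, but the amplitude is read from the **raw** ΔF/F₀:
  the peak frame is refined to the raw argmax within half a smoothing
  window and the amplitude is the raw height above the trendline there.
  Rationale: at 1 Hz a transient peak spans ~1 frame, and 7-point
  Savitzky–Golay smoothing attenuates a 1-frame peak by ~45% — reading
  amplitudes off the smoothed trace would systematically halve them.
  Event parameters are therefore measured on the raw data, with
  smoothing used only to stabilize detection. Two smoothed maxima that
  refine to the same raw frame are one event. A transient truncated by
  the end of the recording keeps its amplitude but reports
  `decay_time_s = None` rather than a fabricated decay.
- `build_raster` marks onset-to-end frames per ROI; `count_active`
  counts ROIs with ≥ 1 event per block and averages across blocks.

## Correlation analysis

- **Thresholded signals.** Before correlating, each ΔF/F₀ trace is
  zeroed strictly below its firing threshold (`thresholded_signal`), so
  correlations measure co-*firing* rather than shared noise or drift.
- `pairwise_correlation` computes Pearson r for every ROI pair;
  zero-variance (never-firing) traces are excluded by default.
  A pair is **correlated** iff r > 0.5 (strict).
- Centroid distances (`pair_distances`, `attach_distances`) feed
  `compare_distance_distributions`: median distance of correlated vs
  non-correlated pairs, compared by a two-tailed Mann–Whitney U test.
  `mann_whitney_u` enumerates the exact null when max(n, m) ≤ 8
  (≤ C(16, 8) = 12 870 arrangements) and uses the normal approximation
  with tie correction otherwise.
- `cluster_matrix` reorders the correlation matrix by hierarchical
  clustering for display.

## Population summaries

- `classify_soma`: SD < 20 µm ≤ MD ≤ 25 µm < LD.
- `percent_active(mean_active, n_total)` — percent of all neurons
  firing per block.
- `subtype_composition`: per-class share among all neurons and among
  firing neurons.
- `estimate_subtype_activity(overall_active_pct, share_active_pct,
  share_all_pct)` estimates the percent of a *class* that fires:
  `overall × (share among firing) / (share among all)`. With 12.3%
  overall activity this gives ≈ 3% for SD (17.1/67.3) and ≈ 18% for MD
  (39.5/27.3) — the two acceptance targets (`scripts/acceptance.py`).
- `compare_groups` dispatches ANOVA + Tukey HSD, Kruskal–Wallis,
  Mann–Whitney, or paired t; degenerate inputs are reported in the
  result, not raised. `significance_stars` maps p to ns/*/**/***.
- `before_after_summary` counts ROIs active before vs after a treatment
  boundary (the activity-blockade analysis).

## Determinism and provenance

A single integer seed determines the entire synthetic session. Pipeline
CSV outputs begin with a `# config_sha256=<hash> seed=<seed>` comment
and a rerun with the same config is byte-identical; `summary.json`
mirrors the returned summary. Unknown config keys are rejected
(`ConfigError`), and stage failures name the stage (`StageError`).

## Limitations

- No spike inference: events are calcium transients; at GCaMP6s decay
  times and 1 Hz sampling, bursts within ~2 s merge into one event.
- Motion correction is rigid-translation only; no non-rigid warping.
- The generator renders circular somata with uniform brightness; real
  somata are irregular and the segmenter's size filter carries slack
  for that.
- The mean + SD firing threshold is intentionally permissive on quiet
  traces (see above); population counts should be read per block, where
  a single spurious crossing changes a count by at most one.
- Distance comparisons need enough correlated pairs to power the
  Mann–Whitney test; small fields (few pairs) give directionally
  correct but non-significant medians.
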