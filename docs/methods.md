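# Methods

## The forecasting problem

A staged embryo movie is a sequence of 2D frames, each labelled with a
developmental stage (NC13, then NC14A–D) and belonging to one video (one
embryo) of one genotype. Within a frame, every segmented nucleus is either
transcriptionally active (a nascent-transcription focus above threshold) or
not. The quantity of interest is the per-grid-cell count of active nuclei at
stage *t*, predicted from spatial features measured at stage *t−1* of the
same embryo. Training pools all (video, stage-pair, cell) rows; the model is
a single gradient-boosted tree ensemble shared across stages, so stage
identity enters only through the features themselves (total activity and the
global moments shrink as the band narrows, which is what lets the model beat
a persistence forecast).

## Active-nucleus calling

"Prevalence of bright green pixels" is formalized as a two-threshold rule:

1. a per-pixel intensity cutoff on the green channel (default: Otsu's
   threshold computed on the frame; a constant channel yields a cutoff above
   its maximum, i.e. no green pixels),
2. a per-nucleus prevalence threshold (default 0.05) on the fraction of
   in-mask pixels above the cutoff.

Both are exposed because neither has a canonical value; the defaults are
deliberately permissive (a single bright focus occupies a small fraction of a
nucleus). Centroids are unweighted pixel centroids of the label mask, which
keeps the tabulation independent of the segmenter and of intensity
calibration. Lowering the prevalence threshold can only grow the active set
(monotonicity), which the tests rely on.

Segmentation is delegated: any integer label mask is accepted, whether from
the bundled renderer, a file, or an external deep-learning segmenter behind
`segment_adapter`. The adapter raises a capability error with instructions to
use precomputed masks when no segmenter is installed; it is never a hard
dependency.

## Feature set

Per grid cell of side *g* (half-open cells `[k·g, (k+1)·g)`; boundary points
belong to the higher-index cell; the last row/column may be partial):

- **n** — active-nucleus count; per frame these sum exactly to the frame's
  active count at every grid size (a conservation law used as a test).
- **Ripley's K** — `K(r) = A/(n(n−1)) Σᵢ Σ_{j≠i} 1(d_ij ≤ r)/e_ij` over
  ordered pairs, computed on the cell's own active points with the cell as
  the observation window (*A = g²*). The default radius is *r = g/2*, one
  constant radius per grid size. Pairs are found with a KD-tree; equivalence
  with the naive double loop is tested to 1e−9 relative tolerance. Edge
  correction defaults to none (*e_ij = 1*); the translation correction
  `e_ij = (W−|Δx|)(H−|Δy|)/(WH)` is available and is used for the CSR
  calibration, where `E[K(r)] = πr²` for uniform points. K is treated as
  local (per cell) rather than frame-global because it sits alongside *n* as
  a within-window statistic; a frame-global evaluation can be had by calling
  `ripley_k` on the whole frame with the image as the window.
- **m1, m2 per axis** — frame-global mean and *central* second moment
  (variance) of active positions along AP and DV. The central moment is used
  because spread, not raw scale, is what distinguishes a narrowing band from
  a drifting one. With zero active nuclei the moments are undefined and
  propagate as missing values with a warning.

Cells with fewer than two points have no defined K. They carry NaN through
stage averaging (NaNs are excluded from the mean; an all-NaN cell stays NaN)
and receive a sentinel of 0 plus a `ripley_defined` flag column when the
supervised dataset is assembled, so a learner can distinguish "no clustering"
from "not measurable". The flag is not among the default training features.

## Stage averaging and the one-stage shift

Because stages contain different numbers of frames, every feature (including
the count) is arithmetically averaged per (video, stage, cell); targets are
therefore real-valued stage-average counts and predictions are clipped at
zero but not rounded. Supervised pairs link adjacent stages present in a
video: X = stage *t−1* features, y = stage *t* count, per cell. Five stages
give four stage-pairs; a single-stage video contributes nothing (warned, not
an error).

## Model and validation

XGBoost regression with 300 trees, depth 4, learning rate 0.1, squared-error
objective, `tree_method="hist"`, one thread, fixed seed — modest defaults for
a six-feature tabular problem, fixed for reproducibility rather than tuned.
Held-out evaluation is at the video level (a movie is never split across
train and test); K-fold CV groups rows by video when at least K videos exist,
else by (video, stage-pair), else by rows. The ablation harness re-runs CV on
identical folds for each named feature subset ("m2" denotes both axis second
moments jointly).

Two reference baselines calibrate forecast skill: persistence (predict the
previous stage's count unchanged) and the training-set global mean.

## Metrics

- rmse and mae over all grid cells of the predicted vs actual count matrix.
- Marginal profiles: per-row (DV) or per-column (AP) *means* of the count
  matrix — average active nuclei per grid cell at that axis position — so
  profiles are comparable across grid sizes.
- KL divergence `Σ p ln(p/q)` in nats, direction actual ‖ predicted, computed
  on the DV marginal by default (the axis along which the expression band
  lives; a full-grid variant sits behind a flag). Both profiles are
  normalized, shifted by ε = 1e−9 and re-normalized; the smoothing keeps
  empty bins finite and the re-normalization makes the result invariant to
  rescaling either profile.
- ap_mae / dv_mae between marginal profiles and mean_mae = their arithmetic
  mean, the quantities used for genotype comparison.

## Group comparison

Metric records are one value per (video, stage, metric). The bootstrap
resamples records with replacement within each genotype (group sizes
preserved, 10 000 replicates by default) and reports the percentile CI of the
mean difference, mutant − wild-type; the point estimate is the plain group
mean difference. The resampling unit is the (video, stage) record: it
preserves the two-sample structure without assuming independence model
beyond what the records themselves carry. The percentile method is used
rather than BCa — simplest, and adequate at the B used.

The mixed-effects model is `value ~ group` with random intercepts for video
and for stage, expressed as crossed variance components in statsmodels
MixedLM (REML). Random intercepts only: the smallest structure that absorbs
between-embryo and between-stage variation. Non-convergence is reported as a
status flag, never as a silent NaN.

## Synthetic movies

The generator emulates the statistical structure the analysis assumes, not
microscopy appearance. Nuclei are placed by minimum-spacing dart throwing
(spacing 1.5 × radius, hash-grid accelerated) so rendered frames remain
segmentable, then jittered with Gaussian noise (s.d. 2 px). Activity is
Bernoulli per nucleus with probability
`bg + (peak − bg)·exp(−(y − cH)²/(2(σH)²))` — Gaussian in DV, flat in AP.
Defaults describe the study conditions: 2000 × 2000 px frames, 500 nuclei of
radius 18 px (diameter ≈ 36 px, matching the observed cell size), five
stages, ten frames per stage, band centre drifting 0.62 → 0.55 of image
height and σ narrowing 0.16 → 0.08 across stages (late-stage narrowing of
the wild-type domain), peak activity 0.9 over background 0.02. The mutant
variant multiplies every stage's σ by a widening factor (default 1.75),
emulating the expanded domain when the repressor sites are removed. Nucleus
counts and frames per stage are free parameters with no measured
counterpart; the defaults are chosen to give realistic nuclear density at
this magnification.

Rendering draws nuclear discs in the red channel, a bright focus (radius
r/3) inside active nuclei in the green channel, and a label mask in draw
order; the detection round trip (render → extract → same active set) is an
exact oracle for both modules.

What the generator does **not** emulate — and hence what passing tests do
not establish about real movies: nuclear divisions and movement between
frames, intensity noise and photobleaching, segmentation errors, anisotropic
or curved expression domains, and burst kinetics within a stage. Results on
synthetic data validate the machinery, not the biology.

Determinism: one master seed; each (video, stage, frame) gets a fixed
substream via a seed sequence, so any frame is reproducible in isolation and
whole runs are bit-identical for a fixed config + seed.

## Problem sizes in the shipped experiments

The test-suite and acceptance-script experiments run at deliberately modest
sizes chosen to make their statistical signal unambiguous: grid sweeps and
conservation checks use 2–3 frames per stage over four videos; the
forecast-vs-baseline comparison uses eight frames per stage (stage averaging
at that depth cleanly resolves the band's narrowing against sampling noise)
at g = 250; the full pipeline demonstration uses five frames per stage, four
videos per genotype, g = 62.5 and 2000 bootstrap replicates. Bootstrap
coverage is checked at 200 simulation replicates of n = 20 per group, and
mixed-effects recovery over 25 replicates of a 6-video × 5-stage design.

## Known limitations

- Ripley's K is single-radius; no L-transform or multi-radius curves.
- The per-cell window makes K sparse at fine grids (g = 31.25 leaves almost
  every cell with < 2 points, so the feature degenerates to its sentinel
  there — consistent with the observation that the finest grid reduces the
  task to per-cell binary occupancy).
- The mixed model assumes Gaussian errors on metric values, which are
  non-negative; with strong group separation and little residual noise its
  p-values can be extreme.
- Stage labels are taken as given; no automatic staging is attempted.
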