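# Methods

## Vibration model (synthetic generator)

The generator emulates a mid-glottal videokymographic recording of
sustained phonation. The default acquisition is 3200 frames/s for 2000
frames (625 ms). A recording is a sequence of vocal cycles realized on a
**continuous time axis** and only then sampled on the frame grid, so
quantization error (at most half a frame period per event) is an explicit,
testable property rather than an artifact of the construction.

Cycle *i* has

* period `T_i = (1/f0_hz)·(1 + ε_i)`, with `ε_i` iid Gaussian of SD
  `sigma_T`, truncated at ±3 SD so periods stay positive;
* peak amplitude `A_i = base_amplitude_px·(1 − nonvibrating_fraction/2)·(1 + η_i)`,
  with `η_i` iid Gaussian of SD `sigma_A`, same truncation, floored at 5%
  of the base amplitude;
* an open phase occupying `(1 − closed_quotient)` of the period, shaped as
  a raised-cosine pulse, on a constant `posterior_gap_px` baseline.

The Gaussian law is an assumption (the data this package emulates does not
constrain the noise law); it buys the closed form
`E[Jitt] = 100·(2/√π)·sigma_T` used throughout the tests, since for iid
normals `E|X − Y| = 2σ/√π`. The raised cosine is likewise a choice: smooth,
single-peaked, and qualitatively matching published width waveforms. A
stiff, infiltrated (malignant-type) fold is modelled by
`nonvibrating_fraction > 0`, which suppresses that fraction of one fold's
amplitude; in rendered frame stacks the corresponding edge barely moves.

Frame stacks render a dark glottal gap (intensity 30) between bright
tissue (200). The gap width tapers along the glottal axis as
`sin(π·y/H)`, widest at mid-glottis. Pixels are centered on integer
coordinates and filled by exact partial-pixel coverage, so subpixel edge
detection is meaningful; Gaussian pixel noise is added last and clipped
to [0, 255].

### Key parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `fps` | 1/s | 3200 | emulated camera's high-speed mode |
| `n_frames` | – | 2000 | 625 ms of phonation |
| `f0_hz` | Hz | 250 | typical sustained-phonation F0 |
| `sigma_T`, `sigma_A` | – | 0 | injected perturbation, relative SD |
| `base_amplitude_px` | px | 12 | peak glottal half-width at mid-glottis |
| `closed_quotient` | – | 0.4 | fraction of the cycle with closed glottis |
| `posterior_gap_px` | px | 0 | incomplete-closure residual width |
| `asymmetry` | – | 1 | left/right amplitude share ratio |
| `nonvibrating_fraction` | – | 0 | stiff-fold amplitude suppression |

### Cohort presets

Three per-group parameter distributions (normophonic / benign /
malignant). Per-subject `sigma_T` and `sigma_A` are lognormal with medians
back-derived from the target group medians of Jitt and Shimmer via the
closed form — e.g. normophonic `sigma_T = 1.30/112.84 ≈ 0.0115`, benign
`3.00/112.84`, malignant `4.26/112.84`; shimmer targets 3.85 / 10.21 /
10.81% give the `sigma_A` medians — with log-spread 0.7 chosen to mimic
the reference cohort's dispersion-to-median ratios near 1. F0 is
gender-dependent (women higher); the per-gender centers were solved so
each group's gender mixture mean matches the group F0 (e.g. normophonic:
0.658·285 + 0.342·210 ≈ 259 Hz with the group's 25 F / 13 M composition).
Malignant subjects additionally draw `nonvibrating_fraction` from
U(0.3, 0.8). This calibration is necessarily approximate: only group-level
medians and dispersions were available as targets, not distributions.

**What the generator does not emulate:** mucosal-wave propagation,
endoscope motion, illumination gradients, anterior–posterior phase
differences, irregular (biphonic/subharmonic) vibration regimes, and any
spatial calibration (widths stay in pixels). Passing tests therefore
validate the measurement chain and protocol logic, not clinical
performance on real recordings.

## Kymographic edge detection

Per kymogram row: light Gaussian smoothing (σ = 0.5 px), threshold at the
midpoint between the row-local gap minimum and the row median (tissue
level), and linear interpolation of the two threshold crossings to
subpixel positions. Detection uses only normalized row contrast, so it is
invariant to intensity gain/offset and equivariant under translation. Rows
whose contrast falls below 10% of the global dynamic range are treated as
*closed* (width 0, left = right), not missing; a fully uniform kymogram is
therefore a legitimately closed glottis. If more than half of the rows of
a structured kymogram are below the contrast floor the recording is
rejected as unusable — mirroring the clinical exclusion of recordings
unsuitable for analysis. The smoothing width was chosen as the best
noiseless/noisy compromise: heavier smoothing (σ ≥ 1) systematically
widens narrow gaps and costs ~0.8 px RMS on the round trip.

## Cycle segmentation

Closure candidates are maximal runs of the (lightly smoothed) waveform
below 25% of its 2nd–98th-percentile dynamic range, separated by at least
a quarter of the dominant period taken from the autocorrelation peak.
Each cycle onset is then refined on the **raw** waveform: the rising and
falling crossings of the pulse's 50% level (local minimum to
parabolic-refined local peak) are located by linear interpolation and
extrapolated back to the pulse foot, `t_onset = t_up − (t_down − t_up)/2`,
which is exact for a raised-cosine pulse. Two numerical details matter:

* Any marker placed at a fixed *phase fraction* of the cycle sits at an
  offset proportional to `T_i` and biases measured jitter low by ~10% at
  a closed quotient of 0.4; the onset extrapolation removes that bias.
* The per-pulse 50% level and the parabolic peak refinement prevent
  frame-grid sampling of the pulse maximum from masquerading as amplitude
  perturbation (without it, a perfectly periodic waveform shows ~1.3%
  spurious Shimmer; with it, < 0.2%).

Runs truncated by the recording boundaries are skipped. Cycle amplitude is
the parabolic-refined peak minus the in-cycle minimum of the raw waveform,
robust to posterior-gap baseline offsets. Fewer than `min_cycles`
(default 10) detected cycles, or a constant waveform, raises an
unusable-recording error. Periods are reported in ms; all quotients drop
incomplete windows at the series ends.

## Statistics

Kruskal–Wallis uses the tie-corrected H (via scipy); a parameter with no
variation at all is reported as a "no variation" row instead of a p-value.
No multiple-testing correction is applied across the 12 parameters — a
deliberate mirroring of the emulated protocol, flagged here as a caveat.
Single-parameter ROC analysis orients each parameter so that larger values
indicate disease (the flip is recorded), computes AUC by the midrank
Mann–Whitney identity, and attaches a DeLong 95% CI; a percentile
bootstrap CI is available behind a flag. AUC equals the concordant-pair
fraction with ties counted half, which the tests verify against a
brute-force double loop.

## Classification protocol

* **Split:** group-stratified 70/30; per-group training counts by
  largest-remainder rounding (groups 38/64/36 → 27/45/25, total 97), with
  a chi-square balance check attached. Different seeds permute
  assignments but never the counts.
* **Feature selection** (training split only): candidate sets from
  univariate-AUC top-k (k ∈ {3, 5, 8}), a |Spearman ρ| > 0.9 redundancy
  filter keeping the higher-AUC member, and all features; gender is always
  kept as a candidate. Sets are benchmarked by mean accuracy over 5-fold
  × 2-repeat stratified CV with a fixed reference XGBoost. The published
  predictor sets for both tasks are available as `features="published"`
  and are the default when selection is skipped.
* **Tuning:** Bayesian optimization (Gaussian-process surrogate, Matern
  5/2, expected improvement, 10 random initial trials, 50 trials by
  default) over learning rate (log 0.01–0.3), max depth (2–6), trees
  (50–300), subsample and column subsample (0.5–1), min child weight
  (1–10), maximizing mean 5-fold stratified CV AUC on the training split;
  the final model is refit on the full training split.
* **Thresholds:** organic detection uses the training Youden optimum;
  malignancy detection uses the largest threshold with 100% training
  sensitivity (the minimum positive-class score) — the operating point
  that never misses a cancer on the data it was set on. With degenerate
  (all-equal) scores both rules collapse to sensitivity 1 / specificity 0.
* **Explanation:** exact TreeSHAP on the log-odds scale via XGBoost's
  native contribution predictor; per sample the attributions plus the base
  value reproduce the margin to float32 precision (checked), and features
  are ranked by mean |attribution|.
* **Gender encoding:** 0 = female, 1 = male, fixing the sign convention of
  the SHAP narrative (male as elevated malignancy risk).
* **Determinism:** every stochastic step (split, CV folds, optimizer,
  XGBoost) is seeded; a fixed (data, seed, config) triple reproduces the
  report bit-for-bit, and feature selection, tuning and thresholding
  provably never touch the test split (a corruption test asserts this).
* **Persistence:** a single JSON file holding the booster dump,
  hyperparameters, threshold, feature list, seeds and metrics.

## Problem sizes

Unit and acceptance tests run on 400–2000-frame recordings,
16-seed ensembles for the closed-form recovery checks, and a
200-subjects-per-group cohort for the protocol-level checks (model vs
best univariate parameter, label-permutation null, threshold-rule
sensitivity), with 10–20 optimization trials — sizes chosen so the full
suite completes in well under a minute of compute while keeping the
Monte-Carlo error far inside the asserted tolerances.

## Known limitations

* Kymographic equivalence with proprietary clinical software cannot be
  claimed; only self-consistency on synthetic data is demonstrated.
* The perturbation-measure definitions are the standard MDVP-style forms;
  other implementations differ in normalization and window handling, so
  absolute values are comparable only within this package.
* Preset calibration reproduces group medians and ordering, not full
  distributions; classifier metrics on synthetic cohorts say nothing
  quantitative about patient data.
* The F0 group contrast in synthetic cohorts can reach nominal
  significance at large n even though it is driven purely by the gender
  mixture, unlike the emulated study's non-significant F0 — a consequence
  of calibrating to group means with simple lognormal spreads.
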