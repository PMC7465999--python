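# Methods

## Scope and design

The package implements a complete analysis chain for n-back driver
cognitive-load classification — generator → preprocessing → 323-feature
extraction → feature selection → classification/evaluation — with the
synthetic-data generator as a first-class, tested component. The chain
is deterministic given one integer seed; every stage can also consume
real data (EDF physiology + vehicular CSV + an event list).

## The synthetic session model

A session is a schedule of 60-s events, each a (scenario, task) pair
with scenarios CR/HE/SW and tasks baseline/1-back/2-back. The default
schedule holds 12 events per participant (two baseline passes plus one
1-back and one 2-back pass per scenario), mirroring the baseline-heavy
imbalance of within-subject n-back driving designs; the default cohort
is 16 participants, i.e. 192 windows with a 96/48/48 task split.

Channel models (default rates: 256 Hz EEG/EOG/ECG, 32 Hz
GSR/respiration, 10 Hz vehicular):

* **EEG** (30 channels, 10–20 montage): spectrally shaped noise — a
  1/√f pink background plus independent band-limited components per
  canonical band (δ, θ, α, β, γ). Simple, but sufficient to make every
  band-power and ratio feature meaningful.
* **EOG**: blink templates (fast half-cosine closure ≈ 0.12 s, slower
  reopening ≈ 0.18 s, amplitude ≈ 300 units) at Poisson times with a
  0.5-s refractory gap, on drifting noise.
* **ECG**: an IBI point process — Gaussian around the participant's
  mean interval with AR(1) beat-to-beat correlation (φ = 0.6, so the
  nonlinear HRV members are non-degenerate) plus 0.1-Hz (LF) and
  respiratory-frequency (HF) oscillatory modulation — convolved with a
  PQRST template.
* **GSR**: tonic drift plus phasic skin-conductance responses
  (≈ 1.5-s rise, 4-s exponential decay) at Poisson times.
* **Respiration**: a sinusoid at the participant's rate (≈ 0.25 Hz)
  with additive noise.
* **Vehicular**: lateral position as a mean-reverting
  (Ornstein–Uhlenbeck) path; steering wheel angle as a smooth
  correction component plus a telegraph zigzag whose switch rate
  drives the reversal count; yaw as low-pass noise; lane departure
  flagged when |lateral position| > 0.9 m.

Every injected event (blinks, R peaks, SCR peaks, steering reversals)
is recorded in a GroundTruth object used by the oracle tests.

### Load effects and calibration

Task effects are multiplicative on the generating parameters (α/θ EEG
power, blink rate, mean HR, SDNN scale, LF/HF, SCR rate and amplitude,
respiration rate, lateral-position SD, steering reversal rate), all 1
for baseline by construction. The side-wind scenario raises the
multipliers (power 1.5 on the exponent scale) because continuous
lateral control expresses load most strongly there.

Effect magnitudes are not reported quantitatively in the literature
this design follows, so the defaults were calibrated once and frozen:
multipliers of ~1.1–1.25 (1-back) and ~1.2–1.6 (2-back) combined with
per-participant trait heterogeneity (baseline HR ~ N(70, 6) bpm, alpha
amplitude and blink/SCR rates log-normally dispersed, etc.). The
calibration criterion: a default random forest on the
baseline-vs-task regrouping reaches test balanced accuracy ≥ 0.85 on
the full multicomponent feature set while the EEG-only block stays
clearly below — so the pipeline's headline claim (multicomponent
beats single-modality) is expressible but not trivial. What passing
these tests shows is that the *pipeline* recovers planted structure;
it does not validate the generator against real drivers — real EEG
artifacts, non-stationarity, electrode drift and behavioural
compensation are all absent.

A fast tabular generator (`generate_feature_table`) plants
standardized class-mean shifts (0 / e/2 / e for baseline / 1-back /
2-back, alternating sign across columns) directly into a named
323-column table for selection/classification tests at scale; its
default composition mirrors the 306/237/178 reference imbalance.

## Preprocessing

* EEG: 8th-order Butterworth band-pass 0.5–60 Hz plus 4th-order
  48–52 Hz band-stop, both applied forward–backward (zero phase), so
  spectral features are not phase-shifted. Requires fs > 120 Hz.
* Median filter (default kernel 5) for GSR, respiration, vehicular
  channels.
* QRS detection: 5–15 Hz band-pass → derivative → squaring → 150-ms
  moving-window integration → running signal/noise thresholds with a
  200-ms refractory period → peak snap to the band-passed maximum.
  Recall and precision are ≥ 0.99 on clean synthetic ECG.
* IBI cleaning: intervals outside [300, 2000] ms or deviating > 30 %
  from the 5-interval local median are replaced by the local median of
  neighbouring good intervals. Deterministic and idempotent; the
  original tooling this replaces was an interactive GUI.
* Segmentation: window = [event_start + 10 s, event_start + 60 s),
  half-open, all channels sliced consistently; truncated events are
  skipped with a warning.

## Feature conventions

Decisions that the upstream description leaves open, fixed here:

* Bands are half-open [lo, hi): δ [0.5, 4), θ [4, 7), α [8, 12),
  β [12, 30), γ [31, 50) Hz (the printed θ–α and β–γ gaps are kept).
* Welch everywhere with a Blackman window and 50 % overlap; segment
  lengths 5 s (EEG), 10 s (GSR), 25 s (respiration; the 0.1-Hz-wide
  bands need both fine resolution and low main-lobe leakage), and
  32 s on the 4-Hz cubic-interpolated IBI tachogram (LF [0.04, 0.15),
  HF [0.15, 0.40), total power [0, 0.40)).
* Entropies: SampEn/ApEn with m = 2, r = 0.2 × SD, Chebyshev distance,
  matches counted at d ≤ r (SampEn excludes self-matches);
  permutation entropy order 3, delay 1, normalized by log 3!.
  DFA: first-order detrending, box sizes 4–16 beats.
* Per-event features (blink duration, SCR rise time, …) are
  window-summarized by the **mean** over events; windows with no
  events carry NaN for those members (count/rate members are 0), and
  the modelling stage imputes NaNs with the training-column median.
* GSR "peak index" is the mean peak sample index normalized by window
  length (a peak-timing centroid). GSR peaks are picked on a 1-Hz
  low-passed copy with prominence ≥ 0.05 conductance units.
* Steering reversal rate: count of direction reversals with angular
  gap ≥ 1° on the Lowess-smoothed (locally linear, 110 points) wheel
  angle. Steering entropy is Boer-style: second-order Taylor
  prediction, 9 bins with edges at ±0.5α, ±α, ±2.5α, ±5α where α is
  the 90th percentile of absolute baseline prediction errors (the
  window's own errors when no baseline is supplied), Shannon entropy
  in bits. "High-frequency steering component" is Welch power above
  0.3 Hz. Zero crossings are strict sign changes of the raw angle.
* Quantiles interpolate linearly between order statistics; kurtosis is
  Pearson (non-excess).
* Lateral-position MSE is taken around the lane centre (0 m).

## Selection

SFFS (classic semantics: best single forward addition, conditional
backward removal whenever dropping a member strictly improves the
best-known score at the smaller size, ties broken by column order,
cap at 15 features) runs over the 270 EEG columns only — they come
from neighbouring electrodes and are heavily redundant. The wrapper
score is the 5-fold cross-validated scr = 2·sin(π·sen/2)·sin(π·spe/2)
of a Gaussian-kernel SVM (macro-averaged one-vs-rest for multiclass);
scr is bounded in [0, 2], zero when either class collapses, so the
wrapper cannot buy score on the majority class alone. All other
columns are ranked by random-forest permutation importance (mean
decrease accuracy, 10 repeats) on a held-out 20 % validation split;
columns with strictly positive mean importance are kept. SFFS is a
heuristic: tests assert it recovers planted features and stays within
5 % of exhaustive search on small pools, not exact optimality.

## Classification and evaluation

70/30 split and 5-fold CV folds are stratified by the mapped label
(the 178-of-721-scale imbalance makes unstratified splits unstable)
and fully seed-controlled. Features are median-imputed and z-scored
with statistics fitted on training rows only. k-NN uses K = 5,
Euclidean distance and 1/d² vote weights (exact-zero distances win
their neighbourhood); the SVM uses a Gaussian kernel with C = 1,
γ = 1/(n·var), one-vs-rest for multiclass; the random forest uses 500
bootstrap-aggregated trees of unlimited depth. No imbalance
correction is applied; BACC and MCC are reported precisely because of
that. Confusion matrices are stored rows = predicted ×
columns = actual; one-vs-rest reduction conserves totals. Metric
members with zero denominators are flagged undefined rather than NaN.
The driving scenario can be appended as an integer-coded categorical
feature (CR 0, HE 1, SW 2); scenario-wise evaluation reruns the whole
split→train→test pipeline inside each scenario stratum.

## Problem sizes

Defaults were chosen so a full run stays light: the default cohort
(16 participants × 12 events) generates and extracts in ~25 s and the
complete acceptance computation (cohort, selection, nine model ×
scheme evaluations) in ~90 s on one CPU; the test suite uses 2-participant
cohorts for unit fixtures and 10-seed loops for the statistical
properties.

## Known limitations

* The generator's effect sizes are calibrated, not measured; absolute
  classification numbers on synthetic cohorts are not comparable to
  any real study — only directions and orderings are.
* EEG artifact handling is reduced to an optional amplitude clip; no
  ICA/ocular correction (windows here are artifact-free by
  construction).
* Rows are split i.i.d.; models are not individualised and no
  leave-one-participant-out protocol is provided.
* The EDF writer covers plain 16-bit EDF only (no EDF+ annotations).
* Blink and SCR detectors assume the synthetic waveform polarity
  (positive deflections); real recordings may need inversion first.
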