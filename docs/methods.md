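# Methods

`ecgload` implements a transparent pipeline from single-lead ECG (or
precomputed RR series) to session-level internal training load: signal
conditioning, R-peak detection, HRV feature extraction, Banister-form TRIMP
target construction, leakage-audited feature selection, cross-validated
supervised estimation, and Shapley attribution.  Every stage is exercised
end-to-end against a synthetic session generator, so the whole pipeline is
testable without any external recording archive.

## The synthetic session generator

Each session is one observational unit with a subject id, sex, session
class (training or competition), duration, and physiological targets (mean
HR, resting HR, maximum HR, RMSSD, LF/HF).

**Beat model.** Beat times follow an integral pulse frequency modulation
(IPFM) scheme: the instantaneous cardiac period is

    T(t) = T0 + A_LF sin(2π·0.1·t + φ1) + A_HF sin(2π·0.25·t + φ2),

and a beat is emitted whenever ∫ dt/T(t) crosses an integer (dense-grid
trapezoid integration, dt ≤ 10 ms, with two vectorised Newton polish steps;
beat times are deterministic functions of the spec and seed).  Sinusoidal
band surrogates were chosen over AR spectra because they make the LF/HF
ratio analytically controllable: for pure tones it equals A_LF²/A_HF².

**Why a broadband component exists.** A sinusoid of period-amplitude A
sampled once per beat contributes `sqrt(2)·A·|sin(πfT0)|` to the RMS of
successive differences.  At exercise heart rates the factor `|sin(πfT0)|`
is small (≈0.13 for the LF tone, ≈0.32 for the HF tone at 142 bpm), so
realising an RMSSD of ~50 ms with tones alone would require period
excursions far below the 250 ms physiological guard.  The generator
therefore shifts power into a white beat-to-beat jitter component (clipped
at 3 SD) whose flat spectrum contributes `σ_w²·bandwidth/f_Nyquist` to each
band; tone powers are then re-solved so the series' LF/HF ratio still
equals the target.  Tones alone are used whenever they fit within the
guard.  A short fixed-point calibration (≤3 passes, rescaling T0 and the
modulation amplitudes against the *empirical* mean RR and RMSSD of the
emitted series) absorbs the second-order bias of the amplitude map, which
is non-negligible at large modulation depth.  Contracts: empirical RMSSD
within 15% of target, mean HR within 2 bpm, LF/HF within sampling error.
Targets that cannot be realised inside the guard raise a diagnostic error;
the cohort sampler shrinks infeasible RMSSD draws to the feasible region.

**Waveform model.** The ECG is a fixed PQRST template (sum of five
Gaussians, 1 mV R spike) placed at each beat time.  Morphology realism is a
non-goal: only R-peak timing feeds the pipeline.  Corruption follows the
noise spec: baseline wander (sinusoid below 0.5 Hz, default 0.2 Hz),
powerline hum (50 Hz by convention here; configurable), motion bursts
(1–3 s windows of white noise at a Poisson rate), and recording gaps
(contiguous interior runs totalling exactly `round(gap_fraction·n)`
samples, `gap_fraction ≤ 0.02`).

**Cohort defaults.** Per-class population parameters are the descriptive
statistics of the two session classes in athlete monitoring: training
sessions draw mean HR 142.6 ± 11.8 bpm, RMSSD 56.1 ± 13.7 ms,
LF/HF 1.33 ± 0.41, RHR 62.8 ± 7.9, HR reserve 138.1 ± 12.3; competition
sessions 159.3 ± 14.9 bpm, 49.5 ± 15.2 ms, 1.76 ± 0.53, 66.5 ± 8.3,
147.8 ± 13.1.  Session durations are 40 ± 4 min (training) and 60 ± 6 min
(competition), chosen as realistic structured-session lengths.  Sexes
alternate across subjects; HRV draws are sex-blind.

**What the generator does not emulate.** Real ECG morphology and its
inter-subject variability, ectopic beats, respiratory sinus arrhythmia
beyond the HF tone, intensity drift within a session (warm-up/cool-down),
sex differences in HRV, and any respiration channel.  Consequently, a
passing pipeline here demonstrates correctness of the *computational*
chain under controlled autonomic structure and additive corruption — not
detector robustness to pathological morphology or real motion artifact.

## Signal conditioning

* Band-pass: 0.5–40 Hz fourth-order Butterworth, applied zero-phase
  (forward–backward, second-order sections, reflect padding).  The stated
  6 Hz fourth-order low-pass is reserved for **derived** series
  (instantaneous HR-like traces) and for the artifact-replacement smoother:
  applied to the raw ECG it would destroy QRS energy (QRS content spans
  roughly 5–40 Hz), making R-peak detection impossible.
* Artifact detection: non-overlapping windows (default 1 s) are flagged
  when their variance exceeds `max(k, 1)` times the record's median
  windowed variance (default k = 5; values below 1 clamp to the median
  itself).  Mask granularity is the window.
* Artifact mitigation: flagged spans are replaced by the 6 Hz-smoothed
  trace and, if still above it, variance-rescaled about their mean down to
  the record's median windowed variance.  Unflagged samples are returned
  bit-identical.  This "replace-and-renormalise" policy is the package's
  reading of adaptive artifact filtering; an LMS-style filter would need a
  reference channel that single-lead recordings do not have.
* Gaps: interior gaps are linearly interpolated; leading/trailing gaps are
  trimmed (linear interpolation is undefined there).  The gap budget is
  strict: a fraction ≥ 2% is rejected with the offending fraction reported.
* SNR: `10·log10(P_signal/P_noise)` with the noise estimated as raw minus
  band-passed signal; zero noise power reports +inf rather than an error.
  For synthetic data, where the clean waveform is known, `true_snr`
  measures against the ground-truth reference instead.
* Normalization: z-scores use the sample mean/SD of the *fitting* data and
  return the statistics so held-out folds are always transformed with
  training-fold statistics.  Outlier removal is a single pass at 3 sample
  SDs of the mean, computed once — no re-iteration — so a mass-dominated
  spike in a small sample (e.g. one 100 among four 0s, 1.79 SD) is
  deliberately kept.
* Windowing: 60-s windows at 30-s hop, starts at 0, 30, 60, … while
  `start + 60 ≤ span`; every interior instant is covered exactly twice.

## R-peak detection

A Pan–Tompkins-style chain with the classic constants, since only the
approach, not the parameters, is standardised: derivative, squaring, 150 ms
moving-window integration, dual adaptive thresholds with 0.125
running-mean updates, a 200 ms refractory period, and a search-back pass at
half threshold when an inter-peak interval exceeds 1.66× the running RR
average.  The beat fiducial is the local maximum of the filtered ECG within
±40 ms of the (lag-corrected) integrator peak, which gives millisecond IBI
accuracy.  All thresholds derive from the data, so detections are invariant
to positive amplitude scaling and equivariant to time shifts.

RR cleaning flags intervals outside [250, 3000] ms or deviating more than
30% from the median of their 11-interval neighbourhood, and replaces them
by local linear interpolation; a series with >20% suspect intervals is
rejected.  Detector scoring uses greedy one-to-one nearest matching within
50 ms (default) and reports F1 = 2TP/(2TP+FP+FN) and the mean absolute
inter-beat-interval error over matched consecutive pairs.

## HRV features

* Time domain (per 60-s window, mean-aggregated to session): RMSSD (RMS of
  successive differences, population convention), SDNN (sample SD), mean
  HR = 60000/mean RR.
* Frequency domain (session-long series; 60-s windows cannot resolve
  0.04 Hz content): the RR series is cubic-spline interpolated onto a
  uniform 4 Hz grid, mean-detrended, Welch-estimated (60-s Hann segments,
  50% overlap), and integrated over LF [0.04, 0.15) and HF [0.15, 0.40) Hz.
  HF = 0 yields a missing ratio, never an infinity.  Known limitation:
  spline resampling through sparse beat samples attenuates HF content at
  low heart rates (beat rate < ~4× band edge), biasing LF/HF upward below
  ~70 bpm; at exercise heart rates the bias is ~2–3%.
* Nonlinear: Poincaré SD1 = RMS(successive differences)/√2 — the
  successive-difference mean is treated as zero, the standard Poincaré
  reading, making SD1 ≡ RMSSD/√2 an exact identity — and SD2 =
  SD(successive sums)/√2 (population).  Sample entropy SampEn(m=2,
  r=0.2·SD) counts template matches with Chebyshev distance, self-matches
  excluded, the same template count at both lengths, truncated at 2000
  intervals to bound the O(N²) cost.
* Session aggregation: mean over valid windows.  Resting and maximum HR
  are baseline cardiovascular indicators and are taken from session
  metadata when present; without metadata the package falls back to the
  5th percentile of windowed mean HR (resting proxy) and the windowed
  maximum — proxies that are meaningful only when the recording includes
  rest periods, and logged as such.

## TRIMP target and leakage audit

TRIMP = Σᵢ Dᵢ·ΔHRᵢ·exp(b·ΔHRᵢ), with ΔHR = (HRex−HRrest)/(HRmax−HRrest)
clamped to [0, 1] (observed HR may exceed a declared maximum on noisy
data), Dᵢ in minutes, and b = 1.92 (male) / 1.67 (female).  The default
interval basis is per-window: each 60-s half-overlap window contributes one
hop-length (0.5 min) interval, so durations tile the analysed span once and
the sum is invariant to splitting a constant-intensity session.  A
whole-session single-product variant is available by configuration.

Intensity strata are empirical TRIMP tertiles (linear-interpolation
quantiles at 1/3 and 2/3, left-closed bins, boundary ties to the lower
stratum).  The leakage audit removes predictors named after the target or
its derivatives (TRIMP, ACWR) and any affine alias of the target (|Pearson
r| = 1 within 1e−9); a column identical to the target is a hard failure.
Near-circular physiological predictors (mean HR itself) are retained by
design — the documented circularity of this modeling task lives in the
features, not in hidden copies of the target.

## Selection and modeling

Selection order is fixed: constant columns out, then the iterative VIF
filter (VIFⱼ = 1/(1−R²ⱼ); drop the single largest above 5 per pass, ties to
the later-listed column), then kNN mutual-information ranking (k = 3), then
recursive feature elimination (forest importances, one drop per fit,
default keep 8).  VIF precedes RFE because importances are unstable under
collinearity.  Selection and z-scoring run inside CV training folds only.

Models: gradient-boosted trees (XGBoost; 500 trees, depth 4, learning rate
0.05, early stopping after 50 rounds on an inner 10% split), random forest
(500 trees), and an RBF SVM (C = 1, γ = 1/p after z-scoring).
Cross-validation is 10-fold, stratified on session type plus TRIMP stratum
(falling back to type-only when a composite stratum is smaller than k),
deterministic under the seed.  Metrics: MAE, RMSE, R² = 1 − SSres/SStot
(negative values are reported, not clipped; constant targets report a
missing R²); macro precision/recall/F1 and macro one-vs-rest AUC for the
three-class task.  Model pairs are compared with two-sided paired t-tests
on fold-wise differences (df = k−1), Holm-corrected across the family;
zero-variance differences short-circuit to p = 1 (zero mean) or p = 0.

**Shapley attribution** is exact interventional coalition enumeration: for
p ≤ 12 features the coalition value v(S, x) = E_b[f(x_S, b_∖S)] is computed
against a background sample for all 2^p subsets, giving attributions that
satisfy local accuracy (Σφ = f(x) − E_b[f]) by construction and exactly
match the Shapley definition; beyond 12 features a seeded
permutation-sampling approximation reports its Monte-Carlo error.
Tree-model predictions are single precision, so cross-checks against
independently coded oracles compare at the 1e−4 grain.

## Known limitations and an honest negative result

On the default 200-session synthetic cohort, the boosted model's
cross-validated R² for TRIMP regression is ≈ 0.7–0.8, not higher, and this
is a property of the task, not the learner: the target is an exact
deterministic function of (predictor roster, session duration, sex) — an
analytic reconstruction using those reaches R² > 0.999 — but duration and
sex are TRIMP constituents deliberately excluded from the predictor set by
the leakage policy.  Their within-class variability (±4–6 min; two b
values) is unrecoverable from HRV features that carry no duration or sex
information, and the exponential TRIMP form amplifies these errors in the
right tail.  Reported cross-validated skill can only approach 1 when
session duration is nearly deterministic given the predictors (e.g. highly
standardised session lengths per class).  The permutation-null control
(R² ≤ 0.1 on shuffled targets), the boosted-vs-SVM ordering, and the
classification AUC (~0.92) behave as expected.

## Problem sizes and tolerances

Test and acceptance runs use seeded cohorts sized for a single CPU: a
40-session cohort of 8-minute records for the signal chain, 100 five-minute
RR series for spectral recovery, and a 200-session cohort at default
durations for modeling.  Numerical tolerances: SNR/metric identities at
1e−9; brute-force HRV oracles at 1e−9 (1e−12 for SampEn); spectral target
recovery at 15% (mean over 100 seeds); detector F1 ≥ 0.99 and |IBI error|
≤ 10 ms on clean records; booster-related comparisons at single precision.
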