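# Methods

## Signal model and pipeline

The object of analysis is the normal-to-normal interval (NNI) series: the
times between consecutive normal heartbeats, in milliseconds, indexed by
beat time in seconds. The pipeline is

1. **Pre-conditioning** — sharp-peak removal on the interval sequence;
2. **Resampling** — cubic-spline interpolation of intervals against their
   midpoint times onto a uniform 4 Hz grid (the tachogram);
3. **Band features** — per sliding window: Welch band powers LFp/HFp over
   LF = [0.04, 0.15) Hz and HF = [0.15, 0.4) Hz, normalized powers, and
   the power ratio;
4. **Instantaneous amplitude** — zero-phase bandpass into LF and HF,
   Hilbert envelope, per-window two-sided trimmed mean (LFiA, HFiA);
5. **Categorization** — polynomial-kernel SVM over a 2-D feature pair,
   scored by categorization accuracy (CA, %), with optional per-subject
   baseline standardization and Wilcoxon rank-sum scenario contrasts.

## Windowing

Windows are half-open `[start, start + L)`, default L = 300 s with a 10 s
step. Time is measured in seconds from the first beat. A 300 s window
holds 12 full cycles of the 0.04 Hz LF lower edge; under the ten-cycle
rule of thumb it supports periods up to L/10 = 30 s. The effective Nyquist
limit of the un-interpolated NNI sequence is half the beat rate (0.5 Hz at
60 bpm), so the analyzed range 0.04–0.4 Hz is safe for ordinary heart
rates. `validate_window_length` exposes this arithmetic. Windows that
straddle a scenario boundary have no ground-truth state and are dropped;
additionally a configurable buffer (default 120 s) is trimmed from both
ends of every labeled segment before windows are labeled, to exclude
residuals of the adjacent activity.

## Spectral estimation

The power spectral density is estimated by Welch's method: Hann taper,
100 s segments (≥ 4 LF cycles each), 50% overlap, per-segment mean
removal; band power is the trapezoid integral of the PSD over the
half-open band. Band edges are half-open so that 0.15 Hz belongs to HF
only and no power is double-counted. Total power is operationalized as
TP = LFp + HFp, which makes the normalization identities exact by
construction: LFn = LFp/TP, HFn = HFp/TP, LFn + HFn = 1 and
HFn = 1 − LFn. This is the precise sense in which normalized powers carry
a single degree of freedom; the test-suite asserts the identity to
machine precision on every emitted feature row.

On a pure in-band tone of amplitude *a* the estimator recovers the
analytic band power *a*²/2 to well within 2%, and it agrees with a
brute-force rectangular-periodogram oracle within 3% on multi-tone
signals; both checks are in the suite.

## Pre-conditioning rule

An interval is a *sharp peak* when it deviates from the running median of
its 11-interval centered neighborhood by more than 30% of that median.
Flagged intervals are replaced by linear interpolation between the
nearest surviving intervals (replacement, not deletion, preserves the
time axis that windowing needs) and beat times are re-accumulated. The
rule is idempotent in practice — a second pass makes no further
replacements on the suite's fixtures — and both threshold and context are
configuration. The 30%/11-beat values are conventional choices; no claim
is made that they reproduce any particular published trace.

## Instantaneous amplitude

The LF and HF signals are obtained with an order-4 Butterworth bandpass
applied forward and backward (`sosfiltfilt`): envelope extraction is
phase-sensitive, and zero-phase filtering avoids group-delay distortion
while doubling effective stopband attenuation (an out-of-band tone one
octave past the edge is suppressed far below 5% in the tests). The signal
is mean-removed before the Hilbert transform — a nonzero mean would
corrupt the analytic-signal modulus. The envelope is computed once on the
full record and then windowed, which avoids per-window filter transients;
the first and last two periods of the band's lower edge are flagged as an
edge margin, and windows overlapping it carry a quality flag rather than
being dropped.

The per-window statistic is the two-sided trimmed mean with
`floor(trim·n)` samples dropped from *each* tail (default trim = 0.2,
i.e. 40% of samples removed in total). The phrase "the 20% largest and
smallest values" is ambiguous between per-tail and total; per-tail is the
default reading here and the total interpretation is available as
`trim_mode="total"`. Floor (not round) in the trim count and a stable
sort make the statistic deterministic; an implementation-independent
sort-slice-average oracle and `scipy.stats.trim_mean` both confirm it in
the tests. A window of length 300 s at 4 Hz holds 1200 envelope samples,
so any disturbance shorter than 20% of the window (≤ 60 s) is removed
entirely by the trim — the mechanism behind the artifact-robustness test,
where a 10 s / 300 ms deep-breath excursion perturbs the windowed HFp
trace several times more than the HFiA trace.

## Categorization

Features are z-scaled per dimension, then fit with an SVM with a
polynomial kernel of degree 3 and C = 1 (one-vs-one for multiclass);
degree and C are configuration, and no claim of optimality is made. CA is
resubstitution accuracy by default — the evaluation is a separability
measure of the training scatter, not a generalization estimate — with a
stratified k-fold option for the latter. One-dimensional metrics run
through the identical pipeline with the second coordinate pinned to a
constant (0 after scaling; any constant gives identical predictions,
which the suite asserts), making 1-D and 2-D accuracies directly
comparable.

Baseline standardization subtracts, per subject and per feature, the
median over that subject's first resting period, mapping every subject's
baseline to the origin; it is idempotent after the first application.
Scenario contrasts use two-sided Wilcoxon rank-sum tests on one average
value per subject and scenario ("average" read as the arithmetic mean;
median available). For groups of at most 10 without ties the exact
permutation null is used — fully separated 5-vs-5 groups give exactly
p = 2/252 — otherwise the tie-corrected normal approximation.

## Synthetic data

The generator modulates the interval function directly,

    m(t) = mean_nni + amp_lf·sin(2π f_lf t) + amp_hf·sin(2π f_hf t) + ε,

with ε white Gaussian (seeded) and beat times accumulated by
t_{k+1} = t_k + m(t_k)/1000. An integral-pulse-frequency-modulation model
was deliberately not used: direct modulation keeps the band content
analytically known (a tone of amplitude *a* carries power *a*²/2), which
is what makes the generator an oracle. Artifacts: deep breath and
transient bradycardia are raised-cosine interval excursions of given peak
magnitude and duration; an ectopic beat rescales one interval by 0.6 and
its successor by 1.4 (the compensatory pair of a premature beat; the
magnitudes of real ectopy vary, this is a standard stylization).

The `part1` preset emulates a five-scenario protocol — Rest 1, Math,
Rest 2, Exercise, Rest 3, 900 s each (the short transition interludes of
a live protocol are omitted). Archetype parameters (ms):

| scenario | mean NNI | LF amp @ 0.1 Hz | HF amp | noise SD |
|----------|---------:|----------------:|-------:|---------:|
| rest     | 1000     | 40              | 50 @ 0.25 Hz | 15 |
| math     | 900      | 60              | 20 @ 0.25 Hz | 15 |
| exercise | 650      | 40              | 20 @ 0.30 Hz | 15 |

Directions follow the qualitative physiology the package is built to
detect: mental stress raises LF and suppresses HF relative to rest;
exercise shortens the mean interval and suppresses HF while LF stays at
the rest level (consistent with exercise LF remaining similar or lower).
The magnitudes realize the preset's design intent of an XOR-like layout:
rest and exercise coincide on the LF axis, math and exercise on the HF
axis, so no single feature separates all three states while the joint
2-D scatter does. These magnitudes are configuration, not physiological
claims.

What the generator does *not* emulate: respiratory-sinus-arrhythmia
coupling (HF frequency fixed per scenario rather than tracking a
breathing signal), 1/f broadband structure (noise is white), circadian
or fatigue trends, inter-subject variability (a protocol is one
"subject"), and QRS morphology (no ECG is synthesized). Passing tests
therefore demonstrate correctness of the estimators and the claimed
robustness and separability mechanisms on controlled input — not
clinical validity on human recordings.

## Numerical choices and degenerate inputs

- Resampling grid covers [first midpoint, last midpoint] at 4 Hz; fewer
  than 4 beats is an error, spans under 50 s warn.
- Band powers of a constant signal are exactly 0; both-zero band powers
  make the normalized pair undefined (error, not NaN propagation); zero
  HFp makes P1/P2/P5 and the ratios NaN-flagged.
- `floor` everywhere a count is derived from a fraction (trim counts,
  window counts, cycle counts), with a 1e-9 epsilon against float
  representation of products like 250·0.04.
- Determinism: all randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; refitting the SVM on identical data gives
  identical predictions.

## Problem sizes

The bundled protocol simulations use 900 s segments (4500 s total,
≈ 5000 beats) and the robustness experiment a 1800 s recording; both were
chosen as the smallest sizes that give every scenario dozens of
fully-interior analysis windows (≈ 36 per labeled segment after buffers).

## Known limitations

- Resubstitution CA overstates out-of-sample accuracy; use the k-fold
  option for generalization claims.
- The sharp-peak rule is a stand-in for unpublished pre-conditioning
  procedures; its thresholds are exposed but not validated against
  clinical artifact annotations.
- The spline resampler can overshoot at genuinely discontinuous interval
  jumps (mitigated, not eliminated, by peak removal).
- VLF/ULF bands, Lomb–Scargle or autoregressive spectra, and adaptive
  respiration-tracking HF bands are out of scope.
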