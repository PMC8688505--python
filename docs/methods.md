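# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and what the synthetic-data experiments do and
do not demonstrate about real EEG.

## Synthetic data model

The generator (`microdyn.synth`) plants every quantity the analysis later
estimates.

**Template maps.** Microstate templates are random mixtures of real
spherical harmonics of degree ≤ 3 evaluated at the electrode positions
(coefficients ~ N(0, 1/ℓ²)), mean-centred across channels and
unit-normalized.  Candidates are rejection-sampled until all pairwise
absolute spatial correlations are ≤ 0.7, failing after 1000 attempts.
This produces smooth, dipolar-looking scalp fields without claiming to
reproduce the published canonical topographies.  The shipped A–G templates
in `microstates.canonical_templates` are likewise *synthetic* parametric
stand-ins (linear and Gaussian-blob fields oriented like the published
class descriptions) used only to attach conventional names to fitted maps.

**Label sequences.** A semi-Markov process: dwell times are geometric with
mean `fs · mean_duration_ms / 1000` samples (memoryless, matching a
first-order Markov surrogate), with an optional fixed-duration mode for
sharp run-length oracles.  Jumps follow a row-stochastic matrix with the
diagonal removed and re-normalized.  Default dwell is 50 ms — a
conventional value for microstate analyses; the underlying study data's
dwell distribution is not characterized, so this is a package choice.

**EEG assembly.** `signal(t) = a(t) · Γ_label(t) + noise(t)` with a
sinusoidal alpha-band carrier `a(t)` (10 Hz, random phase per run) scaled
so the noise-free peak GFP equals `amplitude_uv` (default 15 µV), plus
spatially smoothed white noise (Gaussian kernel on great-circle distance,
σ = 0.5 rad) scaled to `RMS(signal)/RMS(noise) = snr`.  Default snr = 1
for generic fixtures; the recovery experiments state their snr per run.

**What this emulates and what it does not.** The generator reproduces the
things the estimators are sensitive to: quasi-stable topographies with
alpha-modulated amplitude, controllable dwell/transition statistics, and
controllable long-range structure.  It does not model eye-blink or muscle
artifacts, 1/f background spectra, inter-channel noise correlations of
real amplifiers, or the semantics of the design tasks.  Passing tests
therefore validate the *estimators and pipeline plumbing*, not claims
about real design-task EEG.

**Planted long-range memory.** A binary "gate" — the sign of exact
fractional Gaussian noise (Davies–Harte circulant embedding), held in
blocks of 25 samples — selects between two semi-Markov sequences running
on disjoint class groups.  Sign-thresholding preserves the fGn's Hurst
exponent (the arcsine law preserves the power-law autocorrelation tail),
so a larger gate exponent plants a larger mean Hurst over the class
bipartitions.  The block-holding keeps dwell structure intact but inflates
small-window DFA slopes; cohort Hurst values are therefore interpreted
*comparatively* across conditions, not as absolute exponents.

**Cohort conditions.** The synthetic study fixes, per condition, the dwell
time, the transition bias toward a preferred successor (0 = uniform
switching, i.e. maximal jump entropy), the gate exponent, and an
alpha-power gain relative to rest.  Idea generation (IG) is the most
random (bias 0, gate 0.5, largest alpha drop), the rating conditions
(RIG/RIE) the most structured (bias 0.5, gate 0.8).  These values encode
the qualitative contrast under study and were fixed at design time.

## Preprocessing

One-pass zero-phase band-pass: a Hamming windowed-sinc FIR kernel
(transition bandwidth 1 Hz, length `3.3·fs/tb` rounded odd) applied once
by convolution with reflection padding and exact delay compensation.

Global bad channels: (i) *flat* — any rolling window longer than 5 s with
peak-to-peak < 0.5 µV; (ii) *correlation* — correlation with the average
of the 4 nearest electrodes (great-circle distance) below 0.8; (iii)
*amplitude* — channel RMS deviating from the mean channel RMS by more than
3× the pooled per-sample SD.  The amplitude rule intentionally uses the
pooled signal SD as the scale: an across-channel Z-score at threshold 3
would flag ~1 channel in 6 clean recordings purely by the studentized-max
distribution of ~63 Z-scores, whereas the pooled-SD rule fires only on
channels whose amplitude is grossly out of family.  All thresholds are
config keys.

Local QC on 2-s epochs computes variance, median absolute gradient,
amplitude range and deviation-from-mean per (epoch, channel), Z-scores
each across channels within the epoch, and flags |Z| > 3.  On homogeneous
Gaussian data this falsely flags ~1.7% of (epoch, channel) pairs — the
expected cost of a 3-SD rule over ~250 Z-values per epoch; flagged
channels are repaired by spherical-spline interpolation, never dropped.
Segment rejection drops epochs with any |amplitude| > 100 µV or with
single-electrode / electrode-group Gaussian log-likelihood Z-scores beyond
3 across epochs (a parametric reading of the toolbox "probability"
criteria; the exact kernel is not specified there).

Spherical-spline interpolation is the order-4 Legendre series (50 terms,
ridge 1e-5) solved once per bad-channel set and applied to all samples.
ICA-based artifact removal is a pass-through hook only.  Chain order
follows the listing: filter → global detection (channels isolated) → epoch
→ local QC/repair → segment rejection → global interpolation → average
reference → polyphase resampling to 250 Hz.

## Band power and TRP

Welch PSD with a 500-sample Hann window and 250-sample overlap at the
250 Hz analysis rate; band power by trapezoidal integration with linear
interpolation at the band edges.  TRP is `log(P_task) − log(P_rest)` with
the *first* rest block as the only reference; log base 10 by default
(`trp.log_base`) — the base is not fixed by the formula's source and all
downstream inferences are sign/order based.  Welch is run on whole
condition records rather than per 2-s epoch (the stated window/overlap
needs no further assumption).  Channel TRPs average into the five printed
areas × two hemispheres; statistics use the package's own balanced
fully-within-subject rm-ANOVA (orthonormal-contrast decomposition,
Mauchly test at α = 0.05 gating the Greenhouse–Geisser correction,
partial η² per effect), verified against pingouin and statsmodels.

## Microstates

Assignment uses the absolute normalized spatial projection — equivalent to
|Pearson correlation| for average-referenced data and zero-mean unit-norm
maps — everywhere (fitting, back-fitting, GEV), so every quantity is
polarity invariant.  Map updates take the dominant eigenvector of the
assigned samples' outer-product sum.  Restarts initialize from K distinct
random peak topographies; ties in argmax resolve to the lowest class
index; empty clusters reseed from the worst-fit sample.  Convergence:
relative change in F below 1e-6 or 1000 iterations; F is asserted
non-increasing.  CV is undefined for `N_S − 1 − K ≤ 0`; such K are
skipped.  Peak maps enter clustering unnormalized (config switch).

Group alignment iterates subject-level label permutations (exhaustive for
K ≤ 7, Hungarian above — identical optima for the separable sum-of-|corr|
objective) against evolving eigenvector group maps.  Back-fitting labels
*all* samples (GEV, following its reporting convention, is evaluated at
GFP peaks); zero-GFP samples inherit the previous label.  The cohort
pipeline forces K = 7 per run for comparability and can log the CV-optimal
K alongside.

**Known limitation — run fragmentation.**  With a pure sinusoidal carrier
the signal amplitude vanishes twice per alpha cycle; near those zero
crossings additive noise dominates the topography and unsmoothed
back-fitting inserts spurious label switches.  At RMS SNR 2 this caps the
recoverable mean run duration at roughly half the alpha half-cycle
(~22 ms observed for a 50 ms planted dwell) regardless of the planted
value.  Map recovery is unaffected (|corr| ≥ 0.99); duration estimates
at moderate SNR are biased short, which is exactly why the original
no-smoothing choice matters when interpreting absolute durations.

## Sequence statistics

Entropies are raw plug-in (maximum-likelihood) estimates, base 2, with a
bias warning below `10·m^k` samples.  The entropy rate evaluates both
joint entropies over the same window positions so the difference
telescopes exactly for deterministic sequences.  AIF marginals are taken
from the two overlapping segments at each lag (hence `I(0) = H(X)`
identically); the lag grid is every sample up to 200 ms; the first peak is
the first strict local maximum, unsmoothed.  DFA uses the cumulative-sum
profile, non-overlapping windows log-spaced between 4 samples and the
series length, least-squares linear detrending per window, and the
arithmetic mean of per-window RMS residuals as F(Δn).  The reported Hurst
slope is fitted over 4 ≤ Δn ≤ N/4 (larger windows have < 4 replicates and
destabilize the fit); the full-range slope and fit R² are kept in the
diagnostics.  For class counts ≠ 7 the bipartition set generalizes to all
⌊m/2⌋-vs-rest splits (complement pairs deduplicated) — an extension beyond
the 7-class convention.

## Cohort statistics and problem sizes

Sequence statistics are computed per run and averaged within condition;
condition effects use one-way rm-ANOVA with GG correction and 15
Bonferroni-corrected paired tests.  The shipped experiments use cohorts of
3–5 participants with 16–60 s runs, 10-minute single-run recovery
experiments at SNR 2, n = 1e5–1e6 symbol sequences for the entropy/DFA
oracles, and 100 k-means restarts for the CV-based K scan (20 restarts
where only map recovery is at stake).  These sizes were chosen so each
experiment's sampling error is well inside its assertion tolerance.

## Limitations

* Plug-in entropies at history k = 6 on 7 classes are biased low for
  sequences much shorter than 10·7⁶ samples; cohort entropy rates are
  comparative, not absolute.
* The synthetic canonical A–G templates are non-authoritative name
  anchors; label names should not be compared across studies.
* The BrainVision/EDF readers pass through MNE and assume standard 10-10
  electrode names when no montage is embedded.
* Reproducing the original study's absolute numbers requires its deposited
  27-participant dataset; everything here validates the estimators on
  synthetic ground truth instead.
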