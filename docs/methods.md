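# Methods

## Problem and model

During resting-state fMRI, participants are instructed to stay still; the
residual head motion recorded by volume registration is therefore largely
involuntary. This package characterizes the *stochastic signature* of those
involuntary motions: the empirically estimated probability law of the
standardized fluctuations in head speed, summarized by Gamma shape and scale
with the scale read as a noise-to-signal ratio (NSR). The question the
analysis answers is whether these signatures shift with age and whether
autistic cohorts depart from age-matched neurotypical controls — in
particular whether their involuntary motor noise is elevated.

The pipeline is: 6-DOF realignment parameters → scalar speed waveforms →
micro-movement spikes (MMS) → Gamma-family MLE signatures → bootstrap
ensembles per (age bin × diagnosis) cell → pairwise nonparametric comparison
matrices and excursion effect sizes.

## Speed and excursion

The three translation (rotation) channels are collapsed into one speed by
the Euclidean norm of the framewise difference vector divided by the
repetition time — the standard framewise-displacement construction; an
absolute-sum alternative is available (`speed.combine: sum_abs`). No
composition of the three rotation parameters into a single geodesic angle is
attempted, and no head-radius arc-length conversion is applied to rotations.
Angular speed is kept in deg/s internally; rad/s is a pure display
conversion (factor π/180) that cannot affect the scale-invariant MMS but
does change angular excursion magnitudes.

Head excursion is the rectangle-rule path length Σ vᵢ·dt (mm or deg). It is
sign-invariant, additive over segments, and scales exactly with any
multiplicative amplitude factor — which is why it carries anatomical-size
information that MMS deliberately discards, and why the two are analyzed
separately.

## Micro-movement spikes

Each local speed peak p is renormalized as p/(p + m), where m is the mean of
the waveform over the window bounded by the troughs adjacent to the peak.
The window is *closed* — it includes both bounding minima and the peak — by
default; an *open* reading (bounds excluded) is available via
`mms.window: open` because the defining phrase ("points between the two
minima") admits both. Series endpoints act as troughs for boundary peaks so
short scans do not lose edge spikes. Plateaus are handled by run-length
compression: a maximal flat run higher than both flanks is one peak at its
first index, which makes extraction deterministic.

Properties relied on downstream, all property-tested:

- amplitudes lie in (0, 1], and in [0.5, 1] for non-negative waveforms
  (the window mean cannot exceed the peak);
- multiplying the waveform by any c > 0 leaves peak positions and amplitudes
  unchanged (allometric invariance, exact up to float rounding ≤ 1e-12);
- the embedded spike waveform preserves the source frame count.

Two staging options exist because the pipeline's figure order and its prose
admit both: extract peaks from the raw speed, or first form absolute
deviations from the subject's fitted Gamma mean and extract peaks from that
deviation waveform. `extract_mms` itself is a pure operation on the waveform
it is given (default `raw_speed`, which is what the worked toy examples
exercise); the end-to-end pipeline defaults to `mms.source: mean_deviation`,
following the staged pipeline. Both are implemented and selectable; no claim
is made about which the original analysis used.

## Gamma signatures

Four families are fitted by MLE — Gaussian, Lognormal (Gaussian on logs),
Exponential (mean-parameterized), Gamma — and the winner is the raw maximum
log-likelihood with no parameter-count penalty. The Exponential is the
shape-1 Gamma, so the Gamma log-likelihood is never below the Exponential's;
the implementation guards the nesting inequality against floating rounding
by keeping the better of the Newton root and the shape-1 point.

Gamma MLE uses Newton iteration on the profile likelihood for the shape
(digamma-based, tolerance 1e-10 relative, max 200 iterations) from the
Minka/Choi–Wette closed-form initializer; scale = mean/shape. A brute-force
2-D grid + golden-section maximizer of the log-likelihood serves as an
independent oracle in the tests (agreement within 1e-4 relative).

Confidence intervals are asymptotic Wald intervals from the
observed-information covariance, I(a,b) = n·[[ψ′(a), 1/b], [1/b, a/b²]];
coverage at the ensemble sample sizes used here is within [90%, 99%] in
seeded simulation. Wald intervals can extend below zero for very small
samples; sample-size floors (default 10 observations) and structured errors
on zero-variance data prevent silent nonsense.

Moments are closed-form: mean ab, variance ab², SD √a·b, skewness 2/√a,
kurtosis 3 + 6/a. Note that the variance ab² (sometimes written σ_Γ) is not
the SD; the signature object stores mean, variance and SD separately to
avoid the ambiguity. NSR ≡ scale = variance/mean holds to machine precision
by construction.

The log–log Gamma-plane fit regresses log b on log a by least squares and
reports slope, intercept, t-based 95% intervals and the residual norm; a
power-law cloud b = c·aᵏ maps to slope k, intercept log c.

## Cohort cells and bootstrap ensembles

Ages are floored and matched against seven inclusive bins: 5–10, 11–15,
16–20, 21–25, 26–30, 31–40, 41–65 years (configurable; the source tables
are inconsistent about whether the last bin ends at 60 or 65, and we use the
methods-text value 65). Out-of-range ages are excluded with a logged count.

Because cell sizes are uneven, comparisons run on standardized ensembles:
k = 100 subgroups of m = 25 subjects per cell (with replacement by default;
without-replacement supported and consistent in ensemble means within
Monte-Carlo error), each subgroup's MMS amplitudes pooled and fitted once.
The 100 fitted signatures per cell are the comparison units. Pooling
operates on the already per-subject-standardized amplitudes. A single master
seed derives an independent child seed per cell via `SeedSequence` keyed on
a crc32 of the cell label, so any cell is reproducible in isolation and a
whole run is byte-identical under a fixed seed. Degenerate subgroup fits are
redrawn from the same stream (max 10 retries, logged).

## Statistical comparison

Pairwise Kruskal–Wallis matrices are computed within TD, within ASD, and
between the diagnoses (rows ASD bins, columns TD bins), for each signature
selector (NSR, shape, mean, SD, skewness, kurtosis). Kolmogorov–Smirnov
two-sample matrices compare the ensembles' empirical value distributions
(NSR selector by default). P-values are reported raw — deliberately no
multiple-comparison correction, matching the analysis this package
implements; a correction hook exists but defaults off. Stars: * for
p < 0.05, ** for p < 0.01. Within-group matrices are symmetric with unit
diagonal by construction; identical samples short-circuit to p = 1 (the
all-ties case scipy rejects).

Excursion contrasts use Welch's t-test by default (group variances differ
markedly; Student's pooled-variance t available), Cohen's d with the
equal-weight pooled SD √((SD₁²+SD₂²)/2), and Glass's Δ scaled by the control
(TD) group's SD. Magnitude labels: 0.01 very small, 0.2 small, 0.5 medium,
0.8 large, 1.2 very large, 2.0 huge, applied to |d| and |Δ| with the signed
values retained.

## Preprocessing

Rational-rate resampling (per-site P/Q, defaults 1/1 — site-specific factors
are user-supplied config, not built in) uses scipy's polyphase
Kaiser-windowed FIR with delay compensation. The series mean is subtracted
before filtering and restored after, so constants are preserved exactly and
edge transients act only on the zero-mean residual; a few edge samples
remain less accurate than the interior, as with any finite filter. After
resampling, all series are truncated to a common length (minimum over the
collection by default), keeping the head of each series since the
resting-state onset is common to all subjects. No artifact cleaning is
performed anywhere: the analysis is explicitly about the uncleaned motion.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes, not
biomechanics: per-frame displacement-step magnitudes are Gamma(a*, b*)
draws pointed along a persistent random walk on the sphere, integrated into
positions with a slow sinusoidal drift, and the whole trajectory is
multiplied by a per-subject allometric factor (default range 0.8–1.25, a
plausible head-size span for ages 5–65). Rotations follow the same recipe in
degrees. Everything is determined by (seed, group label, subject index).

Two consequences are exact by construction and exploited in tests: the
allometric factor scales speeds and excursions proportionally while leaving
MMS amplitudes unchanged; and because MMS is scale-invariant, a change of
b* *alone* at fixed a* is invisible to the spike statistics. Generating
conditions therefore vary scale and shape jointly: the TD-like law is
(a* = 2.5, b* = 0.04) and the ASD-like law (a* = 1.1, b* = 0.12) — near
Exponential, roughly threefold scale — and the default 14-cell scenario
applies a mild age gradient g ∈ [0.75, 1.25] as (a*/g, b*·g), holding mean
speed a*·b* fixed while relative dispersion falls with age. Default cells:
30 subjects, 150 frames at TR = 2 s.

What passing tests on these cohorts show: the pipeline detects dispersion
contrasts of the programmed size and direction under clean iid Gamma
fluctuation structure. What they do not show: robustness to scanner-specific
noise spectra, padding differences, non-stationarity within a scan, or any
physiological realism of the waveforms — all outside the generator's scope.

## Numerical choices and degenerate inputs

- Motion files are AFNI-style `.1D` text, rotations-first by default
  (`column_order` covers the translations-first dialect); degrees on disk;
  TR comes from the cohort table because `.1D` carries no timing.
- Writing uses 17 significant digits; round-trips are lossless to ≥ 1e-10.
- Zero-variance samples, empty spike trains, too-few observations, flat-zero
  MMS windows and singular information matrices raise structured errors or
  are skipped with logged warnings — never silently defaulted.
- All analysis constants (bins, k, m, star thresholds, selectors, window and
  source flags) live in one YAML-mergeable config with full defaults.

## Problem sizes

Default runs use 14 cells × 30 subjects × 150 frames with k = 100, m = 25
ensembles; repeated-run studies (ordering stability) use the two-cell
contrast at the same sizes. These sizes give stable ensemble means (the
ASD-like cell carries the higher ensemble-mean NSR in ≥ 95% of independent
cohort draws) while a full generate + analyze cycle stays in seconds.

## Known limitations

- Wald CIs are first-order; for very small pooled samples bootstrap
  percentile CIs (available via config) are preferable.
- The KS test is applied to ensemble values whose members share subjects
  (bootstrap overlap), so its p-values are heuristic descriptors here, as
  they are in the design this mirrors.
- The generator's iid increments cannot express long-range temporal
  dependence; MMS timing structure (inter-spike intervals) is produced but
  not analyzed.
- With 25-of-30 subsampling, ensemble members are strongly overlapping;
  ensemble spread understates between-cohort variability by design.
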