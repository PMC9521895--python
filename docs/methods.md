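# Methods

## The response model and its assumptions

The unit of analysis is one participant's liking ratings of a fixed set
of music excerpts, each excerpt carrying a complexity score `x` (the
mean of expert ratings on a 1–10 scale; complexity is treated as the
inverse of predictability). The per-participant model is a quadratic in
raw complexity,

    liking_i(x) = b0_i + b1_i·x + b2_i·x²,

fitted by ordinary least squares. Raw `x` (no centering, no
standardisation) is deliberate: the classification cutoff on the
quadratic component, `b2 ≤ −0.1` (rating units per squared complexity
unit), is only meaningful if `b2` is measured on the raw scale, and
equality at the cutoff is retained (the exclusion rule reads "strictly
larger than −0.1"). The model assumes ratings are conditionally
independent across excerpts given the curve, with homoscedastic noise;
nothing in the fitting requires balanced data, and missing cells are
dropped pairwise within a participant (fits are independent across
participants, so no joint missing-data model is needed). A fit needs at
least 4 complete pairs over at least 3 distinct complexity values.

The preferred level of complexity is the apex of a concave fit,
`−b1/(2·b2)`. Apexes outside the stimulus complexity range are clipped
to the nearest endpoint — observed peak distributions pile up mass at
the lowest stimulus complexity, which an unclipped vertex cannot
produce — while the raw vertex is always retained in `peak_raw`, so
either convention can be reproduced. For non-concave fits the reported
level is the bounded maximum of the fitted quadratic over the closed
range, which calculus places at an endpoint; only the two endpoints are
evaluated. A perfectly flat fit (`b1 = b2 = 0`) has no defined
preferred level and is excluded from association analyses.

The group-level confirmation is a linear mixed model of liking on
`(x, x²)` with participant random intercepts, estimated by REML through
statsmodels; on a balanced complete design its fixed effects coincide
with pooled OLS to numerical precision, which the tests verify.

## Association testing

Preferred complexity is typically non-normal (boundary mass), so the
association statistic is Kendall's τ-b with tie correction. The
confirmatory hypothesis is directional — higher trait scores, lower
preferred complexity — hence one-sided tests against negative τ; the
one-sided p is the halved tie-corrected normal-approximation p on the
hypothesised side (and its complement on the other side).

Partial rank correlations are computed by inverting the pairwise τ-b
matrix of `(x, y, covariates)`; the precision matrix gives the partial
coefficient, which for a single covariate reduces to the classical
recursion `(τxy − τxz·τyz)/√((1−τxz²)(1−τyz²))`. No exact null
distribution for partial τ is available; the p-value reuses the τ null
variance `2(2n+5)/(9n(n−1))` with the effective sample size reduced by
the number of covariates. This is a documented approximation; its
empirical size is checked directly — over 2,000 simulated null
cohorts of 181 participants pushed through the full
fit → classify → peak → test chain, the one-sided α = .05 test rejects
at close to the nominal rate (the acceptance script recomputes this
rate on every run).

Family-wise error across the tested traits is controlled with the
Šidák correction `1 − (1 − α)^(1/m)`; a confirmatory OLS regression of
peaks on the trait battery reports the overall F, R² and adjusted R².
Cronbach's α is included for scale-reliability reporting and
cross-checked against an independent implementation in the tests.

## Power, and the exclusion-threshold trade-off

Power for a correlation test is computed from the exact sampling
distribution of the sample correlation under bivariate normality
(Hotelling's density, evaluated via the Gaussian hypergeometric
function and integrated over the rejection region of the t-test). The
Fisher-z approximation is provided but is not the default: at
n = 159, ρ = .2, one-tailed α = .05 the exact computation gives 81.5%
while Fisher-z gives 81.3%, and the exact figure is the one that
matches pre-registration practice. A Monte-Carlo route with reported
binomial SE serves as an internal cross-check.

The `b2` cutoff trades sample size against measurement error: curves
with near-zero quadratic components have wildly variable apexes. The
trade-off sweep simulates cohorts at a grid of cutoffs and records mean
retained n, RMSE of recovered peaks against latent ground truth, and
the empirical power of the one-sided Kendall test at a target
trait–peak coupling. Under the calibrated configuration (200
participants, 21% non-Wundt, rating noise SD 10) the −0.1 cutoff
retains ≈ 155–159 participants. Note that the empirical Kendall power
at a latent rank correlation of .2 falls well short of the idealized
81.5% Pearson figure: peak measurement error attenuates the observed
correlation (reliability ≈ 0.8 under these conditions) and the rank
test pays an efficiency cost. The idealized figure presumes the stated
correlation holds for the observed quantities without measurement
error.

## The synthetic-data generator

No participant-level data are distributed with studies of this design,
so every downstream stage is exercised on simulated cohorts whose
ground truth is known. The generator emulates:

* **Wundt responders** — ratings `plateau + b2·(x − peak)² + ε`,
  clipped to [0, 100]. Latent peaks are Normal(5.0, 1.8): the location
  and scale match the reported peak distribution of the motivating
  study design (mean ≈ 5, SD ≈ 1.8 on the 2.625–8.625 range). Curve
  sharpness `b2` is Normal(−1.0, 0.3) truncated at −0.2 so the class
  label is generatively unambiguous; plateaus are Uniform(60, 90);
  rating noise SD defaults to 10 (0–100 scale units).
* **Non-Wundt responders** (default 44% of the cohort, matching the
  reported prevalence) — split evenly among convex, flat and monotone
  linear response curves; none has a defined latent peak.
* **Straight-liners** — constant midpoint (50) responses with SD-1
  jitter, the behaviour targeted by the midpoint screening rule.
* **Traits** — marginals matched to the published sample demographics:
  CAPEp and AQ as scaled Beta on [1, 4] (means/SDs 1.48/0.32 and
  2.20/0.38, reproducing the floor skew), adversity as an
  overdispersed count, mood as a 5-point ordinal, training years as a
  right-skewed gamma. One trait (default CAPEp) is coupled to the
  latent peak through a Gaussian copula applied *before* the marginal
  transforms, with latent correlation `2·sin(π·ρ/6)` so that the
  Spearman rank correlation equals the requested `trait_peak_rho`
  exactly; the calibration is verified to ±0.02 over 200 replicates.

What the generator does **not** emulate: familiarity and genre effects
on liking, serial-position and block effects, within-participant drift,
non-Gaussian rating noise, and any dependence of noise on complexity.
Passing tests therefore demonstrate correctness of the estimators and
the honest behaviour of the pipeline under a clean generative model,
not robustness to the full messiness of behavioural rating data.

A note on recoverability: with the 29-point stimulus design, the
delta-method SD of the apex estimator at `b2 = −1` is ≈ 0.38 complexity
units for mid-range peaks at rating noise SD 5, but grows past 1.0 near
the range edges. With latent peaks at their default dispersion the
median absolute peak error at noise SD 5 is therefore ≈ 0.32–0.34
(recomputed by the acceptance script on every run), not arbitrarily
small: peak recovery at the edges of the stimulus range is intrinsically
hard, which is exactly the measurement-error phenomenon the exclusion
threshold exists to manage.

## Wiener entropy

Spectral flatness — geometric over arithmetic mean of a power spectrum
— is 1 for a uniform spectrum and → 0 as power concentrates in one
bin; it is invariant to amplitude scaling, and a zero bin sends it to
0. An excerpt's score cuts the waveform into non-overlapping segments
(50 ms default, 20 ms alternative; stereo is down-mixed first),
computes per-segment flatness with the DC bin excluded, and aggregates
by arithmetic mean (median and log-mean are available).

The per-segment spectrum is estimated by averaging periodograms of
consecutive rectangular 128-sample sub-frames (Bartlett/Welch
averaging). This choice is load-bearing: the bins of a *single*
periodogram of Gaussian white noise are exponentially distributed, so
its flatness converges to `exp(−γ) ≈ 0.56` no matter how long the
segment, whereas averaging K periodograms drives the flatness of a
flat-spectrum signal to `exp(ψ(K) − ln K) → 1`. Averaging gives the
measure its intended anchors — white noise ≈ 0.97, a pure tone ≈ 0.02
at 44.1 kHz with 50 ms windows — and these anchors, scale invariance,
monotonicity in the noise fraction of sine+noise mixtures, and 50 ms vs
20 ms rank agreement are all verified in the tests. The raw
single-periodogram variant remains available (`subframe=None`) for
sensitivity analysis. A Hann sub-frame window is available behind a
flag; the default is rectangular, matching plain division into
segments. Silent segments are excluded with a warning; an all-silent
waveform is a degenerate-input error.

## Numerical and design choices

* OLS via `numpy.linalg.lstsq` on the Vandermonde design; complete
  matrices use one batched solve (bit-identical to row-by-row fits).
  Agreement with the closed-form normal equations is enforced at 1e-8
  on random instances.
* Block allocation (the goal — equal block complexity means and
  variances — is stated, the algorithm is not): sort by complexity,
  deal in serpentine order, then one deterministic greedy pass of
  cross-block swaps that accepts a swap only when it strictly reduces
  the spread of block means plus variances. Sizes never differ by more
  than one; determinism over cleverness at n = 29.
* Pool deduplication keeps, per recurring complexity score, the
  excerpt with the lowest expert-rating variance; a tie on both keys
  keeps the first occurrence and logs a warning.
* Screening: a participant is flagged when more than half of their
  ratings fall in a configurable midpoint band (default 45–55). The
  thresholds for "implausible training years" and CAPEp control items
  are study-specific and exposed as configuration with no default.
* The classification cutoff, clipping behaviour, test sidedness,
  covariate set and family-wise α are all `RunConfig` fields; defaults
  reproduce the canonical analysis (−0.1, clipping on, one-sided
  negative, ACE + mood, α = .05).
* Seeds: every stochastic routine takes an explicit integer seed or
  Generator; identical configuration and seed give bit-identical
  cohorts, reports and sweep tables.

## Known limitations

* The partial-τ p-value is a normal approximation with a heuristic
  df reduction; it is validated empirically at n ≈ 180 but not exact,
  and small-sample partial tests should be interpreted cautiously.
* Peak recovery near the edges of the stimulus range is intrinsically
  imprecise (see above); the apex SD figures assume homoscedastic
  noise.
* The mixed model fits random intercepts only (no random slopes or
  curvatures), mirroring its role as a group-level confirmation rather
  than an individual-differences estimator.
* Wiener entropy is computed on unweighted linear-frequency spectra
  with no perceptual (loudness, bark-scale) weighting; it is an
  objective, not perceptual, complexity measure.
* Simulation sizes in the test-suite and acceptance script (e.g. 2,000
  null cohorts for test size, 1,000 participants for recovery, 100
  replicates for the trade-off sweep) were chosen to keep Monte-Carlo
  error well below the decision margins they feed.
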