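# Methods

## Data model and regions

Two methods measure n subjects at T+1 ordered occasions.  The analysis
operates on the consecutive-time differences (x_it, y_it), i = 1..n,
t = 1..T — the coordinates of the four-quadrant plot.  Quadrants are
defined with boundaries assigned to the "≥ 0" side (A: x ≥ 0, y ≥ 0;
B: x < 0, y < 0; C: x < 0, y ≥ 0; D: x ≥ 0, y < 0), and the exclusion zone
at time t is the closed square −a ≤ x_t ≤ a, −a ≤ y_t ≤ a.  Under the
continuous models used throughout, every boundary convention is
measure-zero; it matters only for data containing exact zeros, where the
closed-"≥ 0" rule applies deterministically.  Missing values are rejected
at ingestion: none of the estimators has a missing-data mechanism, and
silent imputation would change the object being estimated.

## Conventional concordance rate

CCR(a) = (#SA − #AEz(a)) / (nT − #Ez(a)) over the pooled points, with the
agreement-in-zone set AEz taken literally from its printed definition: the
positive cell is the closed square [0,a]², the negative cell the open
square (−a,0)².  For continuous data the asymmetry is measure-zero; for
data with points exactly on the negative cell's boundary the literal
formula can exceed 1 (such a point counts in #SA and #Ez but not #AEz).
The implementation reproduces this faithfully rather than symmetrising,
because pooling across subjects — the property under study — is only
meaningful if the index is computed exactly as practitioners do.  A
denominator of zero (all points in the zone) raises an undefined-rate
error carrying the counts.

## Binomial controls

Both controls first restrict to subjects outside the exclusion zone at
*every* time point (the same conditioning event as the model-based rate);
k_t counts the eligible subjects agreeing at time t and n_t† the eligible
subjects.  control1 pools p = Σk_t / Σn_t† and returns the binomial tail
P(X ≥ m), X ~ Bin(T, p); control2 keeps p_t = k_t/n_t† and returns the
Poisson-binomial tail of the sum of independent Bernoulli(p_t), computed
by exact polynomial convolution (for T = 2: m = 2 gives p₁p₂, m = 1 gives
p₁p₂ + p₁(1−p₂) + (1−p₁)p₂).  A per-time eligibility variant (n_t† counted
time by time) is available via `per_time=True` for sensitivity analysis;
the any-time rule is the default because it matches the conditioning of
the model-based rate, and with it n_t† is constant in t.

## Model-based concordance rate

Z = (X₁..X_T, Y₁..Y_T) ~ N(μ, Σ), with μ and Σ the sample mean and the
unbiased (n−1) sample covariance of the stacked difference vectors — all
subjects contribute, including those inside the exclusion zone, because
the zone is handled by conditioning at the probability level, not by
discarding data.  The reported index is

    P[ ∪_{t=m..T} H_t | NEz(a) ]
      = Σ_{t=m..T} P[H_t ∩ NEz(a)] / (1 − P[∪_s Ez_s(a)]).

**Numerator.**  For a fixed agreement pattern (which time points agree),
the per-time indicator of "in the required quadrant pair and outside the
exclusion zone" equals (1_Q1 + 1_Q2 − 1_E1 − 1_E2), where Q1, Q2 are the
two quadrants (A, B for agreeing times; C, D for disagreeing) and E1, E2
the exclusion-zone cells they contain.  Multiplying over the T time points
and expanding yields at most 4ᵀ signed axis-aligned rectangles in 2T
dimensions; summing the expansion over all patterns with ≥ m agreements
gives the numerator.  For T = 2 this reproduces, term by term, the
sixteen-rectangle sums of the worked two-time-point case (verified in the
test suite against an independently hand-coded expansion).

**Denominator.**  1 − P[∪ Ez_s] by inclusion–exclusion over nonempty
subsets of time points; each subset contributes one rectangle with [−a, a]
bounds on its coordinates and infinite bounds elsewhere.

**Cost and cap.**  The rectangle count grows as ~2ᵀ·4ᵀ; T is capped at 6,
far beyond the T = 2 regime the estimator is designed for but enough to
study short series exactly.

## Numerical integration

Rectangle probabilities are computed by the Genz separation-of-variables
transformation: after a Cholesky factorisation, the d-dimensional
probability becomes a smooth integral over the (d−1)-cube, evaluated with
scrambled Sobol' points.  Design choices:

* **Batching.**  All rectangles sharing a covariance (tens per rate
  evaluation) are integrated in one vectorised pass; the per-time loop runs
  over dimensions only.  This is why the full simulation sweep is feasible
  on one CPU.
* **Error estimate and determinism.**  10 independently scrambled replicate
  streams give i.i.d. means; the reported error is 3 standard errors across
  streams.  Streams are derived from a fixed internal seed and cached, so
  repeated evaluations are bit-identical.
* **Adaptivity.**  Points per stream start at 1024 and double (to 16384)
  only for rectangles still above the tolerance.  The default target is
  1e−6 absolute — an implementation choice; the estimator itself does not
  prescribe an accuracy.
* **Sweep settings.**  The simulation study uses fixed 8 × 128-point
  streams (~1e−4 absolute accuracy), orders of magnitude below the ±0.02
  resolution at which AUC values are compared.
* **Regularisation.**  If the smallest eigenvalue of the sample covariance
  falls below 1e−8 × mean diagonal (possible at the n = 10 resampling
  scale, or with degenerate data), a ridge of that magnitude is added with
  a warning.
* **Clipping.**  Signed-sum cancellation can leave tiny negative pattern
  masses; they are clipped to zero, with a warning if the clip exceeds 10×
  the integration tolerance.  A denominator below 1e−10 (model mass
  essentially confined to the zone) raises an undefined-rate error rather
  than returning a meaningless ratio.

The Monte Carlo oracle (`mc_proposed_rate`) estimates the same conditional
probability by direct sampling and classification — a ratio-of-counts
estimator with the binomial standard error computed from the conditional
sample size.  It shares no code with the rectangle path and serves as the
independent check (the test suite additionally cross-checks the integrator
against scipy's multivariate-normal CDF and closed forms: the bivariate
orthant arcsine identity and product forms).

## Simulation design

The factor grid crosses 30 mean patterns of (μ_X1, μ_X2, μ_Y1, μ_Y2)
(magnitudes 0.5/1.5 in all sign combinations), within-method covariance
ρ ∈ {0, 1/3, 2/3}, between-method covariance ρ_XY ∈ {0, 1/3}, m ∈ {1, 2},
exclusion zone a ∈ {0.5, 1.0} and n ∈ {15, 40} subjects, with unit
variances: 1440 data-generating configurations.  Counting the applicable
estimators (proposal/control1/control2 at m = 1; plus CCR at m = 2) gives
2160 + 2880 = 5040 method-cells; the reference design uses 100 replicates
(144 000 labeled datasets).  Differences are drawn directly as 4-vectors
Z ~ N(μ_Z, Σ_Z) — no raw 3-point series is simulated, as the difference
distribution is the model's object.  Ground truth: Label1 (signs of
(μ_Xt, μ_Yt) agree at both times) for m = 2, Label2 (at least one time)
for m = 1.

Seeding maps (master_seed, configuration index, replicate) through
`numpy.random.SeedSequence` spawn keys, so any single dataset can be
regenerated in isolation.  Each m level draws its own datasets, matching
the design's own counting of 1440 configurations; a `share_across_m`
switch reuses draws across m for paired comparisons.  Estimators that are
undefined on a dataset (e.g. every subject in the zone) are recorded as
rows with a flag and excluded from ROC computation with reported counts —
coercing them to 0 would bias AUC.

**Scale.**  The package's evaluation tests and the acceptance script run
the full grid at 10 replicates per configuration (~3 minutes on one CPU),
one tenth of the reference count.  At this scale overall AUCs are stable
to well under ±0.01, comfortably inside the ±0.02 comparison band.

## Evaluation

AUC uses the rank (Mann–Whitney) convention with ties counted half.  The
operating cutoff is Youden's index (max TPR − FPR) on the pooled ROC; among
tied maximizers the smallest cutoff is chosen for determinism.  The
per-pattern q diagnostic is the fraction of datasets whose rate falls on
the correct side of the pooled cutoff (rate ≥ cutoff called concordant);
cutoffs are estimated once per (m, method) from the all-pattern ROC, not
per pattern, so q measures transferability of a single operating point.

The three-observer protocol draws `subjects_per_draw` subjects with
replacement per iteration (one draw shared by all three pairs), sets a to
the 10% quantile of the pooled absolute differences of both members of the
pair at hand — per pair, per draw — and computes the four estimators at
m = 2.  The (J,R) observer pair carries the concordant label; (R,S) and
(J,S) the discordant one.  The quantile is recomputed per draw because the
zone is meant to scale with the magnitudes actually resampled; computing
it once on the full data is a fixed-zone variant the caller can emulate by
passing an explicit `a` through the lower-level API.

## Synthetic three-observer generator

A latent Gaussian construction: subject level b_i ~ N(120, 15²) plus
per-time shifts N(0, 8²) form the latent trajectory; J and R add
independent N(0, 3²) observer noise; S adds a +8 bias, couples to the
latent shifts with attenuation 0.4, and carries N(0, 12²) machine noise.
The mmHg-like scales are chosen so that consecutive-time differences of
J and R are dominated by the shared latent shifts (high trend concordance)
while S's differences are noise-dominated (low concordance).  What it
emulates: the aligned-subject structure, the concordant/discordant pair
contrast, realistic magnitudes.  What it does not: the real data's
non-normality, observer-specific biases, or its exact rates — passing
tests on this generator demonstrates that the pipeline detects a known
contrast, not that any real device agrees with its reference.

## Known limitations

* Normality of the difference vectors is assumed, consistent with the
  Bland–Altman framework; no non-normal model is provided.
* No confidence intervals or inference for any of the rates.
* The exclusion zone is a centred square only.
* T is capped at 6 by the exact expansion; larger T would need a different
  integration strategy.
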