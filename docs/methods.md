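# Methods

## Isotopic niche geometry

An individual's repeated (δ¹³C, δ¹⁵N) measurements are summarised by a
bivariate normal: sample mean μ̂ and unbiased covariance Σ̂ (denominator
n − 1). The p-level niche ellipse is the density contour
(x − μ̂)ᵀ Σ̂⁻¹ (x − μ̂) = q(p), with q(p) the χ² quantile on 2 degrees of
freedom, and area π·q(p)·√det Σ̂. For 2 df the quantile has the closed form
q(p) = −2·ln(1 − p), which the tests use as an oracle independent of the
implementation (q(0.95) = 5.991465, unit-covariance area 18.8227 ‰²).

Because √det Σ̂ is biased low in small samples, the covariance is rescaled
by (n − 1)/(n − 2) before any geometry is built ("ell95c"). The correction
is applied to the covariance rather than to the area alone so that the
boundary polygon, the union and the area all refer to the same shape; an
area-only correction would make the relative index inconsistent with the
overlay geometry it is defined by. The correction needs n ≥ 3 and the
default minimum of four samples per individual keeps it moderate (factor
≤ 1.5).

Ellipse boundaries are polygonised by mapping m uniformly spaced points on
the circle of radius √q(p) through the Cholesky factor of the (corrected)
covariance. Every vertex satisfies the defining quadratic form to floating
point; the inscribed-polygon area error is ≈ (2π²/3)/m² relative, i.e.
2.5 × 10⁻⁵ at the default m = 512, and conservative term-by-term at any m.
Group niches are exact polygon set-unions (shapely) of the member
boundaries; Monte-Carlo integration appears only as a test oracle, never in
the pipeline, so results are deterministic.

**RINI.** The relative individual niche index divides a member's corrected
ellipse area by its group's union area. Numerator and denominator both use
the *polygonised* shapes, so the ratio is internally consistent at any
vertex count: a lone member scores exactly 1, disjoint equal members score
exactly 1/2, and ΣᵢRINIᵢ ≥ 1 always. The RINI denominator contains only
members with enough samples for an ellipse; the induced underestimate of
the group niche when few members are sampled is carried into the models as
the proportion-sampled covariate rather than corrected geometrically.

Degeneracy: a covariance is treated as singular when det Σ̂ ≤ 10⁻¹²·(tr Σ̂/2)²
(points collinear to tolerance); such individuals are excluded with a
logged count rather than propagated as near-zero ellipses.

The group-level niche uses a different construction on purpose: one
corrected ellipse over the group's pooled samples (all members, including
sparsely sampled ones), with the pooled n driving the correction. The
union is the reference for *relative individual* size; the pooled ellipse
is the comparable *group-level* response.

## Inference

All models are Gaussian. Mixed models use REML for the reported estimates
and standard errors and full-ML refits for the per-term likelihood-ratio
tests (χ² = 2Δℓ against the model with that single term deleted, df = the
number of design columns the term contributes). No stepwise reduction is
performed and p-values are reported unadjusted. Nested random intercepts
(individual within group) are fitted as variance components with the
coarser factor as the grouping dimension. The optimiser falls back from
l-bfgs to derivative-free methods when a near-boundary variance component
makes the profiled system singular; such fits are flagged. Variance
explained follows the fixed/random/residual partition: marginal
r² = σ²_f/(σ²_f+σ²_r+σ²_e), conditional r² adds σ²_r to the numerator.
Non-mixed models are OLS with full-vs-reduced F-tests; a numerically
perfect fit reports an infinite F and is flagged rather than erroring.

Group size is the mean daily head count over the window spanned by the
relevant samples, with census gaps forward-filled up to 3 days (the field
visit cadence); longer gaps drop the day from the mean. The small/large
boundary sits at 17 members, with 17 itself assigned to "large" — the
observed size distribution is bimodal with a gap there, so no datum is
affected. Spearman's ρ (average ranks) uses the exact permutation null for
n ≤ 10 — relevant because the sampling-bias check runs on 9 groups — and
the t-approximation above that.

## The synthetic study

The generator emulates the field design: 9 social groups (3 small, sizes
uniform on 8–14; 6 large, 20–30), group centroids near (−18.0, 11.5) ‰
truncated to the observed vibrissa envelope, individual centroids scattered
around the group centroid (SD 0.28/0.42 ‰ per axis), 4–7 samples per focal
individual (mean 4.92, SD 1.02), sampling windows of 650 ± 104 days,
censuses every 3 days, and a Beta-distributed sampled fraction per group
(mean 0.34, emulating the observed 13–70% range) rescaled per size so the
*expected* proportion sampled is independent of group size, matching the
observed independence of the two. Additional roster members contribute 1–3
samples each: they inform the pooled group ellipse but hold no RINI.

**Calibrated specialisation signal.** The target is
E[√RINI] = 0.72 − 0.010·N for a group of N members. RINI depends on the
union geometry of *estimated* ellipses and has no closed form, so the
within-individual covariance scale is calibrated against the actual
geometry code: for a grid of group sizes (8…30), replicate groups drawn
with common random numbers make the mean √RINI a deterministic, increasing
function of the scale, which is bisected to the target; between grid sizes
log₁₀(scale) is interpolated linearly. (A global polynomial fit of the
scale curve was rejected: the curve is smooth but not polynomial in N, and
the misfit leaked into the realised slope.) The calibration depends only on
the configuration, not the run seed, and is cached, so replicate studies
share it. The intercept 0.72 is a feasibility choice: with 4–7 samples per
ellipse, estimation noise spreads member areas so the attainable mean
√RINI is capped (≈0.75 at N = 8, ≈0.59 at N = 30) no matter how strongly
ellipses overlap; 0.72 keeps the whole target line strictly inside the
attainable band. Infeasible slope/intercept pairs raise a configuration
error rather than silently clamping.

All randomness flows from one root seed through named substreams (sizes,
centroids, windows, per-group composition, weights), so adding a group
leaves existing groups' draws untouched, and the truth record emits every
latent parameter (sizes, centroids, sampled fractions, calibrated scales).

**Weights.** Weekly paired-morning weights derive from one latent daily
weight per animal-week (additive age, sex, 60-day rainfall and group-size
effects; individual, group and day-level Gaussian components; weekly head
counts wander by ±1 to give within-group size variation). The overnight
change depends negatively on the latent weight, so the observed daily
change regresses to the mean exactly as repeated field weighings do, and
the change model's first-morning-weight coefficient is a configured truth
(−0.037 g/g), not an artefact. Age slopes are expressed per year of age
(1.28 and 21.2 g·yr⁻¹). Weeks are not coupled through a random walk: the
generator is a statistical emulator of the fitted models, not a
growth model.

## Problem sizes and numerical checks

The test suite validates, among others: the analytic area against the
closed-form quantile (rel. error < 10⁻⁶); polygon unions against a
10⁶-point point-in-any-ellipse Monte-Carlo oracle (within 0.5% on twenty
5-ellipse configurations); 0.95-ellipse coverage of 50,000 fresh draws
(0.95 ± 0.005); LRT and F-test null rejection rates at 200 and 500
replicates (5% ± 3 and ± 2.5 points); and end-to-end recovery of the
configured √RINI slope over 100 replicate synthetic studies (negative sign
in ≥ 95%, mean within 2 Monte-Carlo SEs of −0.010) plus the weight-model
slopes at ≈5,000 records. The acceptance script reruns the slope-recovery
study at 60 replicates. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping a full run in
minutes.

## What passing tests do and do not show

The generator reproduces the study's *design* and the analysis's
*assumptions* — Gaussian isotopic scatter, a linear group-size effect on
E[√RINI], additive weight effects, independence of sampled proportion and
group size. Passing recovery tests therefore show the estimators are
consistent and approximately unbiased under those assumptions at realistic
sample sizes; they cannot show that real vibrissa data meet the
assumptions (temporal autocorrelation within a whisker, non-Gaussian diet
switching, dispersal between groups, and isotope–physiology interactions
are all absent from the emulator). Two further known limitations: the
calibrated within-covariance scale declines with group size, so the pooled
group ellipse inherits a weak negative size trend that real groups need
not show (the group-level model can flag a marginal effect on synthetic
data even though none is configured at the group level); and the
between/within variance split is chosen to reproduce observed isotope
envelopes, not estimated from any real population — it must not be read as
a property of the study system.
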