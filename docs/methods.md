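# Methods

## Problem setting

The package analyzes areal (region-level) prevalence data: each unit i
carries an event count and a denominator (e.g. women meeting the
recommended number of antenatal-care contacts out of women surveyed),
optional community-level covariate proportions, and a position in a
spatial neighborhood structure. The questions it answers are (a) is the
outcome spatially clustered, (b) how do covariates relate to it, linearly
or nonlinearly, and (c) how much residual variation is spatially
structured versus unstructured.

## Aggregation

Group prevalences are computed as `100 * Σ events / Σ sample`, i.e. the
sample-size-weighted mean of unit proportions. This makes the pooled
value an exact identity over any partition of the units — a property the
test suite checks — and reproduces the packaged country table's printed
aggregates exactly. Display rounding is half-away-from-zero to 2
decimals (the convention of printed survey tables); full precision is
always carried alongside.

The packaged table's sub-regional grouping follows the standard
sub-Saharan Africa sub-regions (Southern: Lesotho, Namibia, South
Africa; Central: Angola, Cameroon, Chad, DR Congo, Gabon; East and West
the remaining 12 and 14 countries). The survey-era split at 2016/2017
reflects the WHO guideline revision: surveys through 2016 measured the
≥4-contact recommendation, later surveys the ≥8-contact one.

## Spatial dependency

Neighborhood graphs: queen contiguity (boundaries sharing at least one
point), symmetrized k-nearest neighbors (default k = 5, a common areal
default; the degree after union-symmetrization is ≥ k), and distance
band (default threshold "auto" = the maximum nearest-neighbor distance,
the smallest band leaving no isolates). Weights are binary by default —
the Moran/Geary formulas are computed with general w_ij, so row
standardization is a flag, not an assumption.

Moran's I and Geary's C use the classical Cliff–Ord closed forms for the
null variance under either the normality or the randomization
assumption (default: randomization, which is consistent with the
permutation null — the test suite verifies the analytic variance
against a large permutation sample). Permutation p-values use the
add-one estimator, two-sided around the null expectation (−1/(N−1) for
I, 1 for C). We follow the standard orientation: C < 1 indicates
positive spatial autocorrelation (one occasionally sees the inequality
misprinted in applied papers).

## Response normalization

Bounded, heavily skewed proportions violate the Gaussian error
assumption, so the response is passed through the ordered-quantile
(rank inverse-normal) transform: Φ⁻¹((r − c)/(n − 2c + 1)) with c = 0.5
(Blom's c = 0.375 available), ties sharing the average-rank score. Of
the usual normalization candidates (Box–Cox, Yeo–Johnson, log, ...) this
is the only one defined for arbitrary bounded data and is deterministic;
it is therefore the single transform implemented. New values are mapped
by monotone piecewise-linear interpolation between the observed
(value, score) knots, with linear extrapolation beyond the range, so the
transform is exactly invertible on (and near) the training values and
fitted values can be reported back on the proportion scale.

## The geo-additive model

    y_i = x_i'β + Σ_j f_j(x*_ji) + u_i + v_i + ε_i

* Linear covariates are standardized (mean 0, sd 1) before fitting;
  reported coefficients are on that scale.
* Each smooth f_j lives on equal-width bins of its covariate (default
  20; empty bins are dropped so the random walk steps over occupied
  bins only) under an RW2 prior: K = D₂'D₂ penalizes second
  differences, leaving constants and linear trends unpenalized
  (rank B − 2).
* u is intrinsic CAR on the neighborhood graph: Q = D − A, improper
  along per-component constants (rank N − #components). Singleton
  components have no iCAR density and their u entries are pinned at
  zero.
* v is i.i.d. N(0, 1/τ_v); u + v is the classic BYM decomposition
  (not the reparameterized BYM2).
* Priors: Gamma(1, 5·10⁻⁵) on every precision (τ_ε, τ_u, τ_v, each
  τ_j) — the conventional weak default for latent Gaussian models —
  and N(0, 1000²) on fixed effects. All configurable.

Variant ladder for model comparison: `linear_fixed` (β only),
`additive_fixed` (+ smooths), `additive_iid` (+ v), `bym` (+ u).

## Inference: exact blocked Gibbs

Because the likelihood is Gaussian with identity link, every full
conditional is conjugate and the posterior can be sampled exactly — no
Laplace or variational approximation. Each iteration:

1. **Joint latent draw.** The i.i.d. effect v is collapsed
   analytically into the noise (v + ε ~ N(0, 1/τ_ε + 1/τ_v)), the block
   θ = (β, all f_j, u) is drawn from its exact Gaussian full
   conditional under the collapsed likelihood via dense Cholesky, and v
   is then drawn from its conditional given θ. Together this is an
   exact joint draw of (θ, v) given the precisions. Joint sampling is
   essential here: with one observation per unit, v and ε are
   likelihood-confounded, and one-at-a-time updates mix arbitrarily
   slowly along that ridge (empirically, they freeze β at far too
   narrow a spread).
2. **Recentring.** Each smooth block and each non-singleton graph
   component of u is recentred to mean zero, the subtracted means
   absorbed into the intercept. This enforces the sum-to-zero
   identifiability constraints of the improper RW2/iCAR priors; for a
   connected graph the absorption is exact. A 10⁻⁶ ridge on the
   improper prior blocks keeps the joint Cholesky well-posed along the
   directions the recentring removes.
3. **Precisions.** Conjugate Gamma draws with shape = prior shape +
   rank(structure)/2 and rate = prior rate + quadratic form/2, where
   rank is N − #components for Q and B − 2 for each K. A precision
   exceeding 10¹⁴ aborts with a diagnostic (it indicates a degenerate,
   e.g. noise-free, response).

Correctness is established two ways in the test suite: the conjugate
sub-model (fixed noise precision, no random effects) against its
closed-form Gaussian posterior, and the full joint update on a 5×5 BYM
lattice against the exact mean and covariance of the recentred posterior
constructed densely from first principles.

Defaults: 10,000 iterations, 2,000 burn-in, thinning 2. The validation
and calibration studies in the tests and the acceptance script use
shorter chains (800–1,200 iterations) and lattices of 100–225 units —
sizes at which the measured coverage, selection and calibration rates
are already stable.

### The v/ε confounding and the predictive focus

With a single Gaussian observation per unit, only the sum of the
unstructured-effect and noise variances is identified; the posterior for
the split (τ_v, τ_ε) is a ridge, and chains legitimately drift toward
either corner. Parameter inference is unaffected (β, u and the smooths
depend only on the sum), but any quantity that conditions on the
arbitrary split is not meaningful. All observation-level predictive
quantities therefore use the marginal focus: the per-observation density
is N(y_i | η_i, 1/τ_ε + 1/τ_v) with η the structural predictor
(β, smooths, u — no v). For variants without v this reduces to the
usual conditional density. Conditional-focus DIC/WAIC for unit-level
random effects is a known-degenerate choice that rewards interpolation;
with the marginal focus the model-comparison criteria depend only on
identified quantities.

## Model comparison and calibration

From the S×N pointwise log-density matrix:

* **DIC** = D̄ + pD, pD = D̄ − D(θ̄), plug-in θ̄ = posterior-mean
  structural predictor and posterior-mean predictive variance. Negative
  pD is reported as computed, never clipped.
* **WAIC** = −2(lppd − pWAIC); lppd via log-sum-exp, pWAIC the sum of
  pointwise 1/(S−1) sample variances of the log-density (the external
  reference implementation used in the tests divides by S; the oracle
  test converts exactly). Pointwise variances above 0.4 trigger a
  reliability warning.
* **CPO_i** = harmonic mean of per-draw densities (log-sum-exp
  stabilized), reported as Σ log CPO; by Jensen's inequality
  Σ log CPO ≤ lppd, which the tests assert.
* **Ranking**: DIC ascending, then WAIC ascending, then Σ log CPO
  descending; exact ties are reported explicitly, and reports computed
  on different response vectors are refused.
* **PIT_i** = posterior-predictive probability of a replicate below the
  observed value, under the same marginal focus. An importance-weighted
  leave-one-out variant (`method="loo"`) reweights draws by
  1/p(y_i | θ_s). Uniformity is tested by Kolmogorov–Smirnov.

Caveat: for variants with a structured effect u, the conditional PIT
conditions on a unit-level quantity informed by y_i and is conservative
(non-uniform) even under a correct model; calibration statements about
PIT are therefore made on the fixed-effects/smooth family, or with the
LOO variant.

## Synthetic scenarios

`make_scenario` generates lattice data from exactly the model above:
covariates Uniform(0,1); smooths from a fixed named library (sinusoid,
quadratic, changepoint, flat — each centred to mean ~0 over U(0,1) so
they are comparable to the sum-to-zero smooth estimates); u sampled from
the iCAR distribution by eigendecomposition of Q restricted to the
sum-to-zero subspace; v and ε Gaussian; observation either Gaussian
(y = η + ε) or binomial (events ~ Bin(n_trials, logistic(η))), the
latter mimicking survey-style count tables. Ground truth (β, curves,
fields, variances) is stored with every scenario.

What the generator deliberately does **not** emulate: multi-stage survey
sampling designs and their weights, irregular administrative geographies
(a lattice stands in for real boundaries), within-country heterogeneity
of province sizes, and covariate correlation structures. Passing the
recovery/calibration studies therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness
to survey-design artifacts.

Default study conditions for the simulation studies: 15×15 (recovery)
or 10×10/12×12 (selection, calibration) lattices, β = (0.5, 1.0), one
sinusoid smooth, τ_u = 1, τ_v = 10, σ_ε = 0.5 — a regime where the
structured field, the unstructured noise and the covariate effects are
all of comparable, realistic magnitude.

## Numerical notes

* Weight matrices are dense; the intended scale (tens to ~500 areal
  units) makes dense Cholesky factorizations trivial, and no sparse
  path is provided.
* Equal-width binning of smooth covariates keeps incidence matrices
  one-hot; bin midpoints are reported on the original covariate scale.
* k-nearest ties are broken by node label order, making graph
  construction deterministic.
* All stochastic entry points take explicit seeds; fixed seeds make
  scenario generation bit-reproducible and CLI outputs hash-identical.

## Known limitations

* Gaussian likelihood only (after normalization); binomial/Poisson
  spatial GLMMs are out of scope.
* The rank-normal transform is fitted to the analyzed response itself;
  uncertainty in the transform is not propagated.
* The iCAR/BYM variance split (structured vs unstructured) is weakly
  identified in general, and not identified at all between v and ε —
  interpret τ_v and τ_ε only through their sum.
* Leave-one-out quantities (CPO, LOO-PIT) use harmonic-mean-style
  importance weights, which are noisy when the posterior is sharply
  concentrated; flagged observations should be read with care.
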