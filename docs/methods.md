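# Methods

## Setting and model

All inference in this package is design-based: the finite population
`F = {(x_i, y_i, z_i) : i = 1..N}` is fixed, and every probability statement
refers to the sampling mechanism only.  The target is the population mean
`ȳ₀ = N⁻¹ Σ y_i` (or, more generally, a parameter `ξ₀` solving a
population-averaged estimating equation).  A two-phase design observes the
p-vector `x` on a phase-I sample `A` and `(x, y)` on a phase-II subsample
`B ⊆ A`; the per-unit weight base is the cumulative product of conditional
inclusion probabilities `π*_i = π_{I,i} · π_{II,i|A}` (extended
multiplicatively to further phases).

## Rejective designs

A rejective phase redraws the candidate sample until the Mahalanobis
balance statistic `Q = d ᵀ V⁻¹ d` of the auxiliary mean difference
`d = x̄_later − x̄_earlier` falls strictly below `γ²`.  Two variance modes
are implemented:

* **srs_closed_form** — equal-probability SRS phases; `V = (1/n_II − 1/n_I)
  V_xx,I` with `V_xx,I` the phase-I sample covariance (divisor `n_I − 1`),
  and unweighted phase means.
* **general** — arbitrary phase designs; Hájek phase means, and `V` is the
  conditional design covariance of the later-phase Hájek mean computed from
  second-order inclusion probabilities.  The pair probabilities have closed
  forms per design kind (SRS, Poisson independence, stratified products),
  and the double sum collapses to a linear-cost expression because the pair
  deviation `π_ij − π_i π_j` takes only two values within a design stratum.

The accepted sample is distributed as the candidate design conditioned on
`{Q < γ²}` (strict inequality).  The acceptance loop consumes one seeded
generator sequentially, so the number of candidate draws is reproducible;
an empty Poisson candidate counts as a rejected draw (estimators are
undefined on empty samples and the event is negligible at design sizes).
The loop fails loudly after `max_draws` (default 10⁶) with the running
acceptance rate in the message.  A numerically singular balance metric
(condition number above 10¹²) is a hard error — a silent pseudo-inverse
would change the law of Q.

Without rejection `Q → χ²_p`, so a target acceptance rate `a` corresponds
to `γ² = F⁻¹_{χ²_p}(a)`; the recommended default is `a = 0.001`.  Note the
distinction between the *threshold* and the *rate*: the benchmark threshold
`γ² = 0.01` corresponds to an acceptance rate of about `P(χ²₁ ≤ 0.01) ≈ 0.08`
(≈ 12.6 candidate draws per accepted sample).

## Limit law and variances

The √n_II-scaled error of the phase-II (Hájek/double-expansion) mean under
a rejective design converges to `a·L_{p,γ²} + b·Z₁ + c·Z₂` with independent
standard normal `Z₁, Z₂` and

```
L_{p,γ²} = χ_{p,γ} · S · Γ_p^{1/2},
v_{p,γ²} = var(L) = P(χ²_{p+2} ≤ γ²) / P(χ²_p ≤ γ²) ≤ 1 ,
```

where `χ_{p,γ} ~ χ_p | (χ²_p ≤ γ²)`, `S` is a random sign, and
`Γ_p ~ Beta(1/2, (p−1)/2)` makes `S·Γ_p^{1/2}` the first coordinate of a
uniform point on the unit sphere.  For `p = 1` the Beta is degenerate at 1
(the 0-sphere is `{−1, +1}`), so `L_{1,γ²}` is a standard normal truncated
to `(−γ, γ)`; the implementation states this case explicitly.  Sampling
uses inverse-CDF truncation (a uniform restricted to
`[0, F_{χ²_p}(γ²)]` pushed through the χ² quantile function), which is
exact for every `γ²` including ∞.

Under two-phase SRS the mixture coefficients involve the sampling fractions
`f_II,I = n_II/n_I`, `f_I,0 = n_I/N`, the population variance `V_yy` and
the squared correlation `R²`; the closed-form asymptotic variance of the
mean and the regression estimator, and the percentage variance reduction
`100·(1−f_II,I)/(1−f_II,I f_I,0)·(1−v_{p,γ²})·R²`, are provided as direct
formulas.  The regression estimator's limit is normal and does not depend
on `γ²` — rejection buys the *plain* estimator the regression estimator's
efficiency.

Mixture quantiles have no convenient closed form and are computed by Monte
Carlo: 2×10⁶ draws by default with a fixed documented seed, linear
interpolation between order statistics (this affects only the last digit at
that draw count).  Replication studies need quantiles for thousands of
plug-in coefficient triples, so a `MixtureBasis` caches one set of
`(L, Z₁, Z₂)` draws and combines them per triple (common random numbers);
the basis default is 2×10⁵ draws, which puts the Monte Carlo error of a
97.5% quantile near 0.4% — negligible against the replicate-level noise it
feeds into.

## Variance estimation and intervals

Two routes, dispatched by design kind with no silent fallback:

* **SRS route** — `V̂_uv` with divisor `n_II − 1`; residual variance
  `V̂_ee` with divisor `n_II − p − 1` (degrees of freedom spent estimating
  the slope); `V̂_yy = β̂ᵀV̂_xxβ̂ + V̂_ee`; `R̂²` from the raw cross
  moments, clipped to `[0, 1 − 10⁻¹⁰]` so the near-degenerate normal
  component of the plug-in mixture remains well defined.
* **General route** — three components of `n_II · var`: `V̂₁ = n_II β̂ᵀ
  V_xx,I β̂` (the balanced term, multiplied by `v_{p,γ²}` under rejection),
  a phase-II residual double sum `V̂₂`, and a phase-I double sum `V̂₃`,
  each built from conditional pair probabilities.  Estimating a phase-I (or
  population) double sum from the observed phase-II sample lifts each pair
  term by its selection probability (`1/π_{II,ij|A}`, and additionally
  `1/π_{I,ij}` for the phase-I term); the Sen–Yates–Grundy pairwise-difference
  forms — nonnegative by construction for fixed-size designs, and the
  default for them — carry the same lifting factors.  SYG forms refuse
  Poisson phases (no fixed size).

Mean-estimator intervals take quantiles `ν_α` of the mixture law with
plug-in coefficients (R̂² on the SRS route, `√V̂₁, √V̂₂, √V̂₃` on the
general route): `(point − ν_{1−α/2}/√n_II, point − ν_{α/2}/√n_II)`.
Regression-estimator intervals are normal-based.  The degrees-of-freedom
correction in `V̂_ee` is applied on both routes — the estimated-slope bias
argument is the same.

## Estimating equations

Built-in estimating functions: mean (`y − ξ`), proportion (`I(y<c) − ξ`),
mean/variance pair, and quantile (`I(y≤ξ) − τ`).  Smooth kinds solve the
π*-weighted equation by closed-form weighted moments (or bracketed Brent
iteration to 10⁻¹⁰ for user-supplied scalar functions); the quantile kind
uses the exact generalized inverse `inf{ξ : s̄_II(ξ) ≥ 0}` on the sorted
support — no iteration, and the step-function bracketing
`s̄(ξ−) < 0 ≤ s̄(ξ)` holds exactly.

The variance keeps the three-component structure with `s_i(ξ̄)` in place of
`y_i` and the π*-weighted projection coefficient `B̂` of `s` on `x` in
place of `β̂` (population-level sums are unobservable under two-phase
designs, so the plug-in uses phase-II weighted sums).  The sandwich is the
inverse-Jacobian form `Γ̂⁻ᵀ (V̂₁ˢ v_{p,γ²} + V̂₂ˢ + V̂₃ˢ) Γ̂⁻¹ / n_II`,
which coincides with the direct form for the |Γ| = 1 built-ins and gives
the classical `τ(1−τ)/(n f²)` Bahadur scaling for quantiles.  For the
quantile kind the Jacobian is the outcome density at the quantile,
estimated by a π*-weighted Gaussian kernel with Silverman's rule-of-thumb
bandwidth `0.9 · min(sd, IQR/1.34) · n_eff^{−1/5}` (Kish effective sample
size; the robust scale matters for skewed outcomes — the SD-only factor
oversmooths and makes the interval visibly conservative).  This choice is
isolated behind `derivative_mode` and is the open design decision of the
module.

## Three-phase designs

Phase I is an SRS; phase II is Poisson sampling proportional to `x` with
rejection on x-balance (threshold `γ₁²`, general variance mode); the
second-tier auxiliaries `z` observed on phase II are residualized on `x`
(block Gram–Schmidt, π*-weighted, so the residual block `a` has weighted
mean zero and is weighted-orthogonal to `x` exactly); phase III is Poisson
sampling proportional to the row sums of `z` with rejection on the balance
of `a` (threshold `γ₂²`).  Balancing `a` alone at phase III is the default
— `x` is already balanced at phase II — with joint `(x, a)` balancing
available by flag.  Point estimators are the triple-expansion Hájek mean
and a regression estimator adjusting by both blocks from a single
π***-weighted fit.  Size measures are shifted positive when a z-row-sum is
nonpositive and flattened (a constant added) just enough that every pps
inclusion probability stays below 1; both adjustments are recorded in the
draw metadata, never applied silently.  Analytic three-phase variance
estimators are not provided; three-phase uncertainty is Monte Carlo
calibrated via the harness, and outputs say so.

## Synthetic populations

The two-phase benchmark population is `x_i ~ √0.5·(χ²₁ − 1)` (mean 0,
variance 1, right-skewed), `y_i = 1 + βx_i + e_i`, `e_i ~ N(0,1)`, with
`β ∈ {0.5, 1, 2}` giving `R² = β²/(β²+1) ∈ {0.2, 0.5, 0.8}`; the benchmark
design is `N = 100 000, n_I = 5000, n_II = 200`.  The three-phase analogue
uses a shifted-gamma `x` (strictly positive, as pps sampling requires, and
right-skewed like real size measures), a 3-vector `z` loaded on `x`, and
`y` linear in both; it is a structural stand-in, not a replication of any
real survey file — the joint distribution of a real application's
variables is not reproduced, so three-phase results are ordering and
consistency statements, not numeric matches.  What the generators do not
emulate: measurement error, nonresponse, clustering, stratified frames
with many strata, and domain structure; passing tests therefore demonstrate
design properties (unbiasedness, variance reduction, coverage) under clean
conditions, not robustness to those complications.

## Reproducibility and numerical choices

Every stochastic operation takes one integer seed (or a numpy
`SeedSequence`) and documents its stream consumption order; the rejection
loop's draw count is part of the reproducible state.  The Monte Carlo
harness fixes one population per scenario and matches the per-replicate
phase-I sample and phase-II candidate stream across rejective and
non-rejective arms, so the first rejective candidate *is* the plain draw
and variance-reduction comparisons are paired.  Matrix solves guard on
condition number 10¹² (balance metrics, regression cross-products,
Jacobians) and raise named errors rather than regularizing.  Replication
summaries use 1000 replicates at the benchmark sizes (about half a minute
per scenario on one core); module-level tests use scaled-down designs
(populations of 3 000–20 000, phase sizes in the hundreds) chosen so that
5-standard-error Monte Carlo bands are decisive.

## Known limitations

* Fixed-size unequal-probability (conditional Poisson) phases, cluster
  designs and the cube method are out of scope.
* The REE is implemented for stratified second phases as defined; no
  calibration/raking weighting.
* Simplified variance estimators that avoid phase-II pair probabilities are
  not implemented; the pairwise double sums require them.
* Three-phase confidence intervals are Monte Carlo calibrated only.
* Regression weights (and their negativity diagnostic) are defined for the
  equal-probability SRS case only, where their weighted-average identity
  holds.
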