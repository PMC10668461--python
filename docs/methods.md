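# Methods

## The model

`vaxdyn` treats a household's stated vaccine intent as a two-state Markov
chain observed through a panel survey.  In round *t* household *i* answers
"yes" (y_it = 1) or "no" (y_it = 0) to whether it would take a free
vaccine.  Transition probabilities depend on household and local-context
covariates:

    Pr(y_it = 1) = logistic( x_i θ0 + y_{i,t-1} · x_i γ + α_k(i) + τ_t )

where x_i = (1, age, sex, urban, violence count, electoral
competitiveness, road density) on raw scales, θ0 are the effects for
households that said "no" in the previous round, θ1 = θ0 + γ the effects
after a previous "yes", α_k is a fixed effect of the administrative unit
containing the household, and τ_t a fixed effect of the survey round.
Survey weights enter as pseudo-likelihood multipliers (normalized to mean
one).  From the fitted coefficients one forms, at any covariate profile,
the 2×2 row-stochastic matrix

    P = [[1 − p01, p01], [1 − p11, p11]],
    p01 = logistic(x θ0 + α + τ),   p11 = logistic(x θ1 + α + τ),

whose stationary distribution π = (π_no, π_yes), with the two-state closed
form π_yes = p01 / (p01 + p10), describes the long-run split between
hesitancy and acceptance at that profile.  Counterfactual scenarios move a
single target covariate to its survey-weighted 1st or 99th percentile
(everything else at the weighted median, α at the median estimated unit
effect, τ at the mean estimated round effect) and compare stationary
yes-probabilities; differences are reported in percentage points.

## Estimation

The penalized weighted Bernoulli likelihood is maximized by Newton–Raphson
with step halving (so the penalized log-likelihood is non-decreasing along
the iteration path — an invariant the tests check).  Convergence requires a
maximum absolute score below 1e-8 or a parameter step below 1e-10; a
plateau backstop (negligible likelihood change with score already below
1e-5) terminates quasi-separated crawls that would otherwise inch toward an
infinite coefficient forever.  Perfectly separated samples raise a
convergence error carrying diagnostics; converged fits with standardized
coefficients beyond ±15 emit a warning naming the columns.

Continuous covariates are z-scored internally and every reported quantity
is back-transformed to raw scales (an exact linear map, applied to the
covariance as well), so reported coefficients are directly comparable to
generating values or natural units.

A ridge penalty (default 1e-6) applies to the unit and round fixed-effect
coefficients only, so θ0 and γ stay maximum-likelihood interpretable while
units or rounds with all-identical outcomes remain estimable.

### Identification of unit-level covariate effects

With unit fixed effects in the model, the main effects of covariates that
are constant within units (violence count, competitiveness, road density)
are exactly collinear with the unit-effect vector.  The ridge resolves the
indeterminacy by a minimum-norm normalization: the fitted unit effects are
orthogonal to the span of the unit-level covariates, and the covariate
coefficients absorb the rest.  Two consequences shape the package:

* The synthetic generator draws its true unit effects inside that
  identified parameterization — reference unit pinned at 0, the remainder
  residualized against [1, unit-level covariates] and rescaled to the
  configured standard deviation.  Outside it, a "true coefficient" for a
  unit-level covariate is not the estimand of any estimator and recovery
  would be ill-posed.
* These coefficients are effectively estimated from a between-unit
  regression with as many observations as there are units.  At the
  reference scale (25 units) they are noisy, and the sandwich covariance
  cannot see the normalization component of that noise.  The reported
  covariance therefore adds, for directions in the exact null space of the
  design, the penalty-scale variance 1/λ — an honest statement that the
  data alone do not pin those directions down.  The same convention floors
  near-zero Hessian eigenvalues during fitting, which also covers the
  degenerate case where the unit-level covariates span the whole unit
  space (very few units).

Round effects are identified relative to the earliest round that enters
estimation; since round 1 contributes no lagged observation, that reference
is round 2.

### Cluster-robust covariance

Inference follows the two-way clustering of the study design: sandwich
estimators clustered by administrative unit and by survey round are
combined by inclusion–exclusion (V_unit + V_round − V_unit×round), each
with a CR1 factor G/(G−1); negative eigenvalues of the combined matrix are
truncated to zero with a logged warning.  On full-rank designs with
singleton clusters this collapses to the heteroskedasticity-robust
sandwich, and to the one-way estimator when one dimension's partition
coincides with the other — both verified against independently coded
oracles.

### Stationary distribution

The stationary distribution is the left eigenvector of P for eigenvalue 1.
Because a row-stochastic matrix has that eigenvalue exactly, the
eigenvector is computed as the SVD null space of Pᵀ − I assembled from the
off-diagonal entries (avoiding the cancellation in (1 − p) − 1); this keeps
the eigen route within 1e-12 of the closed form even for chains with a
tiny spectral gap, which a general eigensolver does not guarantee.  A chain
with an off-diagonal exactly 0 is absorbing: the exact degenerate
distribution is returned with a flag; the identity chain raises.

### Cluster bootstrap

Scenario uncertainty comes from resampling administrative units with
replacement (the level at which both the fixed effects and the clustered
covariance operate), refitting the model per resample — warm-started from
the full-sample estimates — and recomputing each scenario's stationary
yes-probability with the resample's own median unit effect and mean round
effect.  Intervals are nearest-rank 2.5/97.5 order statistics of the B
replicates (default B = 1000); failed refits are redrawn, with more than
10% failures an error.  High-minus-low differences carry their own
percentile intervals in percentage points.

## The synthetic world

The generator emulates the study's data constellation on a planar
Cartesian grid measured in km (coordinates are labelled lon/lat for schema
compatibility; real geographic inputs are treated planarly — a documented
approximation):

* **Geography** — a rows×cols grid of square level-2 units (default 5×5 of
  10 km), ids `U001…`.
* **Households** — default 2,000, clustered in 3 named villages per unit
  (the gazetteer maps village name → interior point); age ~ uniform 18–90,
  sex ~ Bernoulli(0.5), urban ~ Bernoulli(0.35); weights i.i.d. lognormal
  (σ = 0.5) normalized to mean exactly 1 — a stand-in for the real survey's
  undocumented weight construction.
* **Violence** — per-unit Poisson counts with intensity uniform on
  (0, 150) events over the 20-year window before the first survey date
  (2021-06-01), points uniform in the unit, dates uniform in the window.
* **Elections** — a near-square constituency grid whose interior borders
  are shifted by 0.37 units so they never coincide with unit borders; each
  constituency holds a two-candidate race with competitiveness
  (1 − winning margin) uniform on (0.05, 0.95).
* **Roads** — 40 random 2–4-vertex polylines spanning the domain, classes
  primary/secondary/other with probabilities 0.4/0.3/0.3; only
  primary + secondary count toward density.
* **Panel** — 5 rounds; round 1 drawn from each household's stationary
  distribution (so the chain starts at equilibrium; a Bernoulli(0.5) start
  is available); later rounds from the transition model.  The generating
  covariates are the *realized* harmonized values (actual event counts,
  interpolated competitiveness, clipped road density), recorded in
  `truth.json`, so re-harmonizing the written files reproduces them
  exactly.
* **Attrition** — missing completely at random: each household leaves
  permanently after any round with probability 0.05, making presence
  monotone.  MCAR matches the study's finding that dropouts were
  observably similar to stayers; informative attrition is out of scope.

Default generating coefficients (raw scales) are chosen so a median
household behaves like the headline two-state matrix — roughly 0.35
no→yes and 0.96 yes→yes — with violence negative in both lag states
(θ0 = (−0.33, −0.010, 0.10, 0.20, −0.006, 0.80, 1.20),
γ = (4.11, −0.004, 0, 0.10, −0.006, 0.40, 0.60) over
(intercept, age, sex, urban, violence, competitiveness, road density)),
unit-effect sd 0.3, round effects (0, 0, −0.10, 0.05, −0.05).

What the generator does **not** emulate: informative attrition, spatially
correlated household covariates, measurement error in geocoding, raster
covariates (night lights, terrain — representable only as pass-through
numeric columns), and real sampling-weight calibration.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under a correctly specified model, not robustness to those real-data
features.

## Spatial harmonization choices

* Geocoding is exact matching after case-folding and whitespace
  normalization; unmatched names are returned, never dropped.
* Point-in-polygon uses covering semantics; a boundary point goes to the
  lexicographically smallest unit id (deterministic, order-independent).
* The violence window is half-open: [first survey − 20 years, first
  survey).
* Competitiveness transfers to units by overlap-area weighting, the
  standard areal interpolation for an intensive variable; a unit with zero
  constituency overlap is reported missing and the context build fails
  loudly rather than imputing.
* Road density sums primary and secondary clipped lengths per unit divided
  by unit area (km/km²); class "other" is excluded.
* The estimation lag requires consecutive observed rounds; household-rounds
  without an immediately preceding observation are excluded and counted.

## Problem sizes used in the test suite

Parameter-recovery calibration runs 100 replicates at the reference scale
(2,000 households, 5 rounds, 25 units) and checks that 95% Wald intervals
(two-way clustered, with the null-space variance term) cover every non-FE
generating coefficient in at least 90 replicates.  Bootstrap calibration
runs 100 replicates of scaled-down worlds (36 units, 1,200 households, 3
rounds) at B = 200, checking coverage of the analytic high-violence
stationary probability; the scaled sizes keep the study's structure (many
units, few rounds) while making 20,000 model refits cheap.  Geometric
operations are checked on 100 random small instances each against a pure
Python winding-number oracle, an exhaustive event recount, a 0.1 km
rasterized overlap oracle, and an 8,000-piece polyline subdivision oracle.

## Known limitations

* Unit-level covariate main effects are weakly identified at realistic
  unit counts; their intervals are wide by design (see above), and
  scenario estimates targeting them inherit that width.  This mirrors a
  genuine limitation of the underlying design (unit fixed effects plus
  unit-level covariates), not an implementation artifact.
* The two-way clustered covariance is noisy when one dimension has few
  clusters (e.g. 4 estimation rounds); the inclusion–exclusion combination
  can require negative-eigenvalue truncation.
* Planar treatment of geographic coordinates; no geodesic areas or
  lengths.
* Percentile (not BCa) bootstrap intervals; nearest-rank order statistics.
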