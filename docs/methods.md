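# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Proximity construction

**Geodesic distance** is great-circle (haversine) distance on a sphere of
mean radius 6371.0088 km. An ellipsoidal geodesic would differ by < 0.5%,
which the min–max scaling of the log-distance matrix absorbs; the spherical
closed form is dependency-free and exactly testable. Geographic proximity is
`1 − minmax(log d)` computed over off-diagonal pairs only, with the diagonal
fixed at 1: the closest pair of capitals scores 1, the farthest 0. Duplicate
capitals (zero distance) are an error, as is an all-equal distance
configuration (degenerate scaling). Ties elsewhere are allowed.

**Language proximity** `s = (n_r − n_i)/n_r` counts *edges*: `n_r` is the
deepest root-to-tip path in the taxonomy, `n_i` the deepest path from the
pair's most recent common ancestor down to any tip below it. Counting nodes
inclusive of endpoints would add 1 to both counts and rescale all
proximities monotonically without changing any qualitative result; the edge
convention makes `s = 1` for identical languages and `s = 0` exactly when
the MRCA is the root. The implementation assigns each internal node's
cross-subtree tip pairs in one postorder pass and is verified exactly
against a brute-force root-path oracle on random trees.

**Speaker weighting** drops languages below 1‰ of a nation's population and
does **not** renormalise the remaining shares: totals below 1 shrink the
weighted proximity, which is the literal double-sum formula. A
`renormalize=True` switch restores sum-to-one weighting for sensitivity
analyses. The raw linguistic diagonal w_ll can be below 1 for multilingual
nations; it is recorded for inspection, and the stored diagonal is forced to
1 because the matrix's downstream role is a correlation structure.

**Positive-definiteness repair** (`as_correlation`) floors eigenvalues at
1e-6 (with 10% headroom, because the subsequent unit-diagonal rescale shaves
the smallest eigenvalue) and alternates flooring with rescaling until the
floor holds. Rank deficiency is common and expected: any two nations sharing
one majority language produce an exactly duplicated row. The Frobenius
distance moved is reported, and a repair that moves any entry by more than
0.05 warns (or errors in strict mode).

## Generative model

The simulator draws α<sub>y</sub> ∼ MVN(0, λΣ) — the vector-normal notation
"Normal(0, √λ·Σ)" is read as a standard deviation √λ applied to a
unit-diagonal correlation matrix Σ, i.e. covariance λΣ. This reading is
forced by the design's own interpretation of λ ∈ {0.2, 0.5, 0.8} as "20/50/
80% of variance explained": residual variance is 1 − λ, so total marginal
variance must be exactly 1, which holds only for covariance λΣ. The
residual pair per nation is bivariate normal with variances (1−λ), (1−ρ) and
covariance r√((1−λ)(1−ρ)); the marginal corr(y, x) is therefore
r√((1−λ)(1−ρ)), which the tests check in closed form.

Replicate seeds are derived counter-style from (seed, cell index, replicate
index) via `numpy.random.SeedSequence` spawn keys, so any grid cell is
reproducible in isolation and adding estimators or cells never perturbs
another cell's data. The default grid covers one Σ source (3 × 3 strengths
× 4 effect sizes × 100 replicates = 3600 datasets); passing both sources
runs the spatial and cultural studies back to back.

## Estimators

All estimators standardize y and x (z-scores) and decide "effect present"
by a two-tailed 95% interval excluding zero.

* **OLS family** (naive, latitude, longitude, continent FE, family FE,
  radius mean): ordinary least squares with t intervals. Fixed effects are
  dummy-coded with the alphabetically first level as reference (slope
  inference is unaffected by the reference choice); a level with a single
  member is retained with a warning — it absorbs its own observation. The
  2000-km control is the mean of x over *other* nations within 2000 km,
  falling back to the global mean (flagged) for isolated nations.
* **Conley standard errors**: OLS point estimate with a spatial-HAC sandwich
  using a Bartlett kernel (linear decay to zero at the cutoff). Cutoff grid:
  500–5000 km in 500-km steps for capital coordinates; deciles of the
  pairwise distance distribution for ancestry-surrogate coordinates (rows
  without ancestry coordinates are dropped, mirroring partial coverage).
  Following the max-SE selection rule, the reported fit carries the cutoff
  that maximizes the slope standard error. A cutoff below the minimum
  pairwise distance reduces the sandwich to HC0, which the tests assert to
  1e-8.
* **Gaussian-process regression**: y = β₀ + β₁x + f(coords) + e with an
  exponentiated-quadratic kernel on per-axis min–max-scaled (lon, lat). The
  overall noise scale is profiled analytically; the signal-to-noise ratio
  and length-scale maximize the concentrated marginal likelihood over a
  5 × 5 grid of log-scale starts with Nelder-Mead refinement from the two
  best (objective tolerance 1e-8). β₁ and its normal-based interval come
  from GLS at the optimum. Great-circle kernels are out of scope; the
  original approach also worked on scaled planar coordinates.
* **Linguistic random intercepts**: V = σ²(hL + (1−h)I) with
  h = σ²ᵤ/(σ²ᵤ+σ²ₑ) profiled on a one-time eigendecomposition of L (34-point
  grid on [0, 0.99] refined by bounded scalar minimization). With L = I the
  likelihood is flat in h; the fit proceeds at h = 0 — identical to OLS —
  and flags non-identifiability. A `fix_h` argument pins h for exact
  comparison against the closed-form GLS estimator.
* **GP + linguistic intercepts**: V = σ²(a_g K_ℓ + a_u L + I), three
  log-scale hyperparameters, 27-point grid plus refinement, GLS slope at the
  optimum.

The original study fitted the last three models in a Bayesian framework with
priors chosen by prior predictive simulation (unpublished). This package
replaces them with maximum/profile likelihood and Wald intervals — the one
systematic deviation — because the decision rule (95% interval excludes
zero) is preserved and the fits are exactly reproducible without unknown
priors. Calibration at the null is unaffected (the tests verify ~5% false
positives on independent data); under strong autocorrelation ML point
estimation tends to shrink variance components slightly less conservatively
than posterior means, so false-positive rates of the flexible models may
differ from their Bayesian counterparts by a few percentage points.

## Signal model

For a trait observed once or repeatedly per nation:
value<sub>it</sub> = μ + g_i + l_i + u_i + e<sub>it</sub>, with g ∼
MVN(0, σ²_g G), l ∼ MVN(0, σ²_l L), u iid per nation and e iid per
observation. The iid nation term is dropped for cross-sectional data (it
would be confounded with e). Estimation is REML with multi-start
Nelder-Mead on log-variances; the trait is standardized internally (and
rounded at 1e-12, far below statistical precision) so the fit is exactly
invariant to rescaling, and components are reported back on the trait scale.

The *signal* proportions divide by **nation-level** variance: for
longitudinal data the denominator is σ²_g + σ²_l + σ²_u (the observation
residual is within-nation noise); for cross-sectional data the residual *is*
nation-level and enters the denominator. Intervals are profile-likelihood:
each component's log-variance is profiled with nuisance components
re-optimized, bounds located by bisection at the χ²₁(0.95)/2 deficit, and
endpoints mapped to the proportion scale at the profile optima. Evidence
that a component is nonzero uses 2Δ log-likelihood against the boundary
mixture 0.5·χ²₀ + 0.5·χ²₁ (the original study reported Bayes factors, whose
priors are not available; the LRT is the documented substitute).
Identifiability guards reject a constant trait, coinciding G and L, and the
doubly-iid case G = L = I.

## Synthetic worlds

The generator emulates the structural features the analysis relies on:

* **Coordinates**: six continental caps at rough real-continent anchor
  points, populated by von-Mises–Fisher sampling (concentration
  `clustering`, default 12; Europe three times tighter, matching its denser
  capital field), with 75% of capitals drawn from denser sub-regional
  clusters (concentration multiplied by `subcluster_factor`, default 12,
  ~500-km scatter) — emulating dense neighbourhoods like Europe, the
  Caribbean or West Africa. Capitals are jittered to keep every pair at
  least 5 km apart so the log-distance scaling stays finite.
* **Taxonomy**: a root with 18 family clades (real family names), each a
  random Yule-like topology with 3–40 tips. Cross-family proximity is
  exactly 0; within-family proximity is positive.
* **Languages**: families are homed on continents; 85% of "local" majority
  languages come from a family homed on the nation's continent. A handful
  of widely spread languages — four from the largest family and one from
  another, echoing the colonial spread of Spanish/English/French/Portuguese
  and Arabic — are the majority language with continent-specific
  probabilities (overall ≈ 30% of nations, `spread_prob`). This produces
  the large identical-language blocks that drive real-world cultural
  non-independence. 70% of nations are monolingual; the rest mix two or
  three languages with the majority share ≥ 0.55.
* **Ancestry surrogates**: a 2-D classical-scaling embedding of linguistic
  distance (1 − s) among majority languages plus 5% noise, present for
  ⌈coverage·n⌉ nations (default 177/236) — a plausible stand-in for
  genetic-distance coordinates, which in real data cover only a subset of
  nations.

What the generator does **not** emulate: real capital geography (only its
clustering statistics), colonial/trade/migration networks, latitudinal
climate gradients, and the exact spectral weight of the real proximity
matrices. Passing tests therefore demonstrate the estimators' behaviour
under the modelled dependence structure, not the exact false-positive
magnitudes any particular real-world matrix would produce: the qualitative
ordering (naive worst; fixed effects partial; Conley and coordinate controls
insufficient; structure-matched random effects and GPs best) is stable
across generated worlds, while absolute spatial false-positive rates are
sensitive to how concentrated the geographic correlation structure is.

## Problem sizes

The test suite runs worlds of 30–236 nations, 100-replicate grids for the
ordering checks, a 500-replicate null calibration, and 25-replicate
signal-recovery batches at 200 nations; `scripts/acceptance.py` uses the
full 236-nation default world at the study's 100 replicates per cell. These
sizes were chosen so the whole pipeline runs comfortably on a single CPU
while keeping Monte-Carlo noise near the ±5–10 percentage-point level the
comparisons require.

## Known limitations

* Conley inference uses the plain HAC sandwich without small-sample
  degrees-of-freedom corrections; with n ≥ 100 units the difference is
  negligible.
* GP hyperparameters at small n (< ~50) can trade amplitude against
  length-scale (a near-zero length-scale mimics iid noise); the slope is
  insensitive to this ridge, but amplitude diagnostics should not be
  over-interpreted at small n.
* Profile-likelihood intervals for signal proportions are computed on the
  variance scale and mapped through the profile optimum; they are
  approximate for strongly correlated components.
* The review-proportion module computes article-level proportions and
  bootstrap intervals for a coded review table; the analysis-level
  multilevel logistic models of review trends are out of scope.
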