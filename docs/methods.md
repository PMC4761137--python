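# Methods

`riskmap` implements two complementary ways of mapping small-area disease
risk from registry case records, and a synthetic-registry generator that
makes both testable end to end against known ground truth.

## The setting

A provincial cancer registry records diagnoses (site, sex, five-year age
band, calendar year) with a residential geocode whose precision varies: most
recent cases carry an exact civic-address point, older cases often carry
only a postal code — which localizes the case to the set of fine census
regions containing at least one address with that postal code — or only an
administrative (census-division) region.  Census populations by sex and age
band are available at fine census geographies whose boundaries change across
census years; populations are treated as uniform within the inhabited
portion of each fine region.  Stable "community" units (default 311)
aggregate the fine regions for areal analysis.

All geometry lives in one planar metric CRS; bandwidths are quoted in km
(space) and years (time).  Every study year is assigned to the census whose
±2-year window contains it, so quinquennial censuses tile the study period
exactly.

## Track 1 — community-level BYM model

Counts per community are modelled as

    Y_i ~ Poisson(E_i λ_i),   log λ_i = μ + X_i β + S_i + V_i,

with indirectly standardized expected counts E_i = Σ person-years × reference
stratum rate, covariates X_i (well-water %, material and social deprivation
scores), an intrinsic CAR field S (conditional sd σ_S, queen contiguity,
sum-to-zero within each connected component) and exchangeable noise V
(sd σ_V).  Priors are weakly informative and proper: μ, β ~ N(0, 10²),
σ_S, σ_V ~ half-Normal(0, 1).

Inference is Metropolis-within-Gibbs MCMC (default 20,000 iterations, 5,000
burn-in, thinning 5).  Design choices that matter:

- **Colour-class sweeps.** S is updated single-site but vectorized over the
  colour classes of a greedy graph colouring; no two neighbours move in the
  same batch, so each sweep is an exact single-site scan.
- **Recentring by projection.** After each sweep S is recentred to sum to
  zero within each connected component, the standard practice for intrinsic
  CAR samplers; the intercept re-absorbs the level through its own updates.
  Islands (communities with no neighbours) keep S_i = 0 and rely on V_i.
- **Joint rescaling moves.** σ_S and S (and σ_V and V) are also proposed
  jointly, scaled by a common factor e^δ.  The CAR/Gaussian prior term and
  the transform Jacobian cancel exactly in the acceptance ratio, leaving the
  likelihood change, the half-normal prior and the log-scale Jacobian.
  Without these moves the variance parameters mix an order of magnitude more
  slowly.
- **Adaptation** of all proposal scales by Robbins–Monro during burn-in only.
- Posterior summaries are invariant to the input ordering of communities
  (they are sorted internally), and an initial-positive-sequence effective
  sample size below 100 for either σ triggers a warning, not a failure.

Reported quantities are posterior means of the residual relative risk
exp(U_i) = exp(S_i + V_i) and exceedance probabilities
P_i(10%) = Pr[exp(U_i) > 1.1 | data], with reporting bands at 0.8 and 0.95.

Covariates enter in raw units (percentages for well water, PC scores for
deprivation); the deprivation scores are first principal components of three
z-scored census indicators each (income and employment sign-flipped first),
computed on the correlation matrix so they are invariant to affine
rescaling of any indicator, and oriented so higher = more deprived.

## Track 2 — local-EM kernel smoothing

The spatially continuous estimator targets a relative-risk surface λ(s) (or
λ(s, t)) for a point process with offset ρ(s, t), the expected-case density
under reference rates, rasterized by cell-centre containment (default 1 km
cells for full-scale work; the examples in this repository use 2 km cells on
smaller domains).  The fixed point alternates

- **E-step**: each censored case j is distributed over the cells of its
  candidate set A_j with weights ∝ λ(g) ρ(g) Δ²; exact cases put unit mass
  on their cell; coarse-censored cases use the coarse region's cells through
  the same machinery.  Spatio-temporally, mass stays in the case's own
  diagnosis year and its own census period's candidate cells.
- **M-step**: λ_new = smooth(case mass) / smooth(ρΔ²), then rescaled by a
  scalar so that Σ λ ρ Δ² equals the case count exactly.  The rescaling
  makes mass conservation an identity rather than an approximation; it is a
  no-op in the flat-risk limit and commutes with the reductions below.

Iteration starts from λ ≡ 1 and stops when the sup-norm relative change
drops below `tol` (default 1e-4, cap 200 iterations).  A likelihood-based
stopping rule was rejected because the smoothed iteration need not be
monotone in likelihood; the sup-change history is monitored instead and
non-monotone tails are logged.

**Smoothing operator.** The Gaussian kernel (sd = bandwidth, truncated at
4 sd) is made *doubly stochastic* on the study-region mask by symmetric
Sinkhorn scaling, S = diag(d) K diag(d).  Rows summing to one make constant
fields exact fixed points (edge-correction exactness: a flat SIR stays flat
up to the boundary); columns summing to one preserve mass.  In the interior
of a large domain d is constant and S reduces to ordinary normalized
Gaussian convolution.  The temporal kernel is treated identically in 1-D
over the observed year range; with a separable space-time kernel on a
product domain the joint Sinkhorn factorizes, so spatial and temporal
scalings are computed independently.

Useful exact reductions (all covered by tests): with only exact geocodes
the algorithm converges in one iteration to the ratio-of-smooths estimator;
with one region covering the whole grid it returns the flat SIR; with
τ → ∞ the spatio-temporal fit equals the pooled spatial fit at every time.

## Bandwidth selection, testing, exceedance

- **Cross-validation** by repeated half-splits of the *cases* (default 10
  splits, both fold orientations): fit on one half against a halved offset,
  score the held-out half by the censoring-aware Poisson log-likelihood
  (censored cases contribute the log predicted mass over their candidate
  cells, which reduces to the usual cell-count likelihood for exact cases).
  Ties select the larger bandwidth — more smoothing, fewer false structures.
- **Score test** for spatial (or spatio-temporal) structure: the statistic
  is the offset-weighted variance of the fitted surface (after removing each
  location's time mean for the temporal variant); its null distribution
  comes from B parametric-bootstrap datasets at constant λ = 1, re-censored
  by resampling the data's own (precision, candidate-set size) classes, and
  p = (1 + #{T* ≥ T})/(B + 1).  The contract is calibration (type-I error
  near nominal) and power, not a specific closed form.
- **Exceedance surfaces**: B = 100 datasets simulated at constant λ₀ = 1.1,
  re-censored like the data, refit with the same bandwidths; p(s) is the
  proportion of replicates whose estimate exceeds the data's at s, and
  P(s; 10%) = 1 − p(s) (denominator B, matching the proportion-of-datasets
  definition; the +1 correction is reserved for the score test, where
  conservativeness matters).  Non-convergent replicates are dropped and
  logged; more than 10% dropped is an error.

The pipeline runs the spatio-temporal model only when the spatial test is
below a 0.1 gate, and maps exceedance from the pooled spatial model unless a
temporal effect is also detected; index years default to 1980/1990/2000/2010.

## The synthetic registry

The generator emulates the structure of the real setting, not its map:

- **Geography**: Lloyd-relaxed Voronoi communities on a rectangle (default
  311 communities on 300 × 180 km, ≈ the area of the real province), grouped
  into 18 coarse divisions; fine census regions re-tessellated per census
  with no lineage tracking.  Late censuses subdivide communities (strict
  nesting); early censuses — whose real-world counterparts are *coarser*
  than communities — group whole communities within each division, so the
  nesting direction inverts exactly as it does in the source geographies.
- **Population**: per-subdivision totals around 400–700 persons, community
  totals capped near 30,900, split across sex × fourteen 5-year adult age
  bands by largest-remainder rounding; a random ~20% of fine regions get an
  inhabited fraction in (0.6, 1), concentrating density on part of their
  cells.
- **Rates**: age effects rise exponentially (doubling roughly per decade),
  male:female crude ratios 2.9 (bladder-like) and 1.5 (kidney-like),
  calibrated so a province-scale population yields ≈ 3,200 / ≈ 2,100 cases
  over a 13-year window.
- **Risk fields**: constant, one- or two-bump Gaussian excesses (amplitude =
  peak relative risk), or a linear gradient, with optional linear temporal
  drift.
- **Censoring**: per-era precision mixes default to (86.6, 2.3, 11.1)% for
  the recent era and (43.6, 52.9, 3.5)% for the early era; postal-type
  censoring uses the containing fine region plus Uniform{0..3} adjacent
  regions; town-type censoring keeps only the coarse division.  True points
  are retained in a hidden field for evaluation only.
- **Covariates**: six indicators loaded (0.8) on two latent deprivation
  factors with noise sd 0.6, plus a spatially structured well-water
  percentage clipped to [0, 100].

What the generator does **not** emulate: a real coastline or irregular
boundaries, age-period-cohort rate dynamics, migration, spatially clustered
postal-code geometries, or correlation between deprivation and risk unless
explicitly configured.  Passing tests therefore demonstrate the estimators'
internal correctness and calibration under the stated data structure, not
robustness to every artefact of real registry data.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at desk scale: grids of
20×20–60×40 cells (2 km), hundreds to a few thousand cases, B = 49–99
bootstrap replicates, MCMC chains of 3,000–6,000 iterations, and 5–10
replicates for recovery experiments — the same code paths as full-scale runs
with smaller sizes, chosen as the smallest sizes at which the statistical
checks are informative.  Other numerics: kernel truncation at 4 sd; Sinkhorn
tolerance 1e-12; boundary points belong to the cell with the smaller linear
index; rasterization is by cell-centre containment (deterministic,
convergent as Δ → 0); a populated region with no grid cell is an error
(grid too coarse) rather than silently dropped mass.

## Known limitations

- The local-EM track does not accommodate covariates; risk is relative to
  the reference-rate offset only.
- The coarse-grid approximation is the contract: no continuous-space
  integration is attempted, so estimates within half a cell of a boundary
  inherit rasterization error.
- With several non-trivial ICAR components the recentring-by-projection is
  the standard approximation; with one dominant component (the generated
  tessellations are connected) it is exact in the constrained target.
- The grouped early-period geography breaks strict fine-in-community
  nesting by design; community aggregation for those periods goes through
  representative points.
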