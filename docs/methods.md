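# Methods

## Scope and data model

All analyses operate on an *area table*: one row per small area with a
unique id, planar centroid coordinates, the population at risk `n_i` and
the observed case count `O_i`. When an input file carries two census
population columns (`pop2006`, `pop2011`) the population at risk is their
arithmetic mean. Areas with zero population cannot be standardized and are
dropped with an explicit warning. Spatial structure enters through an
undirected edge list (contiguity) and through centroid distances (scan
windows); polygon GeoJSON can be converted to an edge list with the queen
rule (any shared boundary point makes two areas neighbours).

## Internal standardization and raw SIR

Expected counts use internal (crude) standardization,
`E_i = n_i · ΣO/Σn`, so the map is its own reference: `ΣE = ΣO` holds
identically and the E-weighted mean of the raw SIRs `O_i/E_i` is exactly 1.
No age standardization is attempted; the package deliberately reproduces
the crude-rate convention common in registry-based neighbourhood mapping.

## Contiguity weights

Weights are binary and symmetric with zero diagonal. Higher-order
contiguity is defined by shortest-path distance on the contiguity graph:
order-2 neighbours are areas at graph distance exactly 2, and the default
for smoothing is order 2 *including* lower orders, matching the common GIS
convention for "second-order queen, include lower orders". Both behaviours
are exposed (`include_lower`), since published analyses rarely state which
was used. Islands are permitted in the weights object but rejected by any
CAR-based operation, where the conditional distribution is undefined.

## Moran's I

`I = (N/S0)·Σ w_ij z_i z_j / Σ z_i²` on mean-centred values, binary
(unstandardized) weights by default with a row-standardization flag.
Inference is a two-sided permutation test around the exact permutation-null
expectation `E[I] = −1/(N−1)`: `p = (#{|I_perm − E_I| ≥ |I_obs − E_I|}+1)/(n_perm+1)`,
999 permutations by default. The statistic is invariant to positive affine
transforms of the input, and the permutation p is super-uniform under
exchangeability (checked by simulation in the test suite).

## Spatial empirical Bayes (Marshall)

The smoother is Marshall's local empirical Bayes estimator with a
self-inclusive reference window (the area plus its contiguity neighbours).
Smoothing operates on the SIR scale with `E_i` as the exposure, so smoothed
values are directly comparable with raw SIRs and BYM relative risks; crude
rates with population exposure can be smoothed instead via the
column arguments. Negative method-of-moments estimates of the prior
variance truncate to zero, i.e. full shrinkage to the local mean (the
standard convention); an all-zero reference window leaves the estimate at
zero. Global (aspatial) EB is the degenerate case of a window containing
all areas. The implementation is validated against an independently coded
brute-force oracle to 1e-12 on random graphs.

## BYM model and sampler

`O_i ~ Poisson(E_i θ_i)`, `log θ_i = α + u_i + v_i`; flat prior on α,
`u_i ~ N(0, 1/τ_u)` iid, and an intrinsic CAR prior for `v` with
conditional mean the neighbour average and conditional variance
`1/(τ_v·m_i)` (`m_i` = neighbour count; τ_v is a precision). Both
precisions carry Gamma(shape, rate) priors with defaults
`a_v = 0.5, b_v = 0.005` (prior mean 100) and `a_u = 0.5, b_u = 0.5`
(prior mean 1), the weakly-informative choices standard for this model.

Sampling is Metropolis-within-Gibbs:

* α, each `u_i` and each `v_i` move by adaptive random-walk Metropolis.
  The `u` vector updates in one vectorized step (conditionally independent
  components); `v` updates by colour classes of a greedy graph colouring,
  so no two simultaneously-updated areas are adjacent.
* Two mixing moves: a likelihood-invariant shift `(α, u) → (α+δ, u−δ)`
  that decorrelates α from the mean of `u`, and a joint scale move
  `(v, τ_v) → (e^ε v, e^{−2ε} τ_v)` that leaves the ICAR exponent
  invariant and mixes the spatial-field amplitude (without it the τ_v
  chain is visibly sticky).
* Exact conjugate draws: `τ_u | u ~ Gamma(a_u + I/2, b_u + Σu²/2)`,
  `τ_v | v ~ Gamma(a_v + (I−k)/2, b_v + ½Σ_{i~j}(v_i−v_j)²)` with `k` the
  number of connected components (the ICAR rank deficiency).
* After each sweep `v` is recentred to sum to zero per component; on a
  connected graph the removed mean is absorbed into α, which leaves the
  likelihood exactly invariant. On a disconnected graph the projection is
  applied without compensation (the usual identifiability convention);
  all shipped lattices are connected.
* Step sizes adapt toward a 0.44 per-scalar acceptance rate during burn-in
  only and are frozen afterwards, preserving the Markov property of the
  retained draws.

Chains start overdispersed (α, u, v from N(0, 2²), log-uniform
precisions). Convergence is monitored by the Brooks–Gelman–Rubin statistic
`R̂ = sqrt(((n−1)/n·W + B/n)/W)` for α, τ_u, τ_v and a spread of θ_i.
The production default is 100,000 iterations with 5,000 burn-in on 2
chains (thinned by 10 to bound memory); tests and the acceptance script
run scaled-down chains (5,000/1,000 and 20,000/4,000 respectively), which
the diagnostics show to be converged (R̂ < 1.1) at those sizes.

**Parameter-recovery experiment.** The test suite fits 200-area lattices
simulated at α = 0.2, τ_u = 4, τ_v = 10 and checks that the 95% credible
interval for α covers the truth in at least 18 of 20 seeded replicates.
The fits use the *generative* expected counts (`E_i = n_i·r` with the known
baseline rate r): re-standardizing internally from each simulated caseload
would absorb `log` of the realized mean relative risk into the offset and
shift α by approximately `−(σ_u² + σ_v²)/2`, making the generative α
unrecoverable by construction rather than by any fault of the sampler.

## Scan statistic

Windows are the nearest-first cumulative prefixes of every centroid's
distance ordering, capped at a maximum share of the total population;
distance ties break by ascending area id, making enumeration fully
deterministic. The Poisson log likelihood ratio uses the `0·ln 0 := 0`
convention. The alternative is two-sided: windows with `c > E_c` are
high-rate candidates, the rest low-rate, and by default the two directions
are ranked and tested separately against direction-specific null maxima
(a pooled single maximum is available via `pool_directions`). Null
replicates redistribute the observed total C multinomially with
probabilities `E_i/ΣE` (the conditional Poisson model);
`p = (R_beat+1)/(R+1)` counts replicates whose maximum *strictly* exceeds
the observed LLR, which is slightly conservative under ties in discrete
data. Cluster reporting keeps, per direction, the greedy non-overlapping
set in decreasing LLR order, drops clusters with p ≥ α (α = 0.05 default)
and ranks the rest (primary, secondary, tertiary, ...).

The maximum window size is chosen with the Gini coefficient: for each
candidate population fraction (SaTScan's default ladder
0.01–0.50), the significant non-overlapping high-rate clusters define a
Lorenz curve of cumulative observed-case share against cumulative
expected-case share, clusters ordered by decreasing `c/E_c` and the
non-cluster remainder closing the curve at (1, 1); Gini = 2 × the area
between curve and diagonal, and the candidate with maximal Gini wins (ties
to the smaller fraction; if no candidate yields a significant cluster the
optimum is reported as absent). All candidates share one seeded replicate
stream, restricted to each candidate's window set, so the profile is
internally consistent and fast. The reported relative risk is the
inside/outside ratio `(c/E_c)/((C−c)/(C_E−E_c))`; the annual rate per
100,000 is `c/(pop·years)·10⁵`. Report rounding follows registry-table
convention: O/E and RR to 2 decimals, annual rates to 1.

## Synthetic-data generator

`simulate_lattice` builds an `n_rows × n_cols` unit grid (default 22 × 17 =
374 areas) with queen adjacency and log-normal populations (median 8,000
women, log-sd 0.5 — neighbourhood-scale heterogeneity typical of a large
city). `simulate_bym_counts` draws `u` and an exact ICAR field `v` (via the
eigendecomposition of the component Laplacian restricted to the
sum-to-zero subspace), sets `θ = exp(α+u+v)`, and either scales the
baseline so the expected total caseload hits a target (default 3,080 over
3 years) or uses a supplied per-person rate, in which case the generative
`E_i` are returned for recovery experiments. `implant_clusters` multiplies
the Poisson means of the areas nearest a chosen center by a relative risk
and redraws all counts from the same child stream the generator uses, so a
multiplier of 1 with the generating seed reproduces the counts exactly.
The default profile implants one high-risk cluster (15 areas ≈ 4% of the
population, rr 3.9) and one low-risk cluster (15 areas, rr 0.05),
mirroring the hot-spot/cold-spot regimes of the motivating study.

What the generator does *not* emulate: real administrative geographies
(irregular polygon sizes and shapes, edge effects), geocoding failure and
registry under-ascertainment, age structure, and covariate-driven risk
gradients. Passing tests on this generator therefore demonstrate the
correctness and power of the algorithms under the stated statistical
model, not robustness to those real-data features.

**Power experiment.** The scan-power check implants an RR = 4 cluster of 5
areas on a 200-area lattice (~1,000 cases) over a *homogeneous* background
(θ ≡ 1 outside the implant) and requires the primary high-rate cluster to
recover the implant with Jaccard ≥ 0.6 in ≥ 18/20 seeds. On a full BYM
background, spontaneous hot spots legitimately compete with the implant
and recovery is not guaranteed by design; the homogeneous background
isolates the property under test. The type-I error check runs 200 null
datasets (49-area lattice, C = 250, R = 199) and accepts empirical
rejection rates in [0.01, 0.10] around the nominal 0.05.

## Numerical conventions and degenerate inputs

* Distance and LLR computations are plain float64; the LLR of a window
  with `c = 0` or `c = C` uses the `0·ln 0` limit.
* Windows require `0 < E_c < C`; population caps beyond 50% are rejected.
* Constant inputs to Moran's I, degenerate (zero-variance) chains in R̂,
  islands in CAR operations, zero expected counts, and overlapping
  implants all raise informative errors rather than returning NaN.
* Every stochastic routine takes an explicit seed and is reproducible
  bit-for-bit given identical inputs.

## Known limitations

* The BYM fit is a custom Metropolis-within-Gibbs sampler, adequate for
  the few-hundred-area problems it targets; very large maps would warrant
  sparse-matrix CAR updates or INLA-style approximations (out of scope).
* Only circular windows and the purely spatial Poisson scan model are
  implemented (no elliptic windows, space-time scanning, or covariate
  adjustment).
* Coordinates are assumed planar; no projection handling or great-circle
  distances.
* τ_v is weakly identified in sparse-caseload maps and its posterior is
  prior-sensitive (a known property of the ICAR precision), which is why
  convergence, not point recovery, is diagnosed for it.
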