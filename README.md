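# spatepi

Small-area disease mapping and spatial cluster detection for count data:
raw standardized incidence ratios, spatial empirical Bayes and
Besag–York–Mollié (BYM) smoothing, Moran's I, and a purely spatial Poisson
scan statistic with Gini-coefficient cluster-size selection.

The package is aimed at epidemiologists analysing registry case counts over
many small administrative units (census tracts, city neighbourhoods), where
raw rates are unstable and spatially autocorrelated. It was built around a
canonical use case — ~374 urban neighbourhoods carrying ~3,080 female
breast-cancer cases over three years — and ships a synthetic-data generator
that reproduces that structure with known ground truth, so every stage of
the pipeline is testable end to end without access to confidential registry
data.

## The models

**Raw SIR.** With `O_i` observed cases and `n_i` persons at risk in area
`i`, internal standardization sets `E_i = n_i·(ΣO/Σn)`, so `ΣE = ΣO`, and
`SIR_i = O_i / E_i`.

**Spatial empirical Bayes (Marshall).** Each raw SIR is shrunk toward the
mean of a local reference window (the area plus its contiguity neighbours,
second-order queen by default), with prior moments estimated from the
window: `sir_seb_i = m_i + C_i·(SIR_i − m_i)`, `C_i = s²_i/(s²_i + m_i/E_i)`.

**BYM.** `O_i ~ Poisson(E_i θ_i)`, `log θ_i = α + u_i + v_i` with
exchangeable `u_i ~ N(0, 1/τ_u)` and an intrinsic CAR field `v` whose
conditional for area `i` is normal around the neighbour mean with variance
`1/(τ_v m_i)`. Precisions carry Gamma(0.5, 0.005) (spatial) and
Gamma(0.5, 0.5) (unstructured) priors; fitting is Metropolis-within-Gibbs
with exact conjugate precision draws and Brooks–Gelman–Rubin diagnostics.

**Scan statistic.** Circular windows grow nearest-first around every
centroid up to a maximum population share; each window's Poisson log
likelihood ratio is `c·ln(c/E_c) + (C−c)·ln((C−c)/(C−E_c))`, significance
comes from multinomial Monte Carlo replicates, `p = (R_beat+1)/(R+1)`, and
the maximum window size is selected by the Gini coefficient of the
significant non-overlapping high-rate cluster collection.

## Worked example

```python
import spatepi as sp

spec = sp.SimulationSpec(seed=1)          # 374 areas, ~3,080 cases, 2 implants
areas, edges, truth = sp.simulate_study(spec)
sir = sp.compute_raw_sir(sp.compute_expected(areas))

W2 = sp.build_weights(edges.itertuples(index=False, name=None), list(sir["id"]),
                      order=2, include_lower=True)
seb = sp.seb_smooth(sir, W2)

W1 = sp.build_weights(edges.itertuples(index=False, name=None), list(sir["id"]))
m = sp.morans_i(sir["cases"].to_numpy(float), W1, n_perm=999, seed=1)

D = sp.pairwise_distances(sir)
res = sp.scan(sir, D, max_frac=0.04, R=999, seed=1, years=3.0)
tab = sp.cluster_table(res.clusters, sir, years=3.0)
```

which prints (`seed=1`):

```
374 areas, 3310 cases; raw SIR median 0.84, zeros 12
SEB SIR median 0.89, zeros 0
Moran's I(cases) = 0.166 (p = 0.001)
direction  observed  expected   oe   rr  p_mc
     high     389.0    114.82 3.39 3.71 0.001
      low       7.0    130.54 0.05 0.05 0.001
```

Read: the simulated map is spatially autocorrelated (Moran's I 0.166,
permutation p 0.001); smoothing removes all 12 zero-SIR areas; the scan
finds a primary hot spot (3.39× the expected caseload inside the window,
relative risk 3.71 against the rest of the map) and a deep cold spot
(O/E 0.05) — the two implanted clusters, each at the smallest attainable
Monte Carlo p with 999 replicates.

The same pipeline is scriptable from the shell:

```sh
spatepi simulate --seed 1 --out-prefix sim/
spatepi scan --areas sim/areas.csv --gini --reps 999 --seed 1 --out-prefix scan/
spatepi run --out results/            # full pipeline on the default profile
```

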