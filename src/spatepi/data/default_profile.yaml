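# Default synthetic emulation profile: a 374-area urban lattice carrying
# ~3,080 cases over 3 years, moderately spatially autocorrelated relative
# risks, one tight high-risk implant (~4% of the population, rr 3.9) and one
# deep low-risk implant (rr 0.05).
simulation:
  n_rows: 22
  n_cols: 17
  pop_median: 8000.0
  pop_sigma: 0.5
  total_cases: 3080.0
  alpha: 0.0
  tau_u: 4.0
  tau_v: 10.0
  years: 3.0
  implants:
    - {center: 130, n_areas: 15, rr: 3.9}
    - {center: 310, n_areas: 15, rr: 0.05}
  seed: 0

weights:
  order: 2
  include_lower: true

moran:
  n_perm: 999
  variable: cases

bym:
  n_iter: 20000
  n_burn: 4000
  n_chains: 2
  thin: 10
  a_v: 0.5
  b_v: 0.005
  a_u: 0.5
  b_u: 0.5

scan:
  gini: true
  reps: 999
  alpha: 0.05
  max_frac: 0.5
  years: 3.0

seed: 0
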