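"""Besag–York–Mollié (BYM) disease-mapping model fit by Metropolis-within-Gibbs.

Model
-----
Counts are conditionally Poisson with internally standardized offsets:

    O_i | θ_i ~ Poisson(E_i θ_i),      log θ_i = α + u_i + v_i

``α`` is the log baseline relative risk (improper flat prior), ``u_i`` are
exchangeable ("unstructured") effects, u_i ~ N(0, 1/τ_u), pulling areas
toward the global mean, and ``v_i`` carry an intrinsic conditional
autoregressive (ICAR) prior pulling each area toward the mean of its
contiguity neighbours:

    v_i | v_{-i} ~ N( Σ_j W_ij v_j / m_i ,  1 / (τ_v m_i) ),   m_i = Σ_j W_ij.

Both precisions get Gamma(a, b) priors (shape/rate, mean a/b). The defaults,
a_v = 0.5, b_v = 0.005 (prior mean precision 100) for the spatial component
and a_u = 0.5, b_u = 0.5 (prior mean 1) for the unstructured component, are
the weakly-informative choices standard in small-area incidence mapping.

Sampler
-------
* α: random-walk Metropolis on the Poisson log posterior, plus a joint
  "shift" move (α, u) → (α + δ, u − δ) that leaves the likelihood invariant
  and decorrelates α from the mean of u.
* u: all areas proposed at once (conditionally independent given the rest),
  accepted element-wise.
* v: areas grouped by a greedy colouring of the contiguity graph; within a
  colour class no two areas are adjacent, so their full conditionals are
  independent and the class is updated as one vectorized Metropolis step.
* After each sweep v is recentred to sum to zero per connected component
  (ICAR identifiability); for a connected graph the removed mean is absorbed
  into α so the likelihood is untouched.
* τ_u | u ~ Gamma(a_u + I/2, b_u + Σ u_i²/2) and
  τ_v | v ~ Gamma(a_v + (I−k)/2, b_v + ½ Σ_{i~j} (v_i − v_j)²), with k the
  number of connected components (the ICAR rank deficiency), drawn exactly.
* Per-scalar random-walk step sizes adapt toward a 0.44 acceptance rate
  during burn-in only, so post-burn-in draws form a genuine Markov chain.

Chains start from overdispersed initial values (α, u, v from N(0, 2²)) and
convergence is monitored with the Brooks–Gelman–Rubin statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import WeightsMatrix


@dataclass(frozen=True)
class BYMPriors:
    """Gamma(shape a, rate b) hyperpriors for the two precisions."""

    a_v: float = 0.5
    b_v: float = 0.005
    a_u: float = 0.5
    b_u: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a_v, self.b_v, self.a_u, self.b_u) <= 0:
            raise ValueError("gamma hyperparameters must be positive")

    @property
    def prior_mean_tau_v(self) -> float:
        return self.a_v / self.b_v

    @property
    def prior_mean_tau_u(self) -> float:
        return self.a_u / self.b_u


@dataclass(frozen=True)
class MCMCConfig:
    """Run-length and tuning configuration.

    The default mirrors a production disease-mapping run (100,000 iterations,
    5,000 burn-in, 2 chains); tests and quick exploration should scale down.
    """

    n_iter: int = 100_000
    n_burn: int = 5_000
    n_chains: int = 2
    seed: int = 0
    thin: int = 10
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1 or self.adapt_interval < 1:
            raise ValueError("thin and adapt_interval must be >= 1")


@dataclass
class BYMPosterior:
    """Post-burn-in MCMC draws and diagnostics.

    Array shapes: scalars ``(n_chains, n_kept)``; fields ``(n_chains,
    n_kept, I)``. ``theta`` is derived as exp(α + u + v).
    """

    area_ids: tuple
    alpha: np.ndarray
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    tau_u: np.ndarray
    tau_v: np.ndarray
    rhat: dict[str, float]
    acceptance: dict[str, float]

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.alpha[..., None] + self.u + self.v)

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


def car_conditional(
    v: np.ndarray, W: WeightsMatrix, tau_v: float, i: int
) -> tuple[float, float]:
    """ICAR full-conditional mean and variance of v_i given its neighbours.

    mean = neighbour average of v; variance = 1 / (tau_v * m_i).
    """
    if tau_v <= 0:
        raise ValueError("tau_v must be positive")
    w_row = W.W[i].astype(float)
    m = w_row.sum()
    if m == 0:
        raise ValueError(
            f"area {W.area_ids[i]!r} is an island: ICAR conditional undefined"
        )
    mean = float(w_row @ np.asarray(v, dtype=float) / m)
    return mean, 1.0 / (tau_v * m)


def gelman_rubin(chains: np.ndarray) -> float:
    """Brooks–Gelman–Rubin potential scale reduction factor for one scalar.

    R̂ = sqrt(((n−1)/n · W + B/n) / W), with W the mean within-chain sample
    variance and B = n · var(chain means). Values near 1 indicate that the
    chains have mixed into the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    m, n = chains.shape
    within = chains.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("degenerate (constant) chains: R-hat undefined")
    between = n * chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _greedy_coloring(W: np.ndarray) -> list[np.ndarray]:
    """Partition areas into classes with no within-class adjacency."""
    n = W.shape[0]
    color = np.full(n, -1, dtype=int)
    for i in range(n):
        used = {color[j] for j in np.flatnonzero(W[i]) if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


def tau_u_conditional_params(u: np.ndarray, priors: BYMPriors) -> tuple[float, float]:
    """(shape, rate) of the gamma full conditional of τ_u."""
    u = np.asarray(u, dtype=float)
    return priors.a_u + len(u) / 2.0, priors.b_u + float(u @ u) / 2.0


def tau_v_conditional_params(
    v: np.ndarray, W: WeightsMatrix, priors: BYMPriors
) -> tuple[float, float]:
    """(shape, rate) of the gamma full conditional of τ_v (ICAR)."""
    v = np.asarray(v, dtype=float)
    pairs = W.edge_pairs()
    ss = float(((v[pairs[:, 0]] - v[pairs[:, 1]]) ** 2).sum())
    k = len(np.unique(W.connected_component_labels()))
    return priors.a_v + (W.n - k) / 2.0, priors.b_v + ss / 2.0


def _run_chain(
    O: np.ndarray,
    E: np.ndarray,
    W: WeightsMatrix,
    priors: BYMPriors,
    config: MCMCConfig,
    chain_seed,
    spatial: bool,
):
    rng = np.random.default_rng(chain_seed)
    I = len(O)
    Wmat = W.W.astype(float)
    m_i = Wmat.sum(axis=1)
    comp = W.connected_component_labels()
    k_comp = len(np.unique(comp))
    connected = k_comp == 1
    if spatial and np.any(m_i == 0):
        isl = [W.area_ids[j] for j in np.flatnonzero(m_i == 0)]
        raise ValueError(f"island area(s) {isl} have no ICAR conditional; "
                         "pass spatial=False or fix the weights")
    colors = _greedy_coloring(W.W) if spatial else []
    pairs = W.edge_pairs()

    # overdispersed start
    alpha = float(rng.normal(0.0, 2.0))
    u = rng.normal(0.0, 2.0, size=I)
    v = rng.normal(0.0, 2.0, size=I) if spatial else np.zeros(I)
    if spatial:
        for c in np.unique(comp):
            v[comp == c] -= v[comp == c].mean()
    tau_u = float(10.0 ** rng.uniform(-1, 1))
    tau_v = float(10.0 ** rng.uniform(-1, 1))

    step_alpha = 0.1
    step_u = np.full(I, 0.3)
    step_v = np.full(I, 0.3)
    step_shift = 0.2

    n_kept = (config.n_iter - config.n_burn) // config.thin
    out_alpha = np.empty(n_kept)
    out_u = np.empty((n_kept, I))
    out_v = np.empty((n_kept, I))
    out_tau_u = np.empty(n_kept)
    out_tau_v = np.empty(n_kept)

    acc = {"alpha": 0, "u": 0, "v": 0}
    try_n = {"alpha": 0, "u": 0, "v": 0}
    batch_acc_a = 0
    batch_acc_u = np.zeros(I)
    batch_acc_v = np.zeros(I)

    sumO = float(O.sum())
    kept = 0
    for it in range(config.n_iter):
        lam_uv = E * np.exp(u + v)  # Poisson means sans exp(alpha)

        # --- alpha: random-walk Metropolis (flat prior)
        prop = alpha + rng.normal(0.0, step_alpha)
        s = float(lam_uv.sum())
        dlp = (prop - alpha) * sumO - (np.exp(prop) - np.exp(alpha)) * s
        if not np.isfinite(dlp):
            raise RuntimeError(f"non-finite log-posterior at iteration {it}")
        try_n["alpha"] += 1
        if np.log(rng.uniform()) < dlp:
            alpha = prop
            acc["alpha"] += 1
            batch_acc_a += 1

        # --- joint shift: likelihood-invariant exchange between alpha and u
        delta = rng.normal(0.0, step_shift)
        dlp = -0.5 * tau_u * (I * delta**2 - 2.0 * delta * u.sum())
        if np.log(rng.uniform()) < dlp:
            alpha += delta
            u = u - delta

        # --- u: element-wise vectorized Metropolis
        ea = np.exp(alpha)
        lam_base_v = E * np.exp(v) * ea  # Poisson mean sans exp(u)
        prop_u = u + step_u * rng.standard_normal(I)
        dll = (
            O * (prop_u - u)
            - lam_base_v * (np.exp(prop_u) - np.exp(u))
            - 0.5 * tau_u * (prop_u**2 - u**2)
        )
        accept = np.log(rng.uniform(size=I)) < dll
        u = np.where(accept, prop_u, u)
        try_n["u"] += I
        acc["u"] += int(accept.sum())
        batch_acc_u += accept

        # --- v: coloured vectorized Metropolis under the ICAR prior
        if spatial:
            lam_base_u = E * np.exp(u) * ea
            for cls in colors:
                nb_sum = Wmat[cls] @ v  # neighbours are outside cls
                vbar = nb_sum / m_i[cls]
                cur = v[cls]
                prop_v = cur + step_v[cls] * rng.standard_normal(len(cls))
                dll = (
                    O[cls] * (prop_v - cur)
                    - lam_base_u[cls] * (np.exp(prop_v) - np.exp(cur))
                    - 0.5 * tau_v * m_i[cls] * ((prop_v - vbar) ** 2 - (cur - vbar) ** 2)
                )
                accept = np.log(rng.uniform(size=len(cls))) < dll
                v[cls] = np.where(accept, prop_v, cur)
                try_n["v"] += len(cls)
                acc["v"] += int(accept.sum())
                batch_acc_v[cls] += accept

            # joint (v, tau_v) scale move: v -> e^eps v, tau_v -> e^(-2 eps) tau_v
            # leaves the ICAR exponent invariant, so only the likelihood, the
            # gamma prior on tau_v, and a residual -2*eps term (normalization
            # + Jacobian) enter the acceptance ratio; mixes the field
            # amplitude far faster than per-area moves alone.
            eps = rng.normal(0.0, 0.1)
            scale = np.exp(eps)
            v_prop = v * scale
            tau_prop = tau_v * np.exp(-2.0 * eps)
            lam_base_u = E * np.exp(u) * ea
            dlp = float(
                np.sum(O * (v_prop - v) - lam_base_u * (np.exp(v_prop) - np.exp(v)))
            )
            dlp += (priors.a_v - 1.0) * (-2.0 * eps) - priors.b_v * (tau_prop - tau_v)
            dlp += -2.0 * eps
            if np.log(rng.uniform()) < dlp:
                v = v_prop
                tau_v = tau_prop

            # identifiability: sum-to-zero per component
            if connected:
                mu = v.mean()
                v -= mu
                alpha += mu  # exact: alpha + v_i unchanged per area
            else:
                for c in np.unique(comp):
                    v[comp == c] -= v[comp == c].mean()

            sh, rt = tau_v_conditional_params(v, W, priors)
            tau_v = float(rng.gamma(sh, 1.0 / rt))

        sh, rt = tau_u_conditional_params(u, priors)
        tau_u = float(rng.gamma(sh, 1.0 / rt))

        # --- burn-in step-size adaptation toward 0.44 acceptance
        if it < config.n_burn and (it + 1) % config.adapt_interval == 0:
            nb = config.adapt_interval
            step_alpha *= np.exp((batch_acc_a / nb - 0.44) * 0.5)
            step_u *= np.exp((batch_acc_u / nb - 0.44) * 0.5)
            if spatial:
                step_v *= np.exp((batch_acc_v / nb - 0.44) * 0.5)
            step_alpha = float(np.clip(step_alpha, 1e-4, 10.0))
            np.clip(step_u, 1e-4, 10.0, out=step_u)
            np.clip(step_v, 1e-4, 10.0, out=step_v)
            batch_acc_a = 0
            batch_acc_u[:] = 0
            batch_acc_v[:] = 0

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            out_alpha[kept] = alpha
            out_u[kept] = u
            out_v[kept] = v
            out_tau_u[kept] = tau_u
            out_tau_v[kept] = tau_v
            kept += 1

    rates = {k: acc[k] / max(try_n[k], 1) for k in acc}
    return (
        out_alpha[:kept],
        out_u[:kept],
        out_v[:kept],
        out_tau_u[:kept],
        out_tau_v[:kept],
        rates,
    )


def fit_bym(
    sir_table: pd.DataFrame,
    W: WeightsMatrix,
    priors: BYMPriors | None = None,
    config: MCMCConfig | None = None,
    spatial: bool = True,
) -> BYMPosterior:
    """Fit the BYM model to an area table with ``cases`` and ``expected``.

    Parameters
    ----------
    sir_table : DataFrame
        Must align with ``W.area_ids`` (same ids, same order) and contain
        strictly positive ``expected``.
    spatial : bool
        With ``spatial=False`` the ICAR component is dropped (v ≡ 0) and the
        model reduces to an exchangeable Poisson-lognormal fit; this is also
        the only option when ``W`` contains islands.
    """
    priors = priors or BYMPriors()
    config = config or MCMCConfig()
    if tuple(sir_table["id"]) != tuple(W.area_ids):
        raise ValueError("area table and weights matrix must list the same ids in the same order")
    O = sir_table["cases"].to_numpy(dtype=float)
    E = sir_table["expected"].to_numpy(dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")

    per_chain = []
    root = np.random.SeedSequence(config.seed)
    for c, ss in enumerate(root.spawn(config.n_chains)):
        per_chain.append(_run_chain(O, E, W, priors, config, ss, spatial))

    alpha = np.stack([r[0] for r in per_chain])
    u = np.stack([r[1] for r in per_chain])
    v = np.stack([r[2] for r in per_chain])
    tau_u = np.stack([r[3] for r in per_chain])
    tau_v = np.stack([r[4] for r in per_chain])
    rates = {k: float(np.mean([r[5][k] for r in per_chain])) for k in per_chain[0][5]}

    rhat = {
        "alpha": gelman_rubin(alpha),
        "tau_u": gelman_rubin(tau_u),
    }
    if spatial:
        rhat["tau_v"] = gelman_rubin(tau_v)
        # a few representative relative risks
        theta = np.exp(alpha[..., None] + u + v)
        picks = np.linspace(0, W.n - 1, num=min(5, W.n), dtype=int)
        for j in picks:
            rhat[f"theta_{W.area_ids[j]}"] = gelman_rubin(theta[:, :, j])

    return BYMPosterior(
        area_ids=tuple(W.area_ids),
        alpha=alpha,
        u=u,
        v=v,
        tau_u=tau_u,
        tau_v=tau_v,
        rhat=rhat,
        acceptance=rates,
    )


def summarize_posterior(post: BYMPosterior) -> pd.DataFrame:
    """Per-area posterior median and 95% interval of the relative risk θ_i."""
    theta = post.theta.reshape(-1, len(post.area_ids))
    if theta.size == 0:
        raise ValueError("posterior contains no draws")
    med = np.median(theta, axis=0)
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "id": list(post.area_ids),
            "sir_bym": med,
            "bym_lo95": lo,
            "bym_hi95": hi,
        }
    )
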