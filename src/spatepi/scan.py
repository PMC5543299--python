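"""Purely spatial Poisson scan statistic with Gini-based cluster-size selection.

A circular window is grown around every area centroid, nearest-first (distance
ties broken by ascending area id), up to a maximum share of the total at-risk
population. For a window holding ``c`` of the study's ``C`` cases with
``E_c`` expected under the null of constant risk, the log likelihood-ratio
statistic of the discrete Poisson model is

    LLR = c·ln(c/E_c) + (C−c)·ln((C−c)/(C−E_c)),   0·ln 0 := 0,

maximized over all windows. The alternative is two-sided (risk inside differs
from outside); a window is a *high*-rate candidate when c > E_c and *low*
otherwise, and by default the two directions are ranked and tested
separately (a pooled single maximum is available via ``pool_directions``).

Inference is by Monte Carlo: each null replicate redistributes the C cases
multinomially over areas with probabilities E_i/ΣE, the identical window set
is rescanned, and p = (R_beat + 1)/(R + 1) where R_beat counts replicates
whose maximum LLR (in the cluster's direction) strictly exceeds the observed
cluster's LLR.

Because results are sensitive to the maximum window size, the reporting size
is chosen with the Gini coefficient: for each candidate maximum population
fraction, the significant non-overlapping high-rate clusters define a Lorenz
curve of cumulative observed-case share versus cumulative expected-case
share (clusters ordered by decreasing c/E_c, the non-cluster remainder as
the final segment); the candidate maximizing the Gini coefficient — the most
concentrated, least watered-down cluster collection — is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .weights import DistanceMatrix

DEFAULT_GINI_FRACS = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10,
    0.12, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50,
)


@dataclass(frozen=True)
class ScanWindow:
    """A circular scan window: a center and its radius-nearest areas."""

    center_id: object
    radius: float
    member_ids: tuple
    cases: float
    expected: float
    pop: float


@dataclass(frozen=True)
class ScanCluster:
    """A scored (and possibly tested/ranked) scan window."""

    window: ScanWindow
    llr: float
    direction: str  # "high" | "low"
    oe: float
    p_mc: float | None = None
    rr: float | None = None
    annual_rate: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class GiniProfile:
    """Per-candidate maximum-size scan results and Gini coefficients."""

    fracs: tuple
    clusters: tuple  # tuple of tuples of ScanCluster (significant, high-rate)
    gini: tuple
    optimal_frac: float | None
    optimal_gini: float | None


@dataclass(frozen=True)
class ScanResult:
    clusters: tuple  # ranked significant ScanClusters, both directions
    all_candidates: tuple  # non-overlapping candidates incl. non-significant
    n_windows: int
    rep_max_high: np.ndarray = field(repr=False)
    rep_max_low: np.ndarray = field(repr=False)


def poisson_llr(c: float, E_c: float, C: float) -> tuple[float, str]:
    """Log likelihood ratio of one window and its direction.

    Raises ``ValueError`` unless 0 < E_c < C and 0 <= c <= C.
    """
    if not (0 < E_c < C):
        raise ValueError(f"window expected count must lie in (0, C); got E_c={E_c}, C={C}")
    if not (0 <= c <= C):
        raise ValueError(f"window cases must lie in [0, C]; got c={c}")
    llr = 0.0
    if c > 0:
        llr += c * np.log(c / E_c)
    if C - c > 0:
        llr += (C - c) * np.log((C - c) / (C - E_c))
    return float(llr), ("high" if c > E_c else "low")


def _llr_array(oc: np.ndarray, ec: np.ndarray, C: float) -> np.ndarray:
    """Vectorized LLR with the 0·ln0 convention; assumes 0 < ec < C."""
    out = np.zeros(np.broadcast(oc, ec).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = oc * np.log(oc / ec)
        rem = C - oc
        t2 = rem * np.log(rem / (C - ec))
    np.add(out, np.where(oc > 0, t1, 0.0), out=out)
    np.add(out, np.where(rem > 0, t2, 0.0), out=out)
    return out


class _Geometry:
    """Per-center nearest-first orderings and cumulative window sums."""

    def __init__(self, areas: pd.DataFrame, D: DistanceMatrix, max_frac: float):
        if not 0 < max_frac <= 0.5:
            raise ValueError("max_frac must lie in (0, 0.5]")
        if len(areas) == 0:
            raise ValueError("empty area table")
        if tuple(areas["id"]) != tuple(D.area_ids):
            raise ValueError("area table and distance matrix must align")
        self.ids = tuple(areas["id"])
        self.pop = areas["pop"].to_numpy(dtype=float)
        self.cases = areas["cases"].to_numpy(dtype=float)
        self.expected = areas["expected"].to_numpy(dtype=float)
        n = len(self.ids)
        # nearest-first order, distance ties broken by ascending position
        # (areas are kept sorted by id, so position order == id order)
        self.order = np.empty((n, n), dtype=np.intp)
        for i in range(n):
            self.order[i] = np.lexsort((np.arange(n), D.D[i]))
        self.radius = np.take_along_axis(np.broadcast_to(D.D, (n, n)), self.order, axis=1)
        self.popcum = self.pop[self.order].cumsum(axis=1)
        self.ecum = self.expected[self.order].cumsum(axis=1)
        self.ocum = self.cases[self.order].cumsum(axis=1)
        self.C = float(self.cases.sum())
        self.total_pop = float(self.pop.sum())
        self.n = n
        self.max_frac = max_frac
        self.mask = self.pop_mask(max_frac)

    def pop_mask(self, frac: float) -> np.ndarray:
        cap = frac * self.total_pop
        return self.popcum <= cap * (1 + 1e-12)

    def observed_llr(self) -> tuple[np.ndarray, np.ndarray]:
        llr = _llr_array(self.ocum, self.ecum, self.C)
        high = self.ocum > self.ecum
        return llr, high

    def replicate_counts(self, R: int, seed, chunk: int = 50):
        """Yield (chunk, n) multinomial null case tables."""
        rng = np.random.default_rng(seed)
        p = self.expected / self.expected.sum()
        done = 0
        while done < R:
            m = min(chunk, R - done)
            yield rng.multinomial(int(round(self.C)), p, size=m)
            done += m


def enumerate_windows(
    areas: pd.DataFrame, D: DistanceMatrix, max_frac: float
) -> list[ScanWindow]:
    """All distinct circular windows up to the population cap.

    Windows are the cumulative nearest-first prefixes of every center,
    deduplicated by member set.
    """
    g = _Geometry(areas, D, max_frac)
    seen: set[frozenset] = set()
    out: list[ScanWindow] = []
    for i in range(g.n):
        for k in range(g.n):
            if not g.mask[i, k]:
                break
            members = g.order[i, : k + 1]
            key = frozenset(members.tolist())
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ScanWindow(
                    center_id=g.ids[i],
                    radius=float(g.radius[i, k]),
                    member_ids=tuple(g.ids[j] for j in members),
                    cases=float(g.ocum[i, k]),
                    expected=float(g.ecum[i, k]),
                    pop=float(g.popcum[i, k]),
                )
            )
    return out


def _replicate_maxima(
    g: _Geometry, masks: dict, R: int, seed
) -> dict:
    """Per-replicate maximum LLR, separately per direction, per mask."""
    out = {k: (np.full(R, -np.inf), np.full(R, -np.inf)) for k in masks}
    done = 0
    for counts in g.replicate_counts(R, seed):
        m = counts.shape[0]
        ocum = counts[:, g.order].cumsum(axis=2).astype(float)
        llr = _llr_array(ocum, g.ecum[None, :, :], g.C)
        high = ocum > g.ecum[None, :, :]
        for key, mask in masks.items():
            hi = np.where(mask[None, :, :] & high, llr, -np.inf).max(axis=(1, 2))
            lo = np.where(mask[None, :, :] & ~high, llr, -np.inf).max(axis=(1, 2))
            out[key][0][done : done + m] = hi
            out[key][1][done : done + m] = lo
        done += m
    return out


def monte_carlo_pvalues(
    observed_llrs,
    directions,
    areas: pd.DataFrame,
    D: DistanceMatrix,
    max_frac: float,
    R: int = 999,
    seed=None,
) -> np.ndarray:
    """Monte Carlo p-values for observed cluster LLRs.

    p = (R_beat + 1)/(R + 1), with R_beat the number of null replicates whose
    maximum LLR in the cluster's direction strictly exceeds the observed LLR.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    g = _Geometry(areas, D, max_frac)
    maxima = _replicate_maxima(g, {"m": g.mask}, R, seed)["m"]
    rep = {"high": maxima[0], "low": maxima[1]}
    return np.array(
        [(np.sum(rep[d] > llr) + 1) / (R + 1) for llr, d in zip(observed_llrs, directions)]
    )


def select_clusters(candidates, alpha: float = 0.05) -> list[ScanCluster]:
    """Greedy non-overlapping cluster selection and ranking.

    Within each direction, candidates are taken in decreasing LLR order and
    kept if they share no area with an already-kept cluster; clusters with
    p >= alpha are then dropped and ranks 1, 2, 3, ... assigned.
    """
    out: list[ScanCluster] = []
    for direction in ("high", "low"):
        chosen: list[ScanCluster] = []
        used: set = set()
        for cl in sorted(
            (c for c in candidates if c.direction == direction),
            key=lambda c: -c.llr,
        ):
            mem = set(cl.window.member_ids)
            if mem & used:
                continue
            used |= mem
            chosen.append(cl)
        rank = 0
        for cl in chosen:
            if cl.p_mc is not None and cl.p_mc < alpha:
                rank += 1
                out.append(replace(cl, rank=rank))
    return out


def _nonoverlapping_candidates(g: _Geometry, mask: np.ndarray) -> list[ScanCluster]:
    """Observed non-overlapping best windows per direction (no p yet)."""
    llr, high = g.observed_llr()
    llr = np.where(mask, llr, -np.inf)
    cands: list[ScanCluster] = []
    for direction, want_high in (("high", True), ("low", False)):
        dir_llr = np.where(high == want_high, llr, -np.inf)
        flat = np.argsort(dir_llr, axis=None)[::-1]
        used: set = set()
        for f in flat:
            i, k = divmod(int(f), g.n)
            val = dir_llr[i, k]
            if not np.isfinite(val) or val <= 0:
                break
            members = g.order[i, : k + 1]
            mem = set(members.tolist())
            if mem & used:
                continue
            used |= mem
            win = ScanWindow(
                center_id=g.ids[i],
                radius=float(g.radius[i, k]),
                member_ids=tuple(g.ids[j] for j in members),
                cases=float(g.ocum[i, k]),
                expected=float(g.ecum[i, k]),
                pop=float(g.popcum[i, k]),
            )
            cands.append(
                ScanCluster(
                    window=win,
                    llr=float(val),
                    direction=direction,
                    oe=win.cases / win.expected,
                )
            )
    return cands


def scan(
    areas: pd.DataFrame,
    D: DistanceMatrix,
    max_frac: float = 0.5,
    R: int = 999,
    seed=None,
    alpha: float = 0.05,
    years: float | None = None,
    pool_directions: bool = False,
) -> ScanResult:
    """Full purely spatial Poisson scan at a fixed maximum window size.

    Returns ranked significant non-overlapping clusters for both directions
    (or against a single pooled null maximum if ``pool_directions``),
    together with the replicate maxima used for inference.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    g = _Geometry(areas, D, max_frac)
    cands = _nonoverlapping_candidates(g, g.mask)
    rep_high, rep_low = _replicate_maxima(g, {"m": g.mask}, R, seed)["m"]
    if pool_directions:
        pooled = np.maximum(rep_high, rep_low)
        rep = {"high": pooled, "low": pooled}
    else:
        rep = {"high": rep_high, "low": rep_low}
    cands = [
        replace(c, p_mc=float((np.sum(rep[c.direction] > c.llr) + 1) / (R + 1)))
        for c in cands
    ]
    clusters = select_clusters(cands, alpha=alpha)
    if years is not None:
        clusters = [
            replace(c, annual_rate=1e5 * c.window.cases / (c.window.pop * years))
            for c in clusters
        ]
    n_windows = len({frozenset(g.order[i, : k + 1].tolist())
                     for i in range(g.n) for k in range(g.n) if g.mask[i, k]})
    return ScanResult(
        clusters=tuple(clusters),
        all_candidates=tuple(cands),
        n_windows=n_windows,
        rep_max_high=rep_high,
        rep_max_low=rep_low,
    )


def lorenz_gini(obs_shares, exp_shares) -> float:
    """Gini coefficient of a cluster collection's Lorenz curve.

    ``obs_shares[k]`` / ``exp_shares[k]`` are cluster k's share of all
    observed / expected cases. Segments are ordered by decreasing
    obs/exp ratio, the non-cluster remainder closes the curve at (1, 1),
    and Gini = 2 x (area between the curve and the diagonal).
    """
    obs = np.asarray(obs_shares, dtype=float)
    exp_ = np.asarray(exp_shares, dtype=float)
    if len(obs) == 0:
        return 0.0
    if np.any(exp_ <= 0) or obs.sum() > 1 + 1e-9 or exp_.sum() > 1 + 1e-9:
        raise ValueError("shares must be positive fractions summing to <= 1")
    idx = np.argsort(-(obs / exp_), kind="stable")
    x = np.concatenate([[0.0], np.cumsum(exp_[idx]), [1.0]])
    y = np.concatenate([[0.0], np.cumsum(obs[idx]), [1.0]])
    area = float(np.trapezoid(y, x))
    return 2.0 * (area - 0.5)


def gini_select(
    areas: pd.DataFrame,
    D: DistanceMatrix,
    candidate_fracs=DEFAULT_GINI_FRACS,
    R: int = 999,
    seed=None,
    alpha: float = 0.05,
) -> GiniProfile:
    """Choose the maximum window size by the Gini coefficient.

    For each candidate maximum population fraction, the scan is run, the
    significant non-overlapping high-rate clusters are collected, and the
    Gini coefficient of their Lorenz curve is computed. The optimum is the
    candidate with maximal Gini (ties go to the smaller fraction). All
    candidates share one set of null replicates (seeded), restricted to each
    candidate's window set.
    """
    fracs = tuple(sorted(candidate_fracs))
    if not fracs:
        raise ValueError("candidate_fracs must be nonempty")
    if any(not 0 < f <= 0.5 for f in fracs):
        raise ValueError("candidate fractions must lie in (0, 0.5]")
    g = _Geometry(areas, D, max(fracs))
    masks = {f: g.pop_mask(f) for f in fracs}
    maxima = _replicate_maxima(g, masks, R, seed)

    per_frac_clusters = []
    per_frac_gini = []
    for f in fracs:
        cands = _nonoverlapping_candidates(g, masks[f])
        rep = {"high": maxima[f][0], "low": maxima[f][1]}
        cands = [
            replace(c, p_mc=float((np.sum(rep[c.direction] > c.llr) + 1) / (R + 1)))
            for c in cands
        ]
        sig_high = [
            c for c in select_clusters(cands, alpha=alpha) if c.direction == "high"
        ]
        if sig_high:
            E_tot = float(g.expected.sum())
            gini = lorenz_gini(
                [c.window.cases / g.C for c in sig_high],
                [c.window.expected / E_tot for c in sig_high],
            )
        else:
            gini = 0.0
        per_frac_clusters.append(tuple(sig_high))
        per_frac_gini.append(gini)

    if any(per_frac_clusters):
        best = int(np.argmax(per_frac_gini))  # argmax takes first => smaller frac on ties
        opt_frac, opt_gini = fracs[best], per_frac_gini[best]
    else:
        opt_frac = opt_gini = None
    return GiniProfile(
        fracs=fracs,
        clusters=tuple(per_frac_clusters),
        gini=tuple(per_frac_gini),
        optimal_frac=opt_frac,
        optimal_gini=opt_gini,
    )


def cluster_table(
    clusters, areas: pd.DataFrame, years: float = 3.0, ndigits: int = 2
) -> pd.DataFrame:
    """Report table for a cluster collection (one row per cluster).

    Columns: direction, rank, center, n_areas, member ids, at-risk
    population, observed (O), expected (E), annual cases per 100,000,
    O/E, RR and the Monte Carlo p-value. RR follows the inside/outside
    risk-ratio definition rr = (c/E_c) / ((C−c)/(C−E_c)).
    """
    C = float(areas["cases"].sum())
    E_tot = float(areas["expected"].sum())
    rows = []
    for cl in clusters:
        w = cl.window
        rows.append(
            {
                "direction": cl.direction,
                "rank": cl.rank,
                "center": w.center_id,
                "n_areas": len(w.member_ids),
                "member_ids": ";".join(str(i) for i in w.member_ids),
                "pop": w.pop,
                "observed": w.cases,
                "expected": round(w.expected, ndigits),
                "annual_per_100k": round(1e5 * w.cases / (w.pop * years), 1),
                "oe": round(w.cases / w.expected, ndigits),
                "rr": round(relative_risk(w.cases, w.expected, C, E_tot), ndigits),
                "llr": cl.llr,
                "p_mc": cl.p_mc,
            }
        )
    return pd.DataFrame(rows)


def relative_risk(c: float, E_c: float, C: float, E_tot: float | None = None) -> float:
    """Risk inside the window relative to outside.

    rr = (c / E_c) / ((C − c) / (C_E − E_c)) with C_E = total expected
    (equal to C under internal standardization).
    """
    if E_tot is None:
        E_tot = C
    if c >= C:
        raise ValueError("relative risk undefined when the window holds all cases")
    if not (0 < E_c < E_tot):
        raise ValueError("window expected count must lie in (0, total expected)")
    return (c / E_c) / ((C - c) / (E_tot - E_c))
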