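"""Purely spatial Poisson scan statistic."""

import numpy as np
import pandas as pd
import pytest

import spatepi as sp
from spatepi.scan import _Geometry

from conftest import random_area_table


def brute_force_best(areas, max_frac):
    """Exhaustive center x radius scan oracle (nested loops, no sharing)."""
    pop = areas["pop"].to_numpy(dtype=float)
    cases = areas["cases"].to_numpy(dtype=float)
    expected = areas["expected"].to_numpy(dtype=float)
    xy = areas[["x", "y"]].to_numpy(dtype=float)
    C = cases.sum()
    cap = max_frac * pop.sum()
    best = {"high": -np.inf, "low": -np.inf}
    n = len(areas)
    for i in range(n):
        d = np.hypot(*(xy - xy[i]).T)
        order = np.lexsort((np.arange(n), d))
        for k in range(1, n + 1):
            members = order[:k]
            if pop[members].sum() > cap * (1 + 1e-12):
                break
            c = cases[members].sum()
            E_c = expected[members].sum()
            llr, direction = sp.poisson_llr(c, E_c, C)
            best[direction] = max(best[direction], llr)
    return best


class TestPoissonLLR:
    def test_zero_when_observed_equals_expected(self):
        assert sp.poisson_llr(5.0, 5.0, 50)[0] == pytest.approx(0.0)

    def test_high_rate_cluster_cells(self):
        llr, direction = sp.poisson_llr(217, 55.37, 3080)
        assert llr == pytest.approx(139.16, abs=0.01)
        assert direction == "high"

    def test_empty_window(self):
        llr, direction = sp.poisson_llr(0, 1.0, 10)
        assert llr == pytest.approx(10 * np.log(10 / 9))
        assert direction == "low"

    def test_scale_equivariance(self):
        """Scaling (c, E, C) by s scales llr by s, preserving the ranking."""
        base, _ = sp.poisson_llr(30, 12.0, 100)
        scaled, _ = sp.poisson_llr(90, 36.0, 300)
        assert scaled == pytest.approx(3 * base)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sp.poisson_llr(1, 0.0, 10)
        with pytest.raises(ValueError):
            sp.poisson_llr(1, 10.0, 10)


class TestRelativeRisk:
    def test_published_high_primary(self):
        assert round(sp.relative_risk(217, 55.37, 3080), 2) == 4.14

    def test_published_low_secondary(self):
        assert round(sp.relative_risk(27, 118.50, 3080), 2) == 0.22

    def test_unity_when_rates_equal(self):
        # window holding half the cases and half the expectation
        assert sp.relative_risk(50, 50.0, 100) == pytest.approx(1.0)

    def test_all_cases_in_window_rejected(self):
        with pytest.raises(ValueError):
            sp.relative_risk(10, 5.0, 10)


class TestEnumerateWindows:
    def test_singletons_only_when_cap_tiny(self):
        rng = np.random.default_rng(1)
        areas = random_area_table(rng, 8)
        areas["pop"] = 100.0
        areas = sp.compute_expected(areas)
        D = sp.pairwise_distances(areas)
        wins = sp.enumerate_windows(areas, D, max_frac=1.5 / 8)
        assert len(wins) == 8
        assert all(len(w.member_ids) == 1 for w in wins)

    def test_collinear_equal_pop_example(self):
        areas = pd.DataFrame({"id": [0, 1, 2, 3], "x": [0.0, 1, 2, 3], "y": 0.0,
                              "pop": 1.0, "cases": [1, 1, 1, 1]})
        areas = sp.compute_expected(areas)
        D = sp.pairwise_distances(areas)
        wins = sp.enumerate_windows(areas, D, max_frac=0.5)
        sets = {frozenset(w.member_ids) for w in wins}
        assert sets == {frozenset(s) for s in
                        [{0}, {1}, {2}, {3}, {0, 1}, {1, 2}, {2, 3}]}

    def test_windows_nest(self):
        rng = np.random.default_rng(4)
        areas = sp.compute_expected(random_area_table(rng, 12))
        D = sp.pairwise_distances(areas)
        wins = sp.enumerate_windows(areas, D, max_frac=0.5)
        sets = {frozenset(w.member_ids) for w in wins}
        for w in wins:
            if len(w.member_ids) > 1:
                assert frozenset(w.member_ids[:-1]) in sets
            assert w.center_id in w.member_ids

    def test_empty_input_rejected(self):
        areas = pd.DataFrame(columns=["id", "x", "y", "pop", "cases", "expected"])
        with pytest.raises(ValueError):
            sp.enumerate_windows(areas, sp.DistanceMatrix((), np.zeros((0, 0))), 0.3)


class TestScanInference:
    def test_max_llr_matches_bruteforce_both_directions(self):
        rng = np.random.default_rng(77)
        for rep in range(8):
            areas = sp.compute_expected(random_area_table(rng, 15))
            D = sp.pairwise_distances(areas)
            g = _Geometry(areas, D, 0.5)
            llr, high = g.observed_llr()
            llr = np.where(g.mask, llr, -np.inf)
            got_high = np.where(high, llr, -np.inf).max()
            got_low = np.where(~high, llr, -np.inf).max()
            oracle = brute_force_best(areas, 0.5)
            assert got_high == pytest.approx(oracle["high"])
            assert got_low == pytest.approx(oracle["low"])

    def test_relabeling_invariance_of_max(self):
        rng = np.random.default_rng(12)
        areas = sp.compute_expected(random_area_table(rng, 12))
        shuffled = areas.sample(frac=1, random_state=5).reset_index(drop=True)
        shuffled["id"] = np.arange(12)[::-1][np.argsort(shuffled.index)]  # new labels
        shuffled = shuffled.sort_values("id").reset_index(drop=True)
        for df in (areas, shuffled):
            df.sort_values("id", inplace=True)
        b1 = brute_force_best(areas, 0.5)
        b2 = brute_force_best(shuffled, 0.5)
        assert b1["high"] == pytest.approx(b2["high"])
        assert b1["low"] == pytest.approx(b2["low"])

    def test_pvalue_bounds_and_seed_determinism(self, small_study):
        sir, _ = small_study
        D = sp.pairwise_distances(sir)
        r1 = sp.scan(sir, D, max_frac=0.3, R=99, seed=5)
        r2 = sp.scan(sir, D, max_frac=0.3, R=99, seed=5)
        assert [c.p_mc for c in r1.clusters] == [c.p_mc for c in r2.clusters]
        for c in r1.all_candidates:
            assert 1 / 100 <= c.p_mc <= 1.0
        np.testing.assert_array_equal(r1.rep_max_high, r2.rep_max_high)

    def test_select_clusters_ranking_and_nonoverlap(self):
        def mk(members, llr, p=0.001, direction="high"):
            w = sp.ScanWindow(members[0], 1.0, tuple(members), 10, 5, 100)
            return sp.ScanCluster(w, llr, direction, oe=2.0, p_mc=p)

        a = mk([1, 2], 10.0)
        b = mk([2, 3], 8.0)   # overlaps a -> dropped
        c = mk([4], 6.0)
        d = mk([5], 4.0, p=0.2)  # not significant
        picked = sp.select_clusters([a, b, c, d], alpha=0.05)
        assert [(cl.rank, cl.window.member_ids) for cl in picked] == [
            (1, (1, 2)), (2, (4,))]

    def test_implanted_cluster_detected(self):
        spec = sp.SimulationSpec(n_rows=10, n_cols=10, total_cases=600.0,
                                 implants=((44, 5, 4.0),), seed=33)
        areas, edges, truth = sp.simulate_study(spec)
        sir = sp.compute_raw_sir(sp.compute_expected(areas))
        D = sp.pairwise_distances(sir)
        res = sp.scan(sir, D, max_frac=0.2, R=99, seed=1)
        primary = [c for c in res.clusters if c.direction == "high" and c.rank == 1]
        assert primary
        mem = set(primary[0].window.member_ids)
        th = set(truth[0]["member_ids"])
        assert len(mem & th) / len(mem | th) >= 0.6
        assert primary[0].p_mc == pytest.approx(1 / 100)


class TestGini:
    def test_single_cluster_trapezoid(self):
        assert sp.lorenz_gini([0.5], [0.1]) == pytest.approx(0.4)

    def test_no_clusters_zero(self):
        assert sp.lorenz_gini([], []) == 0.0

    def test_profile_prefers_tight_cluster_size(self):
        """With one tight implant the optimum stays near its population share."""
        spec = sp.SimulationSpec(n_rows=12, n_cols=12, total_cases=1000.0,
                                 implants=((66, 6, 4.0),), seed=9)
        areas, edges, truth = sp.simulate_study(spec)
        sir = sp.compute_raw_sir(sp.compute_expected(areas))
        D = sp.pairwise_distances(sir)
        fracs = (0.05, 0.1, 0.2, 0.3, 0.5)
        prof = sp.gini_select(sir, D, candidate_fracs=fracs, R=99, seed=2)
        assert prof.optimal_frac is not None
        share = sir.set_index("id").loc[truth[0]["member_ids"], "pop"].sum() / sir["pop"].sum()
        # optimum within one candidate step of the implant's population share
        bigger = [f for f in fracs if f >= share]
        assert prof.optimal_frac <= (bigger[0] if bigger else 0.5) + 1e-9
        assert 0 <= prof.optimal_gini <= 1

    def test_cluster_table_shape_and_rounding(self, small_study):
        sir, _ = small_study
        D = sp.pairwise_distances(sir)
        res = sp.scan(sir, D, max_frac=0.3, R=99, seed=5, years=3.0)
        tab = sp.cluster_table(res.clusters, sir, years=3.0)
        if len(tab):
            assert {"direction", "rank", "pop", "observed", "expected",
                    "annual_per_100k", "oe", "rr", "p_mc"} <= set(tab.columns)
            assert (tab["oe"].round(2) == tab["oe"]).all()
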