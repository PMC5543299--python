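"""End-to-end pipeline: simulate → SIR → SEB → BYM → scan → report.

A run is configured by a YAML file (see ``spatepi/data/default_profile.yaml``)
with blocks for the simulation profile (or paths to real area/edge files),
the contiguity weights, Moran's I, the BYM sampler and the scan. Outputs are
plain text: ``sir.csv``, ``sir_seb.csv``, ``sir_bym.csv``, ``clusters.csv``,
``moran.json``, ``diagnostics.json``, a log file, and the fully resolved
configuration echoed back for provenance.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .bym import BYMPriors, MCMCConfig, fit_bym, summarize_posterior
from .incidence import compute_expected, compute_raw_sir, morans_i
from .scan import cluster_table, gini_select, scan
from .seb import seb_smooth
from .simulate import SimulationSpec, simulate_study
from .weights import build_weights, pairwise_distances

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """The shipped emulation profile as a config dict."""
    text = (
        importlib.resources.files("spatepi").joinpath("data/default_profile.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_config(path=None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key] = {**base[key], **val}
        else:
            base[key] = val
    return base


def run_pipeline(config: dict, out_dir, skip_bym: bool = False) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    Returns a summary dict of headline numbers (also echoed to the log).
    On stage failure, outputs written so far are preserved and the failing
    stage is logged before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("spatepi")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    stage = "configure"
    try:
        (out / "config.resolved.yaml").write_text(yaml.safe_dump(config))
        seed = int(config.get("seed", 0))

        stage = "input"
        if config.get("areas_csv"):
            areas = spio.read_area_table(config["areas_csv"])
            edges = spio.read_edges(config["edges_csv"])
            truth: dict = {}
            years = float(config.get("scan", {}).get("years", 1.0))
        else:
            sim = dict(config["simulation"])
            sim.setdefault("seed", seed)
            years = float(sim.pop("years", 3.0))
            spec = SimulationSpec.from_dict(sim)
            areas, edges, truth = simulate_study(spec)
            spio.write_area_table(areas, out / "areas.csv")
            spio.write_edges(edges, out / "edges.csv")
            spio.write_json(truth, out / "truth.json")
        logger.info("input: %d areas, %d edges, %d cases",
                    len(areas), len(edges), int(areas["cases"].sum()))

        stage = "sir"
        sir = compute_raw_sir(compute_expected(areas))
        sir.to_csv(out / "sir.csv", index=False)

        stage = "weights"
        wcfg = config.get("weights", {})
        ids = list(sir["id"])
        edge_iter = list(edges.itertuples(index=False, name=None))
        W1 = build_weights(edge_iter, ids, order=1)
        W = build_weights(
            edge_iter,
            ids,
            order=int(wcfg.get("order", 2)),
            include_lower=bool(wcfg.get("include_lower", True)),
        )

        stage = "moran"
        mcfg = config.get("moran", {})
        xvar = mcfg.get("variable", "cases")
        mres = morans_i(
            sir[xvar].to_numpy(dtype=float), W1,
            n_perm=int(mcfg.get("n_perm", 999)), seed=seed,
        )
        spio.write_json(dataclasses.asdict(mres), out / "moran.json")
        logger.info("Moran's I(%s) = %.4f (p = %.4f)", xvar, mres.I, mres.p_perm)

        stage = "seb"
        seb = seb_smooth(sir, W)
        seb.to_csv(out / "sir_seb.csv", index=False)

        diagnostics: dict = {"moran": dataclasses.asdict(mres)}
        if not skip_bym:
            stage = "bym"
            bcfg = config.get("bym", {})
            priors = BYMPriors(
                a_v=float(bcfg.get("a_v", 0.5)), b_v=float(bcfg.get("b_v", 0.005)),
                a_u=float(bcfg.get("a_u", 0.5)), b_u=float(bcfg.get("b_u", 0.5)),
            )
            mc = MCMCConfig(
                n_iter=int(bcfg.get("n_iter", 20000)),
                n_burn=int(bcfg.get("n_burn", 4000)),
                n_chains=int(bcfg.get("n_chains", 2)),
                thin=int(bcfg.get("thin", 10)),
                seed=seed,
            )
            post = fit_bym(sir, W1, priors, mc)
            bym_summary = summarize_posterior(post)
            bym_summary.to_csv(out / "sir_bym.csv", index=False)
            diagnostics["bym_rhat"] = post.rhat
            diagnostics["bym_acceptance"] = post.acceptance
            logger.info("BYM rhat: %s", {k: round(v, 3) for k, v in post.rhat.items()})

        stage = "scan"
        scfg = config.get("scan", {})
        D = pairwise_distances(sir)
        reps = int(scfg.get("reps", 999))
        alpha = float(scfg.get("alpha", 0.05))
        if scfg.get("gini", True):
            profile = gini_select(sir, D, R=reps, seed=seed, alpha=alpha)
            diagnostics["gini"] = {
                "fracs": list(profile.fracs),
                "gini": list(profile.gini),
                "optimal_frac": profile.optimal_frac,
                "optimal_gini": profile.optimal_gini,
            }
            max_frac = profile.optimal_frac or float(scfg.get("max_frac", 0.5))
        else:
            max_frac = float(scfg.get("max_frac", 0.5))
        result = scan(sir, D, max_frac=max_frac, R=reps, seed=seed, alpha=alpha, years=years)
        table = cluster_table(result.clusters, sir, years=years)
        table.to_csv(out / "clusters.csv", index=False)
        spio.clusters_to_geojson(result.clusters, sir, out / "clusters.geojson")
        diagnostics["scan"] = {"max_frac": max_frac, "n_windows": result.n_windows,
                               "n_clusters": len(result.clusters)}
        spio.write_json(diagnostics, out / "diagnostics.json")

        summary = {
            "n_areas": len(sir),
            "total_cases": int(sir["cases"].sum()),
            "moran_i": mres.I,
            "moran_p": mres.p_perm,
            "n_clusters": len(result.clusters),
            "truth": truth,
        }
        if "gini" in diagnostics:
            summary["optimal_frac"] = diagnostics["gini"]["optimal_frac"]
            summary["optimal_gini"] = diagnostics["gini"]["optimal_gini"]
        logger.info("pipeline complete: %s", json.dumps({k: v for k, v in summary.items() if k != "truth"}, default=float))
        return summary
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
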