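"""Spatial empirical Bayes (Marshall) smoothing of standardized incidence ratios.

Each area's raw SIR is shrunk toward the mean of a local reference window —
the area itself plus its contiguity neighbours (typically second-order queen,
lower orders included). Prior moments are method-of-moments estimates from
the window (Marshall's local empirical Bayes estimator, the spatial rate
smoother GeoDa ships). Smoothing operates on the SIR scale with the expected
count E_i as the exposure, so the output is directly comparable to the raw
SIR and to BYM posterior relative risks; pass ``value_col``/``exposure_col``
to smooth crude rates with population exposure instead.

For window R_i = {i} ∪ neighbours(i):

    m_i  = Σ_{j∈R_i} O_j / Σ_{j∈R_i} E_j                      (local mean)
    s²_i = Σ_{j∈R_i} E_j (sir_j − m_i)² / Σ_{j∈R_i} E_j
           − m_i / (Σ_{j∈R_i} E_j / |R_i|)                     (prior variance,
                                                                truncated at 0)
    C_i  = s²_i / (s²_i + m_i / E_i)                           (shrink factor)
    sir_seb_i = m_i + C_i (sir_i − m_i)

A negative moment estimate of the prior variance truncates to zero, i.e. full
shrinkage to the local mean. With the reference window set to all areas the
estimator degenerates to global (aspatial) empirical Bayes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .weights import WeightsMatrix


def seb_smooth(
    sir_table: pd.DataFrame,
    W: WeightsMatrix,
    count_col: str = "cases",
    exposure_col: str = "expected",
) -> pd.DataFrame:
    """Marshall local-EB smoothing of ``count_col / exposure_col`` ratios.

    Parameters
    ----------
    sir_table : DataFrame
        Area table with ``id``, ``count_col`` and ``exposure_col`` columns,
        in the same id order as ``W.area_ids``.
    W : WeightsMatrix
        Contiguity weights defining the local reference windows (self always
        included). An island still has a nonempty window (itself), but then
        the prior variance estimate is degenerate; islands are permitted.

    Returns
    -------
    DataFrame with added columns ``local_mean``, ``shrink_factor`` and
    ``sir_seb`` (plus ``sir`` if absent).
    """
    df = sir_table.copy()
    if tuple(df["id"]) != tuple(W.area_ids):
        raise ValueError("area table and weights matrix must list the same ids in the same order")
    O = df[count_col].to_numpy(dtype=float)
    E = df[exposure_col].to_numpy(dtype=float)
    if np.any(E <= 0):
        bad = df["id"].iloc[int(np.argmin(E))]
        raise ValueError(f"nonpositive exposure for area {bad!r}")
    sir = O / E

    n = W.n
    R = W.W.astype(float) + np.eye(n)  # reference set: self + neighbours
    size = R.sum(axis=1)
    sumO = R @ O
    sumE = R @ E
    m = sumO / sumE
    # exposure-weighted second moment about the local mean
    wss = (R * (sir[None, :] - m[:, None]) ** 2) @ E
    s2 = wss / sumE - m / (sumE / size)
    s2 = np.maximum(s2, 0.0)
    with np.errstate(invalid="ignore"):
        C = s2 / (s2 + m / E)
    C = np.where((s2 == 0) & (m == 0), 0.0, C)  # all-zero window: stay at 0
    smoothed = m + C * (sir - m)

    df["sir"] = sir
    df["local_mean"] = m
    df["shrink_factor"] = C
    df["sir_seb"] = smoothed
    return df
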