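"""Raw standardized incidence ratios and Moran's I.

The area table is a plain :class:`pandas.DataFrame` with one row per
neighbourhood and columns

``id``     unique area identifier
``x, y``   planar centroid coordinates
``pop``    women (persons) at risk, n_i > 0
``cases``  observed case count O_i >= 0

Internal standardization distributes the study-wide total caseload over the
areas in proportion to population: E_i = n_i * (sum O / sum n), so the
expected counts always sum to the observed total and SIR_i = O_i / E_i is
the area's incidence relative to the study average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .weights import WeightsMatrix

logger = logging.getLogger(__name__)

AREA_COLUMNS = ("id", "x", "y", "pop", "cases")


def validate_area_table(areas: pd.DataFrame, drop_zero_pop: bool = True) -> pd.DataFrame:
    """Check the area-table contract; optionally drop zero-population areas.

    Returns a validated copy sorted by id. Areas with ``pop == 0`` cannot be
    standardized; they are dropped with a warning rather than silently.
    """
    missing = [c for c in AREA_COLUMNS if c not in areas.columns]
    if missing:
        raise ValueError(f"area table missing required column(s): {missing}")
    df = areas.copy()
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate area id(s): {dups}")
    if (df["cases"] < 0).any():
        raise ValueError("case counts must be nonnegative")
    if (df["pop"] < 0).any():
        raise ValueError("populations must be nonnegative")
    zero = df["pop"] == 0
    if zero.any():
        if not drop_zero_pop:
            raise ValueError("areas with zero population present")
        dropped = df.loc[zero, "id"].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-population area(s): {dropped}")
        logger.warning("dropping zero-population areas: %s", dropped)
        df = df.loc[~zero]
    return df.sort_values("id", kind="stable").reset_index(drop=True)


def compute_expected(areas: pd.DataFrame) -> pd.DataFrame:
    """Internally standardized expected counts.

    Adds an ``expected`` column with E_i = n_i * (sum_i O_i / sum_i n_i).
    The identity sum(E) == sum(O) holds to numerical tolerance.
    """
    df = validate_area_table(areas)
    total_pop = float(df["pop"].sum())
    total_cases = float(df["cases"].sum())
    if total_pop <= 0:
        raise ValueError("total population is zero")
    if total_cases <= 0:
        raise ValueError("no observed cases to standardize against")
    df["expected"] = df["pop"].to_numpy(dtype=float) * total_cases / total_pop
    return df


def compute_raw_sir(sir_table: pd.DataFrame) -> pd.DataFrame:
    """Raw SIR_i = O_i / E_i. Requires the ``expected`` column."""
    if "expected" not in sir_table.columns:
        raise ValueError("run compute_expected first: 'expected' column missing")
    df = sir_table.copy()
    E = df["expected"].to_numpy(dtype=float)
    if np.any(E <= 0):
        bad = df["id"].iloc[int(np.argmin(E))]
        raise ValueError(f"nonpositive expected count for area {bad!r}")
    df["sir"] = df["cases"].to_numpy(dtype=float) / E
    return df


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with two-sided permutation inference.

    ``E_I = -1/(N-1)`` is the exact permutation-null expectation; the p-value
    counts permutations at least as extreme as observed around that centre,
    with the +1 correction, so ``p in [1/(n_perm+1), 1]``.
    """

    I: float
    E_I: float
    p_perm: float
    n_perm: int


def morans_i(
    x: np.ndarray,
    W: WeightsMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    row_standardize: bool = False,
) -> MoranResult:
    """Moran's I of per-area values ``x`` under contiguity weights ``W``.

    I = (N/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2  with z = x - mean(x) and
    S0 = sum_ij w_ij. Inference is by random permutation of the values over
    the areas (two-sided around E_I).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != W.n:
        raise ValueError("x must be 1-d with one value per area")
    if len(x) < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("x is constant: Moran's I undefined")
    Wmat = W.W.astype(float)
    if row_standardize:
        rs = Wmat.sum(axis=1, keepdims=True)
        nz = rs.ravel() > 0
        Wmat = Wmat.copy()
        Wmat[nz] = Wmat[nz] / rs[nz]
    S0 = float(Wmat.sum())
    if S0 == 0:
        raise ValueError("weights matrix has no edges")
    Wsp = sparse.csr_matrix(Wmat)
    N = len(x)

    def stat(zv: np.ndarray) -> float:
        return (N / S0) * float(zv @ (Wsp @ zv)) / denom

    I_obs = stat(z)
    E_I = -1.0 / (N - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(stat(zp) - E_I) >= abs(I_obs - E_I):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MoranResult(I=I_obs, E_I=E_I, p_perm=p, n_perm=n_perm)
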