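import numpy as np
import pandas as pd
import pytest

import spatepi as sp


@pytest.fixture
def path4_weights():
    """Path graph 0-1-2-3, first-order binary contiguity."""
    return sp.build_weights([(0, 1), (1, 2), (2, 3)], [0, 1, 2, 3])


@pytest.fixture
def triangle_table():
    """Three mutually adjacent areas with O=[0,5,10], E=[5,5,5]."""
    areas = pd.DataFrame(
        {
            "id": [0, 1, 2],
            "x": [0.0, 0.0, 1.0],
            "y": [0.0, 1.0, 0.0],
            "pop": [1.0, 1.0, 1.0],
            "cases": [0, 5, 10],
            "expected": [5.0, 5.0, 5.0],
        }
    )
    W = sp.build_weights([(0, 1), (0, 2), (1, 2)], [0, 1, 2])
    return areas, W


@pytest.fixture
def small_study():
    """A small synthetic study (10x10 lattice, no implants), deterministic."""
    spec = sp.SimulationSpec(
        n_rows=10, n_cols=10, total_cases=800.0, implants=(), seed=42
    )
    areas, edges, _ = sp.simulate_study(spec)
    sir = sp.compute_raw_sir(sp.compute_expected(areas))
    return sir, edges


def random_area_table(rng, n, max_cases=20):
    """Random planar area table with positive expected counts."""
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": rng.uniform(0, 10, n),
            "y": rng.uniform(0, 10, n),
            "pop": rng.uniform(50, 500, n),
            "cases": rng.integers(0, max_cases, n),
        }
    )
    if df["cases"].sum() == 0:
        df.loc[0, "cases"] = 1
    return df
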