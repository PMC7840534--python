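import numpy as np
import pandas as pd
import pytest

import pollsel
from pollsel import synthetic_data as sd


@pytest.fixture(scope="session")
def rates():
    return dict(pollsel.ALFALFA_TRIPPING_RATES)


@pytest.fixture(scope="session")
def calibration_dataset():
    """N=153 alfalfa-calibrated fixture: plants (+seeds), visits, truth."""
    plants, visits, truth = pollsel.simulate_dataset(
        sd.alfalfa_trait_model(),
        sd.alfalfa_preference_model(),
        sd.alfalfa_yield_model(noisy=True),
        n_plants=153,
        seed=20260905,
    )
    return plants, visits, truth


@pytest.fixture()
def toy_visits():
    """Three plants, three species, hand-checkable counts."""
    return pd.DataFrame(
        {
            "plant_id": [1, 1, 1, 2, 3],
            "species": ["bumble", "honey", "leafcutting", "bumble", "honey"],
            "flowers_visited": [10, 10, 5, 7, 4],
        }
    )


def brute_force_transport_cost(x, p, y, q):
    """Independent oracle: discrete 1-D optimal transport cost by linear programming.

    Minimizes sum_ij |x_i - y_j| f_ij subject to marginals p and q.  Kept
    deliberately independent of the package's sorted-CDF implementation.
    """
    from scipy.optimize import linprog

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :]).reshape(-1)
    # row-sum constraints (supply) and column-sum constraints (demand)
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.status == 0, res.message
    return float(res.fun)
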