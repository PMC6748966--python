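import numpy as np
import pytest

from omifuse import (
    OmicsDataset,
    simulate_cnv_matrix,
    simulate_regulation_data,
    solve_penalized_logistic,
    solve_penalized_regulation,
)
from omifuse.simulate import RegulationSimSpec


def make_logistic_pair(seed: int, n: int = 20, p: int = 4, beta_scale: float = 1.0):
    """Small paired case/control datasets with a planted logistic signal."""
    rng = np.random.default_rng(seed)
    datasets = []
    for k in range(2):
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[: max(1, p // 2)] = beta_scale * rng.choice([-1.0, 1.0], max(1, p // 2))
        lp = X @ beta
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        if y.min() == y.max():  # ensure both classes
            y[0] = 1 - y[0]
        datasets.append(
            OmicsDataset(
                sample_ids=[f"s{k}_{i}" for i in range(n)],
                gene_ids=[f"g{j}" for j in range(p)],
                X=X,
                y=y,
                group_label="bipolar" if k == 0 else "schizophrenia",
            )
        )
    return datasets[0], datasets[1]


def make_regulation_pair(seed: int, n: int = 20, p: int = 4):
    """Small paired expression/CNV datasets from the sparse linear model."""
    Z1 = simulate_cnv_matrix(n, p, seed)
    Z2 = simulate_cnv_matrix(n, p, seed + 1)
    spec = RegulationSimSpec(regulated_fraction=0.5, n_shared=2)
    return simulate_regulation_data(spec, Z1, Z2, seed + 2)


@pytest.fixture(scope="session")
def compiled_solvers():
    """Trigger numba compilation once so individual tests time only their work."""
    d1, d2 = make_logistic_pair(0)
    solve_penalized_logistic(d1, d2, 0.1, 0.5, penalty="magnitude", max_sweeps=5)
    solve_penalized_logistic(d1, d2, 0.1, 0.5, penalty="sign", max_sweeps=5)
    r1, r2, _ = make_regulation_pair(0)
    solve_penalized_regulation(r1, r2, 0.5, 0.1, penalty="magnitude", max_sweeps=5)
    solve_penalized_regulation(r1, r2, 0.5, 0.1, penalty="sign", max_sweeps=5)
    return True
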