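import numpy as np
import pandas as pd
import pytest

from fqgdemar import factorial
from fqgdemar.io_formats import ExpressionMatrix, code_design
from fqgdemar.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced cohort: fast to simulate, same statistical structure."""
    return SimulationConfig(n_probes=4000, n_genes=3000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_expression(small_cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Full-size default synthetic cohort (shared across the heavy tests)."""
    return simulate_expression(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_effects(default_sim):
    matrix, design, _ = default_sim
    return factorial.effect_table(matrix, design)


@pytest.fixture()
def toy_matrix_design():
    """Hand-built 4-probe matrix over a balanced 2x2 design (3 per cell)."""
    rng = np.random.default_rng(5)
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(12)],
            "age_years": [30] * 6 + [80] * 6,
            "sex": (["m"] * 3 + ["f"] * 3) * 2,
        }
    )
    design = code_design(meta)
    values = pd.DataFrame(
        rng.normal(7, 1, size=(4, 12)),
        index=[f"p{i}" for i in range(4)],
        columns=meta["sample_id"],
    )
    return ExpressionMatrix(values=values), design


def random_matrix_design(n_probes, seed, cell_sizes=(3, 4, 5, 4)):
    """Unbalanced random fixture for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for (age, sex), size in zip(
        [(30, "m"), (30, "f"), (80, "m"), (80, "f")], cell_sizes
    ):
        for _ in range(size):
            rows.append({"sample_id": f"s{k}", "age_years": age, "sex": sex})
            k += 1
    meta = pd.DataFrame(rows)
    design = code_design(meta)
    values = pd.DataFrame(
        rng.normal(7, 1.5, size=(n_probes, k)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=meta["sample_id"],
    )
    return ExpressionMatrix(values=values), design
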