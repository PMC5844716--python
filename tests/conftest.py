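import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hubnet.diffexpr import CONTROL, EXPERIMENTAL, ExpressionMatrix
from hubnet.simulate import SimulationConfig, simulate_expression


def small_matrix(values: dict[str, list[float]], n_per_group: int = 3) -> ExpressionMatrix:
    """Build a matrix from gene -> intensities (ctrl block then exp block)."""
    samples = [f"c{i}" for i in range(n_per_group)] + [f"e{i}" for i in range(n_per_group)]
    groups = pd.Series([CONTROL] * n_per_group + [EXPERIMENTAL] * n_per_group, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=samples).T, groups)


@pytest.fixture(scope="session")
def noisefree_config() -> SimulationConfig:
    """Planted structure with zero noise and no background interaction edges."""
    return SimulationConfig(
        n_genes=800,
        de_fraction=0.15,
        noise_sd_log2=0.0,
        random_edge_rate=0.0,
        n_terms=20,
        enriched_terms=6,
        hub_spec=[(None, 10, 0.9), (None, 8, 0.9), (None, 6, 0.9)],
        seed=7,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed-pinned)."""
    config = SimulationConfig(seed=1)
    matrix, truth = simulate_expression(config)
    return config, matrix, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
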