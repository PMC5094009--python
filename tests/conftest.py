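import numpy as np
import pandas as pd
import pytest

from hbxprof import (
    call_expression,
    generate_staged_series,
    generate_tissue_panel,
    normalize_to_max,
)


@pytest.fixture(scope="session")
def human_panel():
    return generate_tissue_panel(seed=11)


@pytest.fixture(scope="session")
def mouse_series():
    return generate_staged_series(seed=7)


@pytest.fixture(scope="session")
def called_panel(human_panel):
    return call_expression(human_panel.matrix)


@pytest.fixture(scope="session")
def norm_panel(called_panel):
    return normalize_to_max(called_panel)


def random_matrix(seed, n_genes=50, n_samples=20, scale=10.0, zero_fraction=0.4):
    """Random non-negative FPKM-like matrix with a controlled zero fraction."""
    rng = np.random.default_rng(seed)
    values = rng.exponential(scale, size=(n_genes, n_samples))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )


@pytest.fixture
def matrix_factory():
    return random_matrix
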