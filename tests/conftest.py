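import numpy as np
import pandas as pd
import pytest

from coexdiff import preprocess, simulate


@pytest.fixture(scope="session")
def default_fixture():
    """One default-condition region fixture: (truth, counts)."""
    config = simulate.SimulationConfig(seed=1)
    truth = simulate.generate_truth(config)
    counts = simulate.simulate_expression(truth)
    return truth, counts


@pytest.fixture(scope="session")
def default_expr(default_fixture):
    _, counts = default_fixture
    return preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))


def make_count_matrix(array, lines=None, genes=None, samples=None):
    """Small helper to build a validated CountMatrix from a 2D array."""
    array = np.asarray(array)
    n_genes, n_samples = array.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    lines = lines or ["High"] * (n_samples // 2) + ["Low"] * (n_samples - n_samples // 2)
    meta = pd.DataFrame(
        {"line": lines, "region": "R1", "sex": (["F", "M"] * n_samples)[:n_samples]},
        index=samples,
    )
    counts = pd.DataFrame(array, index=genes, columns=samples)
    return preprocess.CountMatrix(counts, meta)


def make_expr(values, lines=None, genes=None, samples=None):
    """Build an ExprMatrix directly from log2-scale values."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    lines = lines or ["High"] * (n_samples // 2) + ["Low"] * (n_samples - n_samples // 2)
    meta = pd.DataFrame(
        {"line": lines, "region": "R1", "sex": (["F", "M"] * n_samples)[:n_samples]},
        index=samples,
    )
    vals = pd.DataFrame(values, index=genes, columns=samples)
    return preprocess.ExprMatrix(vals, pd.Series(1.0, index=samples), meta)
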