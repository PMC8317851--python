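import numpy as np
import pandas as pd
import pytest

from survgate import (
    ExpressionMatrix,
    ClinicalTable,
    normalize_expression,
)
from survgate.simulate import SimulationConfig, simulate_cohort, simulate_toy_fixture


@pytest.fixture(scope="session")
def toy():
    """Fixed 12-sample / 8-gene cohort with hand-checkable survival values."""
    return simulate_toy_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-signal cohort small enough for fast end-to-end tests."""
    cfg = SimulationConfig(
        n_samples=200, n_genes=300, n_informative_g1=20, n_informative_g2=40,
        effect_size=3.0, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_norm(small_cohort):
    return normalize_expression(small_cohort.expr)


@pytest.fixture()
def tiny_expr():
    values = np.array([[2.0, 4.0, 6.0], [5.0, 5.0, 5.0], [0.0, 0.5, 1.0]])
    return ExpressionMatrix(["gA", "gB", "gC"], ["s1", "s2", "s3"], values)


@pytest.fixture()
def tiny_clin():
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "os_time": [100.0, 200.0, 300.0, 400.0],
        "os_event": [1, 0, 1, 0],
        "mycn": [1, 0, 1, 0],
    }))
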