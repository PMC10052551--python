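import numpy as np
import pandas as pd
import pytest

from drivergnn.features import compute_feature_matrix
from drivergnn.io import ExpressionMatrix
from drivergnn.simulate import SimulationSpec, simulate_bundle


@pytest.fixture(scope="session")
def default_sim():
    """The default planted-driver instance (2000 genes, 200T/30N, 50 drivers)."""
    return simulate_bundle(SimulationSpec())


@pytest.fixture(scope="session")
def default_features(default_sim):
    return compute_feature_matrix(
        default_sim.bundle, default_sim.ppi, default_sim.cprg
    )


@pytest.fixture(scope="session")
def small_sim():
    """A reduced instance for fast unit tests."""
    return simulate_bundle(
        SimulationSpec(n_genes=300, n_tumor=40, n_normal=10, n_drivers=12, n_cprg=40, seed=7)
    )


@pytest.fixture(scope="session")
def small_features(small_sim):
    return compute_feature_matrix(small_sim.bundle, small_sim.ppi, small_sim.cprg)


def make_expression(values, tumor, normal, genes=None):
    """Build an ExpressionMatrix from a 2D array and sample counts."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"t{i}" for i in range(tumor)] + [f"n{i}" for i in range(normal)]
    group = {s: ("tumor" if s.startswith("t") else "normal") for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), group=group
    )


@pytest.fixture
def expr_factory():
    return make_expression
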