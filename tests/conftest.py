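import numpy as np
import pytest
import scipy.sparse as sp

from rareclust import CountMatrix, RunConfig, generate, run_on_matrix, standard_design


@pytest.fixture(scope="session")
def standard_data():
    """The standard planted-cluster fixture (seed 0)."""
    return generate(standard_design(0))


@pytest.fixture(scope="session")
def pipeline_result(standard_data):
    """Full pipeline run on the standard fixture, shared across tests."""
    return run_on_matrix(standard_data.counts, RunConfig(seed=0))


@pytest.fixture
def tiny_counts():
    """4 cells x 3 genes; gene g3 expressed in a single cell."""
    values = np.array(
        [
            [4, 1, 0],
            [2, 3, 0],
            [0, 5, 2],
            [1, 2, 0],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(values),
        [f"c{i}" for i in range(4)],
        ["g1", "g2", "g3"],
    )
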