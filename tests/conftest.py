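import numpy as np
import pytest

import mtis


@pytest.fixture(scope="session")
def smoke_data():
    """Small three-group dataset shared by fast tests."""
    return mtis.simulate_dataset(mtis.preset("smoke"))


@pytest.fixture(scope="session")
def smoke_model(smoke_data):
    cg, _, _ = smoke_data
    return mtis.MTISEncoder(epochs=60, random_state=0).fit(cg)


@pytest.fixture
def toy_counts():
    """2 cells x 3 genes with distinct entries."""
    return mtis.CellGeneMatrix(
        ["c1", "c2"], ["G1", "G2", "G3"], np.array([[0, 1, 5], [2, 0, 3]])
    )
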