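import numpy as np
import pandas as pd
import pytest

from primmus.pipeline import build_mitotic_matrix
from primmus.simulate import SimulationConfig, simulate_phosphosites


@pytest.fixture(scope="session")
def mitotic_config():
    return SimulationConfig(seed=1, n_cells=20_000)


@pytest.fixture(scope="session")
def mitotic_data(mitotic_config):
    """Merged 3-replicate mitotic matrix (2 SILAC + 1 TMT) with ground truth."""
    return build_mitotic_matrix(mitotic_config)


@pytest.fixture(scope="session")
def phospho_data():
    cfg = SimulationConfig(seed=7)
    return simulate_phosphosites(cfg)


@pytest.fixture()
def small_matrix():
    """Tiny hand-built (fraction, replicate) profile matrix."""
    cols = pd.MultiIndex.from_product(
        [["G1", "S", "G2", "M"], ["r1", "r2"]], names=["fraction", "replicate"])
    data = np.array([
        [0.8, 0.8, 1.0, 1.0, 1.2, 1.2, 1.3, 1.3],
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    ])
    return pd.DataFrame(data, index=pd.Index(["P1", "P2"], name="protein_id"),
                        columns=cols)
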