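import numpy as np
import pytest

from cytonet.embedding import EmbeddedNetwork, TrainParams, WalkParams, embed_network
from cytonet.netio import filter_high_confidence, select_universe
from cytonet.synthetic import make_world


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world: 4 modules of 30 genes, all cytokine-hosting,
    12 diseases (half enriched)."""
    return make_world(
        n_modules=4,
        module_size=30,
        n_diseases=12,
        bin_mix=(0.5, 0.5, 0.0, 0.0),
        max_set_size=19,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_emb(small_world):
    """Embedding of the small world's high-confidence subnetwork."""
    high = filter_high_confidence(small_world.network, 800)
    return embed_network(high, WalkParams(seed=7), TrainParams(seed=7))


@pytest.fixture(scope="session")
def small_universe(small_world):
    return select_universe(filter_high_confidence(small_world.network, 800))


@pytest.fixture
def toy_emb():
    """Hand-built embedding with known geometry (unit axes and a diagonal)."""
    genes = ("A", "B", "C", "D")
    m = np.zeros((4, 8))
    m[0, 0] = 1.0  # A = e0
    m[1, 0] = 1.0  # B = e0 (identical to A)
    m[2, 1] = 1.0  # C = e1 (orthogonal to A)
    m[3, 0] = 1.0
    m[3, 1] = 1.0  # D = e0 + e1 (cos(A, D) = 1/sqrt(2))
    return EmbeddedNetwork(genes=genes, matrix=m)
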