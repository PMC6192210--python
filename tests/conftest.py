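import numpy as np
import pytest

from bidiffusion.data import InteractionNetwork
from bidiffusion.similarity import SimilarityMatrix, prepare_similarity
from bidiffusion import synthetic as syn


@pytest.fixture
def toy_network():
    # 3 lncRNAs x 2 miRNAs, 3 known pairs
    A = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    return InteractionNetwork(["L1", "L2", "L3"], ["M1", "M2"], A)


@pytest.fixture
def identity_network():
    return InteractionNetwork(["L1", "L2"], ["M1", "M2"], np.eye(2))


def random_prepared_similarity(n, rng, prefix="e"):
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    sim = SimilarityMatrix([f"{prefix}{i}" for i in range(n)], sym, "expression")
    return prepare_similarity(sim)


def random_network(nl, nm, rng, density=0.5, prefix=("l", "m")):
    A = (rng.random((nl, nm)) < density).astype(float)
    if A.sum() == 0:
        A[0, 0] = 1.0
    return InteractionNetwork(
        [f"{prefix[0]}{i}" for i in range(nl)],
        [f"{prefix[1]}{j}" for j in range(nm)],
        A,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    return syn.generate(seed=1)
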