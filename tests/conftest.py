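from pathlib import Path

import numpy as np
import pytest

import emalam as em

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


def random_estimate(seed: int, N: int = 12, M: int = 20, K: int = 2,
                    concentration: float = 1.0):
    """Small random instance with genotypes drawn from it."""
    return em.simulate_general(N=N, M=M, K=K, concentration=concentration, seed=seed)


@pytest.fixture
def k2_estimate():
    est, _ = random_estimate(seed=11, N=10, M=15, K=2)
    return est


@pytest.fixture
def k3_instance():
    return random_estimate(seed=5, N=15, M=25, K=3)


@pytest.fixture
def anchored_estimate():
    """K=2 estimate whose feasible set is pinned by strong anchors."""
    spec = em.AnchorSpec(
        markers=((0.001, 0.999), (0.999, 0.001)),
        individuals=((0.001, 0.999), (0.999, 0.001)),
    )
    est, _ = em.simulate_general(N=10, M=15, K=2, anchor_spec=spec, seed=3)
    return est
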