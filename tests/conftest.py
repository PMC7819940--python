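import numpy as np
import pytest

from serumeem import EEM, SerumSimConfig, make_grid, simulate_dataset


@pytest.fixture
def small_grids():
    """Coarse grids covering the instrument ranges (fast tests)."""
    return make_grid(250, 450, 10), make_grid(250, 600, 5)


@pytest.fixture
def eem_factory(small_grids):
    ex, em = small_grids

    def make(seed=0, sample_id="s1", replicate_id=1, intensity=None):
        rng = np.random.default_rng(seed)
        if intensity is None:
            intensity = rng.uniform(0, 10, (len(em), len(ex)))
        return EEM(ex, em, intensity, sample_id=sample_id,
                   replicate_id=replicate_id)

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset on coarse grids, shared across tests."""
    cfg = SerumSimConfig(n_samples=24, ex_grid=(250, 450, 10),
                         em_grid=(250, 600, 5), seed=7)
    return simulate_dataset(cfg)


def rank1_tensor(shape=(8, 12, 10), seed=0):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.2, 1.0, shape[0])
    b = rng.uniform(0.2, 1.0, shape[1])
    c = rng.uniform(0.2, 1.0, shape[2])
    return np.einsum("i,j,k->ijk", a, b, c), (a, b, c)


def random_rank_f(shape, F, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.1, 1.0, (shape[0], F))
    B = rng.uniform(0.1, 1.0, (shape[1], F))
    C = rng.uniform(0.1, 1.0, (shape[2], F))
    return np.einsum("if,jf,kf->ijk", A, B, C), (A, B, C)
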