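import numpy as np
import pytest

from idpchain import ChainModelSpec, Ensemble, generate_random_walk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rod():
    """Straight 10-bead chain with 0.38 nm spacing, 3 identical frames."""
    coords = np.zeros((3, 10, 3))
    coords[..., 0] = 0.38 * np.arange(10)
    return Ensemble(coords=coords, label="rod")


@pytest.fixture
def small_random_ensemble(rng):
    """5 frames x 8 residues of smooth random coordinates (nm)."""
    coords = rng.normal(scale=0.5, size=(5, 8, 3)).cumsum(axis=1)
    return Ensemble(coords=coords)


@pytest.fixture(scope="session")
def fjc_large():
    """5000 freely jointed chains of 100 residues (shared, read-only)."""
    spec = ChainModelSpec(n_residues=100, n_frames=5000, seed=42)
    return generate_random_walk(spec)
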