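import numpy as np
import pytest

from trajtree import synthfix
from trajtree.select import SelectionWindow, build_dataset, window_select
from trajtree.trajio import Frame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, n_atoms=12, elements=("C", "O", "H"), spread=6.0):
    """A random frame with generic positions (distance ties have
    probability zero)."""
    els = tuple(rng.choice(elements, size=n_atoms))
    coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
    return Frame(elements=els, coords=coords)


@pytest.fixture(scope="session")
def small_collection():
    """A 30-path, 6-water synthetic collection shared across tests."""
    spec = synthfix.FixtureSpec(n_waters=6, n_paths=30, seed=11)
    return spec, synthfix.generate_paths(spec)


@pytest.fixture(scope="session")
def small_dataset(small_collection):
    spec, records = small_collection
    cfg = synthfix.default_colvar_config(spec.n_waters)
    selected = window_select(records, cfg, SelectionWindow(seed=11))
    return spec, build_dataset(selected)
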