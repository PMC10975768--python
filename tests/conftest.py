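import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16 easy 64x64 scenes with a 7:2:1 split, shared across tests."""
    from kyolo.synthetic import SceneSpec, make_dataset
    root = tmp_path_factory.mktemp("tiny_ds")
    make_dataset(16, root, seed=11, spec=SceneSpec.easy(size=64))
    return root / "manifest.yaml"


def random_boxes(rng, n, lo=0.05, hi=0.4):
    """(n, 4) center-size boxes inside the unit square."""
    wh = rng.uniform(lo, hi, size=(n, 2))
    cxy = rng.uniform(0.25, 0.75, size=(n, 2))
    return np.concatenate([cxy, wh], axis=1)
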