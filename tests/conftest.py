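import numpy as np
import pytest

from droughtvision.ceac import NormalizedLabel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_interior_label(rng, class_id=None, margin=0.02):
    """A label whose box lies strictly inside the unit square."""
    w = rng.uniform(0.05, 0.4)
    h = rng.uniform(0.05, 0.4)
    a = rng.uniform(w / 2 + margin, 1 - w / 2 - margin)
    b = rng.uniform(h / 2 + margin, 1 - h / 2 - margin)
    cid = int(rng.integers(0, 4)) if class_id is None else class_id
    return NormalizedLabel(cid, a, b, w, h).validate()


@pytest.fixture
def make_label():
    return random_interior_label
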