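import numpy as np
import pytest

from dvn.models import LayerSpec, NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tube_volume(rng, shape=(16, 16, 16), radius=1.5):
    """Bright straight tube on a dark noisy background, ~2-3% positives."""
    axis = int(rng.integers(3))
    c = rng.uniform(4, 12, size=2)
    idx = np.indices(shape, dtype=float)
    others = [a for a in range(3) if a != axis]
    d2 = (idx[others[0]] - c[0]) ** 2 + (idx[others[1]] - c[1]) ** 2
    mask = d2 <= radius**2
    img = np.where(mask, rng.uniform(0.6, 1.0), rng.uniform(0.0, 0.35))
    img = img + rng.normal(0, 0.03, shape)
    return img.astype(float), mask.astype(float)


def tiny_fcn_spec(nonlinearity="tanh", in_channels=1):
    """Small 4-layer spec used by the training tests (fast on CPU)."""
    return NetworkSpec(
        [
            LayerSpec(in_channels, 4, (3, 3, 3), nonlinearity=nonlinearity),
            LayerSpec(4, 8, (5, 5, 5), nonlinearity=nonlinearity),
            LayerSpec(8, 8, (3, 3, 3), nonlinearity=nonlinearity),
        ]
    )
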