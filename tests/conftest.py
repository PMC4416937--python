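import numpy as np
import pytest

from sfnet.toydata import generate, preset_two_class


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_two_class():
    """Separable 2-class toy epoch set (N=2, T=100, K=100), fixed seed."""
    return generate(preset_two_class(seed=7))


def random_zero_mean_epoch(rng, n, t):
    X = rng.standard_normal((n, t))
    return X - X.mean(axis=1, keepdims=True)


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))
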