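import numpy as np
import pytest

from fuzzytrack.motion_data import TrainingSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_affine_training_set(rng, n=27, noise=0.0):
    """Random external rows with an exactly affine internal response."""
    X = rng.uniform(-5.0, 5.0, size=(n, 9))
    A = rng.uniform(-1.0, 1.0, size=(3, 9))
    b = rng.uniform(-2.0, 2.0, size=3)
    Y = X @ A.T + b + noise * rng.standard_normal((n, 3))
    t = np.arange(n, dtype=float)
    return TrainingSet(X, Y, t), A, b


@pytest.fixture
def affine_training_set(rng):
    train, _, _ = make_affine_training_set(rng)
    return train
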