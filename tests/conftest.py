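import numpy as np
import pytest

from trigen3d import ExpressionTensor3D, Tricluster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    """An 8 x 5 x 4 uniform-random tensor."""
    return ExpressionTensor3D(rng.uniform(0, 100, size=(8, 5, 4)))


@pytest.fixture
def constant_tensor():
    return ExpressionTensor3D(np.full((4, 3, 3), 5.0))


@pytest.fixture
def full_tricluster():
    """Selects every cell of an 8 x 5 x 4 tensor."""
    return Tricluster(range(8), range(5), range(4))
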