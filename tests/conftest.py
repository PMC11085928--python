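import numpy as np
import pytest

from infiltra import StackParams, generate_stack, generate_training_pairs


@pytest.fixture(scope="session")
def small_stack():
    """A 14-layer, 256 px synthetic stack with 20 nuclei and its truth."""
    params = StackParams(n_nuclei=20, width_px=256, height_px=256, seed=1)
    stack, truth = generate_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def tiny_pairs():
    """Six 64 px training pairs with 3 nuclei each."""
    params = StackParams(width_px=64, height_px=64, n_nuclei=3, seed=5)
    return generate_training_pairs(params, 6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
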