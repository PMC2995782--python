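import numpy as np
import pytest

from ramanzlsr import (
    HyperStack,
    default_macrophage_phantom,
    remove_cosmic_rays,
)


@pytest.fixture(scope="session")
def phantom():
    """Default macrophage phantom (observed stack + ground truth), seed 1."""
    return default_macrophage_phantom(seed=1)


@pytest.fixture(scope="session")
def despiked_phantom(phantom):
    """The default phantom after cosmic-ray removal at the default threshold."""
    stack, truth = phantom
    cleaned, report = remove_cosmic_rays(stack)
    return cleaned, report, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_stack(rng):
    """Small random stack with a strictly increasing non-uniform axis."""
    data = rng.normal(10.0, 2.0, size=(8, 8, 50))
    wn = np.sort(rng.uniform(800.0, 1800.0, 50))
    wn += np.arange(50) * 1e-6  # guard against ties
    return HyperStack(data=data, wavenumbers=wn)
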