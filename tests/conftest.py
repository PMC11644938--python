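import numpy as np
import pytest

from bsdr import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_regression():
    """Small smooth regression dataset with two planted bands (fast fits)."""
    spec = SyntheticSpec(
        n_samples=300, n_bands=40, informative_bands=[10, 30],
        task="regression", smoothness=3, noise_sd=0.05, seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_classification():
    """Small smooth 3-class dataset keyed to two planted bands."""
    spec = SyntheticSpec(
        n_samples=400, n_bands=40, informative_bands=[10, 30],
        task="classification", n_classes=3, smoothness=3, noise_sd=0.05, seed=13,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
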