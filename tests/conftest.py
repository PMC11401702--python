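import numpy as np
import pytest

from octma.pipeline import RunConfig, run_training
from octma.synthetic import SyntheticConfig, generate_strip_dataset


def dyadic_image(rng: np.random.Generator, shape) -> np.ndarray:
    """Random image with values k/256: float64 sums are exact, so
    integral-image identities can be asserted bitwise."""
    return rng.integers(0, 256, size=shape).astype(np.float64) / 256.0


@pytest.fixture(scope="session")
def small_strips():
    """A small labeled strip set shared by feature/classifier tests."""
    return generate_strip_dataset(24, 28, SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def trained_bundle():
    """A full-size trained bundle (92 MA + 110 normal, 100 words, MLP)."""
    bundle, report = run_training(RunConfig(seed=0))
    return bundle, report
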