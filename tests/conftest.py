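import numpy as np
import pytest

from slns.image import MRImage
from slns.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def tumor_phantom(default_spec):
    """Default noisy tumor phantom (sigma=5) with ground truth."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def clean_phantom(default_spec):
    import dataclasses

    return generate_phantom(dataclasses.replace(default_spec, noise_sigma=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_image(rng) -> MRImage:
    return MRImage(rng.uniform(0, 255, (16, 16)))
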