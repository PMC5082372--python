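import numpy as np
import pytest

from aife import GrayImage, MultiModalStack, generate_phantom
from aife.phantom import lesion_masks, reference_phantom_spec


@pytest.fixture(scope="session")
def reference_phantom() -> tuple[MultiModalStack, np.ndarray]:
    """The fixed regression phantom (128x128, seed 7) with its label map."""
    return generate_phantom(reference_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def reference_masks(reference_phantom):
    _, labels = reference_phantom
    return lesion_masks(labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def random_image(rng) -> GrayImage:
    return GrayImage(rng.uniform(0, 255, size=(32, 32)), levels=256)
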