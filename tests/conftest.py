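import numpy as np
import pytest

from hepix.imaging import SpecimenImage
from hepix.synthetic import SyntheticSpec, generate_specimen


@pytest.fixture(scope="session")
def two_texture_specimen() -> SpecimenImage:
    """256x256 specimen with strong cancer/noncancer texture contrast."""
    spec = SyntheticSpec(
        image_size=(256, 256),
        cancer_fraction=0.4,
        texture_amplitude_cancer=60.0,
        texture_amplitude_noncancer=10.0,
        seed=11,
    )
    return generate_specimen(spec)


@pytest.fixture(scope="session")
def small_specimen() -> SpecimenImage:
    """Cheap 96x96 specimen for fast unit tests."""
    return generate_specimen(
        SyntheticSpec(image_size=(96, 96), cancer_fraction=0.35, seed=5)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_specimen() -> SpecimenImage:
    """Constant-valued image, fully tissue."""
    h, w = 48, 48
    pixels = np.full((h, w, 3), 128, dtype=np.uint8)
    return SpecimenImage(
        pixels=pixels,
        tissue_mask=np.ones((h, w), dtype=bool),
        specimen_id="flat",
    )
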