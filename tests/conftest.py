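import numpy as np
import pytest

from radopt.imaging import RasterImage, IMAGE_SIZE
from radopt.phantoms import PhantomConfig, generate_phantom_dataset
from radopt.search_space import FeatureAxis, SearchSpace


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced two-modality phantom cohort with strong class signal."""
    config = PhantomConfig(
        train_patients={"ACP": 8, "NOTACP": 8},
        test_patients={"ACP": 6, "NOTACP": 6},
        train_images_per_patient=2,
        test_images_per_patient=1,
        signal_amplitude=40.0,
        noise_sd=10.0,
        seed=3,
    )
    return generate_phantom_dataset(config)


@pytest.fixture(scope="session")
def toy_space():
    """Three small categorical axes (2 x 3 x 2 = 12 genomes)."""
    return SearchSpace(
        (
            FeatureAxis("alpha", (("a0", 0), ("a1", 1))),
            FeatureAxis("beta", (("b0", 0.1), ("b1", 0.2), ("b2", 0.3))),
            FeatureAxis("gamma", (("g0", "x"), ("g1", "y"))),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gradient_image():
    """Deterministic non-constant image: diagonal intensity ramp."""
    rr, cc = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
    return RasterImage(((rr + cc) / (2 * (IMAGE_SIZE - 1)) * 255).astype(np.uint8))
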