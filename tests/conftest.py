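import numpy as np
import pytest

from renaltlco.phantom import PhantomSpec, generate_phantom, make_target_mask


@pytest.fixture(scope="session")
def target96():
    """Canonical 96x96 target mask with precomputed layers."""
    return make_target_mask(image_size=(96, 96), kidney_axes=(34.0, 20.0), bend=0.3)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, cyst-free default phantom."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0, cyst_count=0, rng_seed=3))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(
        PhantomSpec(noise_sigma=10.0, cyst_count=2, true_egfr=55.0, rng_seed=4)
    )


def random_connected_mask(rng: np.random.Generator, max_size: int = 50) -> np.ndarray:
    """A random connected blob: thresholded smooth noise, largest component."""
    from scipy import ndimage

    h = int(rng.integers(12, max_size + 1))
    w = int(rng.integers(12, max_size + 1))
    field = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=rng.uniform(1.5, 4.0))
    mask = field > np.quantile(field, rng.uniform(0.55, 0.8))
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return random_connected_mask(rng, max_size)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    blob = labeled == (1 + int(np.argmax(sizes)))
    if blob.sum() < 20:
        return random_connected_mask(rng, max_size)
    return blob
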