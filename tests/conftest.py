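import numpy as np
import pytest

from foldmetrics import EyeImagingSpec, render_eye_images


@pytest.fixture(scope="session")
def noisy_step():
    """Seeded noisy vertical step edge (classic TV test image)."""
    rng = np.random.default_rng(42)
    img = np.zeros((48, 48))
    img[:, 24:] = 100.0
    return img + rng.normal(0, 12.0, img.shape)


@pytest.fixture(scope="session")
def rendered_pair():
    """One noise-free dull-fold render with ground truth (no vessels)."""
    spec = EyeImagingSpec(
        n_folds=30, noise_sigma=0.0, vessel_density=0.0, sharp_fraction=0.0
    )
    oct_img, octa_img, truth = render_eye_images(spec, seed=7)
    return spec, oct_img, octa_img, truth
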