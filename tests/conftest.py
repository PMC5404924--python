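import numpy as np
import pytest

from rgcquant.presets import reference_config, reference_retina_spec
from rgcquant.synthetic import generate_retina


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless reference retina (no bundles, flat illumination)."""
    spec = reference_retina_spec(
        seed=7, n_bundles=0, noise_sigma=0.0, illumination_gradient=0.0,
        image_height_px=1100, image_width_px=1100, tissue_radius_um=500.0,
        n_rgc=50, n_amacrine=30, min_center_spacing_um=20.0,
    )
    image, truth, tissue = generate_retina(spec)
    return spec, image, truth, tissue


@pytest.fixture(scope="session")
def noisy_scene():
    """Reference retina at the study noise level with bundles."""
    spec = reference_retina_spec(seed=11)
    image, truth, tissue = generate_retina(spec)
    return spec, image, truth, tissue


@pytest.fixture(scope="session")
def config():
    return reference_config()


@pytest.fixture(scope="session")
def disk_mask_1500um():
    """Filled-disk tissue mask of radius 1500 µm at 1 µm/px."""
    n = 3100
    rr, cc = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= 1500.0**2
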