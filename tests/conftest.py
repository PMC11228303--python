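import numpy as np
import pytest

from fusionrad.radiomics import quantize
from fusionrad.synthetic import PhantomSpec, generate_phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def phantoms_2d():
    """Small high-separability 2D phantom set shared across tests."""
    spec = PhantomSpec(n_samples=12, shape=(32, 32), n_channels=1,
                       separability=1.0, seed=7)
    return generate_phantoms(spec)


@pytest.fixture(scope="session")
def phantoms_3d():
    spec = PhantomSpec(n_samples=4, shape=(24, 24, 12), n_channels=4,
                       separability=1.0, seed=5)
    return generate_phantoms(spec)


def random_quantized(rng, shape=(8, 8), ng=4, roi_prob=1.0):
    """Random quantized image with an optional random ROI."""
    img = rng.normal(size=shape)
    roi = rng.random(shape) < roi_prob
    if not roi.any():
        roi[tuple(0 for _ in shape)] = True
    return quantize(img, roi, ng)
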