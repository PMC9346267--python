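import numpy as np
import pytest

from ihcquant import FieldSpec, analyze_field, generate_field


@pytest.fixture(scope="session")
def default_field():
    """One synthetic field at generator defaults, shared across tests."""
    spec = FieldSpec(n_cells=120, frac_positive=0.5, seed=1)
    image, roi, truth = generate_field(spec)
    return spec, image, roi, truth


@pytest.fixture(scope="session")
def analyzed_field(default_field):
    _, image, roi, truth = default_field
    metrics, cells, channels = analyze_field(image, roi)
    return metrics, cells, channels, roi, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
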