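import numpy as np
import pytest

from skatemorph import SyntheticSpec, template_outline
from skatemorph.io_formats import default_outline_sliders


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def template35():
    return template_outline(35)


@pytest.fixture(scope="session")
def sliders35():
    return default_outline_sliders(35)


@pytest.fixture
def random_config(rng):
    """A factory for well-conditioned random landmark configurations."""

    def make(k=35, scale=1.0):
        base = template_outline(k).coords
        return scale * (base + 0.01 * rng.standard_normal((k, 2)))

    return make


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=77)
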