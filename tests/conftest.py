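import numpy as np
import pytest

from aaascreen.phantom import PhantomSpec, generate_phantom

#: small grid used throughout the unit tests: full anatomy, quarter size
SMALL_SHAPE = (64, 64, 80)
SMALL_SPACING = (3.6, 3.6, 4.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def aaa_phantom():
    spec = PhantomSpec(
        shape=SMALL_SHAPE, spacing=SMALL_SPACING,
        aneurysm=True, aneurysm_max_diameter_mm=42.0, thrombus_fraction=0.3, seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def normal_phantom():
    spec = PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING, aneurysm=False, seed=12)
    return generate_phantom(spec)
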