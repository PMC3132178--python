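import numpy as np
import pytest
from hypothesis import settings

from emdscope import Panorama, ReceptorGrid, SynthesisSpec, generate_natural_panorama

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# test-scale raster: 0.25 deg/px keeps the Gaussian prefilter well sampled
# (sigma ~ 2.8 px) at a fraction of the default image size
TEST_WIDTH = 1440
TEST_HEIGHT = 280


@pytest.fixture(scope="session")
def small_spec() -> SynthesisSpec:
    return SynthesisSpec(width_px=TEST_WIDTH, height_px=TEST_HEIGHT, seed=7)


@pytest.fixture(scope="session")
def small_panorama(small_spec) -> Panorama:
    return generate_natural_panorama(small_spec)


@pytest.fixture(scope="session")
def horizon_grid() -> ReceptorGrid:
    return ReceptorGrid.horizon()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
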