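import numpy as np
import pytest

from hetsim import (
    OpticalConfig,
    PhaseSet,
    SampleImage,
    make_transfer_function,
)
from hetsim.phantoms import PhantomSpec, generate

GRID = (128, 128)
PIXEL_NM = 20.0


@pytest.fixture(scope="session")
def config():
    return OpticalConfig(
        lambda_ill=488.0, lambda_em=510.0, n_sample=1.33, na=1.2,
        pixel_nm=PIXEL_NM,
    )


@pytest.fixture(scope="session")
def det_tf(config):
    return make_transfer_function(config, GRID, "emission")


@pytest.fixture(scope="session")
def exc_tf(config):
    return make_transfer_function(config, GRID, "illumination")


@pytest.fixture(scope="session")
def periodic_sample():
    return generate(
        PhantomSpec(kind="periodic", grid_shape=GRID, pixel_nm=PIXEL_NM,
                    seed=11, spectral_index=0.5)
    )


@pytest.fixture(scope="session")
def point_sample():
    d = np.zeros(GRID)
    d[0, 0] = 1.0
    return SampleImage(density=d, pixel_nm=PIXEL_NM)


@pytest.fixture(scope="session")
def three_phases():
    return PhaseSet.equal_steps(3)


@pytest.fixture(scope="session")
def five_phases():
    return PhaseSet.equal_steps(5)


@pytest.fixture(scope="session")
def pattern_freq(config):
    # 90% of the illumination diffraction cutoff
    return 0.9 * 2.0 * config.na / config.lambda_ill
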