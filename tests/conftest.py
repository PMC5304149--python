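import numpy as np
import pytest

from flimphasor import (
    AcquisitionSettings,
    IRF,
    PhasorSettings,
    SyntheticSpec,
    simulate_cube,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionSettings:
    """Default timing: 12.5 ns period, 64 channels tiling it."""
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def gaussian_irf(acq) -> IRF:
    return IRF.from_gaussian(250.0, acq)


@pytest.fixture(scope="session")
def full_period_settings() -> PhasorSettings:
    """Transform settings that keep the lever weights equal to the total
    intensity fractions: fundamental harmonic over the whole period."""
    return PhasorSettings(harmonic=1, window_fraction=1.0,
                          baseline_subtraction=False)


@pytest.fixture(scope="session")
def nadh_cube(acq):
    """Two-component NADH-like cube with a two-region fraction pattern."""
    spec = SyntheticSpec(
        components=((750.0, 0.30), (2900.0, 0.70)),
        photons_per_pixel=1e4,
        shape=(32, 32),
        spatial_pattern="two-region",
        fraction_delta=0.05,
        seed=5,
    )
    return simulate_cube(spec, acq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
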