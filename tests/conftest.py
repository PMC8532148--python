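import numpy as np
import pytest

import oliverelax as ox


@pytest.fixture(scope="session")
def at28_params() -> ox.DispersionModelParams:
    """Composite dispersion-model parameters of the reference sample."""
    return ox.get_fixture("at28_dispersion")


@pytest.fixture(scope="session")
def at28_t2_components():
    """Two-component 2 MHz T2 of the reference sample (43 / 147 ms)."""
    return ox.get_fixture("at28_t2_2mhz")


@pytest.fixture()
def noiseless():
    """NoiseSpec factory for zero-noise simulations."""
    return lambda seed=0: ox.NoiseSpec("relative_gaussian", 0.0, seed)


@pytest.fixture(scope="session")
def at28_profile_30pt(at28_params) -> ox.DispersionProfile:
    """Noiseless 30-point R1 profile over 10 kHz - 400 MHz."""
    return ox.simulate_dispersion(
        at28_params,
        np.geomspace(0.01, 400.0, 30),
        ox.NoiseSpec("relative_gaussian", 0.0, 0),
        sample_id="at_28",
    )
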