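import numpy as np
import pytest

from echoplace.scene import DeviceSpec, DirectionGrid


@pytest.fixture(scope="session")
def tiny_spec() -> DeviceSpec:
    """Small device for unit tests: 3×3 gaze grid, 2 mics, 8 ms window.

    The shortened recording window (1752 samples) keeps filterbank runs fast;
    it still spans the 5.8 ms onset blank plus a usable echo range (~1.4 m).
    """
    grid = DirectionGrid(
        azimuths=np.array([-10.0, 0.0, 10.0]),
        elevations=np.array([-10.8, 0.0, 10.8]),
    )
    return DeviceSpec(grid=grid, n_mics=2, record_duration=8e-3)


@pytest.fixture(scope="session")
def tiny_spec_noiseless(tiny_spec) -> DeviceSpec:
    return tiny_spec.with_(self_noise_level=0.0)


@pytest.fixture(scope="session")
def full_spec() -> DeviceSpec:
    """The full-scale study device: 31 mics, 31×7 grid, 34 ms at 219 kS/s."""
    return DeviceSpec()
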