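import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blicyto.params import (
    AcquisitionSchedule,
    KillingModelParams,
    LuminescenceParams,
    RenderParams,
)
from blicyto import synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kp() -> KillingModelParams:
    return KillingModelParams()


@pytest.fixture(scope="session")
def lp() -> LuminescenceParams:
    return LuminescenceParams()


@pytest.fixture(scope="session")
def schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def layout():
    return synth.default_plate_layout()


@pytest.fixture(scope="session")
def small_render() -> RenderParams:
    """Compact geometry for fast rendering tests (spots still >=6 sigma
    inside their ROIs: side floor(0.93*16)=14 > 6*1.5)."""
    return RenderParams(
        image_shape=(144, 208),
        well_pitch_px=16.0,
        well_sigma_px=1.5,
        background_flux=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def short_schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule(np.arange(0.0, 241.0, 20.0))
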