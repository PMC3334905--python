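from hypothesis import HealthCheck, settings
import pytest

from mesoplan import CalibrationParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=80,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def cal() -> CalibrationParams:
    """Calibration of the standard 132 µg / 450+450 nl experiment."""
    return CalibrationParams(phi=0.88)


#: the four published (dilution factor, expected hydration wt%) pairs of the
#: standard experiment, used both as calibration input and as ground truth
CAPTION_LEVELS = [(1.0, 75.0), (2.0, 60.0), (4.0, 43.0), (7.0, 30.0)]


@pytest.fixture
def caption_levels():
    return list(CAPTION_LEVELS)
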