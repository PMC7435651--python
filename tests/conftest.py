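import numpy as np
import pytest

from fallsense import GeneratorConfig, InterruptConfig
from fallsense.synthetic_imu import ActivityLabel, ImuTrace


@pytest.fixture
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def int_config() -> InterruptConfig:
    return InterruptConfig()


def make_constant_trace(ax: float, ay: float, az: float, seconds: float,
                        rate: float = 100.0) -> ImuTrace:
    n = int(round(seconds * rate))
    samples = np.zeros((n, 6))
    samples[:, 0] = ax
    samples[:, 1] = ay
    samples[:, 2] = az
    return ImuTrace(rate=rate, samples=samples)


@pytest.fixture(params=list(ActivityLabel), ids=lambda a: a.name)
def activity(request) -> ActivityLabel:
    return request.param
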