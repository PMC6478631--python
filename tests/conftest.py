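import numpy as np
import pytest

from voxgen.contours import ContourSpec

SR = 22050.0


def flat_f0(hz: float) -> ContourSpec:
    return ContourSpec.from_pairs(float(hz), value_scale="log", parameter_id="f0")


@pytest.fixture
def sr() -> float:
    return SR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
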