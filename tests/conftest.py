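import numpy as np
import pytest

import fouriermotion as fm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_spec():
    return fm.GratingSpec()  # 16 deg bars, 180 deg/s, 8-800 lux


@pytest.fixture
def mf_spec():
    return fm.GratingSpec(mode="missing_fundamental")


@pytest.fixture
def small_protocol():
    """Two repetitions per direction, shortened black baseline."""
    return fm.build_protocol(
        reps_per_direction=2, seed=11, timing={"black_s": 30.0}
    )
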