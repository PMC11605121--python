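import numpy as np
import pytest

from gaitfall.anthropometry import build_anthropometry
from gaitfall.models import build_gait_model, build_cpg_parameters


@pytest.fixture(scope="session")
def anthro():
    return build_anthropometry()


@pytest.fixture(scope="session")
def young_params():
    return build_cpg_parameters(build_gait_model("young"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
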