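import numpy as np
import pytest

from pavarb.models import ModelSpec, PriorParams, Variant
from pavarb.task import build_task_config


def make_spec(variant="adaptive", beta=3.0, theta0=0.5, eta0=2.0, w_fixed=None, L0=0.5):
    return ModelSpec(
        variant=Variant(variant),
        beta=beta,
        prior_uncontrollable=PriorParams(theta0, eta0),
        prior_controllable=PriorParams(theta0, eta0),
        w_fixed=w_fixed,
        L0=L0,
    )


@pytest.fixture
def adaptive_spec():
    return make_spec("adaptive")


@pytest.fixture
def fixed_spec():
    return make_spec("fixed", w_fixed=0.5)


@pytest.fixture
def exp1_lc_config():
    return build_task_config("exp1", "lc", seed=11)


@pytest.fixture
def exp1_hc_config():
    return build_task_config("exp1", "hc", seed=11)


@pytest.fixture
def exp2_config():
    return build_task_config("exp2", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
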