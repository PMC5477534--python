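import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roadblock_smx as rb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sfm_template():
    return rb.template_preset("Os400O1")


@pytest.fixture(scope="session")
def sfm_o2_template():
    return rb.template_preset("O2400O1")


@pytest.fixture(scope="session")
def mt_template():
    return rb.template_preset("MT-O1")


@pytest.fixture(scope="session")
def o1_kinetics():
    return rb.in_vitro_kinetics("O1")


@pytest.fixture(scope="session")
def noiseless_bead_config():
    return rb.BeadImageConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def lut(noiseless_bead_config):
    stack = rb.build_lut_stack(noiseless_bead_config)
    return rb.build_lookup_table(stack)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
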