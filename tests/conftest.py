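import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from striatal_rhythms import (IntegrationSettings, NetworkSpec, NoiseSpec,
                              dopamine_condition, simulate)


@pytest.fixture(scope="session")
def tiny_combined():
    """One short combined-network run shared by structural tests."""
    from striatal_rhythms.experiments import make_fixture
    fx = make_fixture("tiny")
    return simulate(fx["spec"], "high", fx["settings"], fx["noise"])


@pytest.fixture(scope="session")
def single_fsi_bursting():
    """Noise-free single FSI in the bursting regime (I_app = 8)."""
    spec = NetworkSpec(n_fsi=1, n_d1=0, n_d2=0, seed=0)
    settings_ = IntegrationSettings(t_total=4000.0, t_transient=500.0, seed=0)
    return simulate(spec, dopamine_condition("baseline", I_app_fsi=8.0),
                    settings_, NoiseSpec.off())
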