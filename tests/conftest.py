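import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wsforecast import networks as nw

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wsp():
    return nw.build_pathway("Wsp")


@pytest.fixture(scope="session")
def aws():
    return nw.build_pathway("Aws")


@pytest.fixture(scope="session")
def mws():
    return nw.build_pathway("Mws")


@pytest.fixture(scope="session")
def all_networks(wsp, aws, mws):
    return {"Wsp": wsp, "Aws": aws, "Mws": mws}


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
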