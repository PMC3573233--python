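import numpy as np
import pytest

from bgdcm import circuit as circ
from bgdcm.circuit import ThetaVector, build_standard_circuit


@pytest.fixture(scope="session")
def config():
    return circ.load_config()


@pytest.fixture(scope="session")
def standard(config):
    return build_standard_circuit(config)


@pytest.fixture()
def theta0(standard):
    return ThetaVector.zeros(standard)


@pytest.fixture()
def theta_off(standard):
    """Parameters with the untreated-state gain increases applied."""
    th = ThetaVector.zeros(standard)
    names = [c.name for c in standard.extrinsic]
    for n in ("ctx_stn", "gpe_stn", "stn_gpi"):
        th.log_mod[names.index(n)] = np.log(1.5)
    return th
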