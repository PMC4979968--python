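import numpy as np
import pytest

from thalcort.experiment import SimulationConfig, run_simulation
from thalcort.model import ThalamicParams
from thalcort.network import build_network


@pytest.fixture(scope="session")
def sp_params() -> ThalamicParams:
    """Relay-nucleus parameter set (SP/NSP column of the parameter table)."""
    return ThalamicParams()


@pytest.fixture(scope="session")
def topology():
    return build_network(seed=0)


@pytest.fixture(scope="session")
def short_run():
    """A short lesion run shared by cheap behavioural tests (6 s, lesion at 3 s)."""
    cfg = SimulationConfig(duration=6000.0, lesion_time=3000.0, seed=11)
    return run_simulation(cfg)
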