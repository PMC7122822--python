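import numpy as np
import pytest

from gridfish import fixtures as fx
from gridfish import fleet as fl


@pytest.fixture(scope="session")
def toy_system():
    """Default 10x10 synthetic study system shared across tests."""
    spec = fx.FixtureSpec(seed=3)
    domain, hsi, fieldm, initial, scenario, bio = fx.make_fixture_set(spec)
    fleet_params = fl.FleetParams(F_base=fx.STUDY_F[2011], v=1.13)
    return {
        "spec": spec,
        "domain": domain,
        "hsi": hsi,
        "field": fieldm,
        "initial": initial,
        "scenario": scenario,
        "bio": bio,
        "fleet": fleet_params,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
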