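import numpy as np
import pytest

from planktos.dynamics import Community
from planktos.environment import ColumnConfig
from planktos.params import default_parameters


@pytest.fixture(scope="session")
def pset():
    return default_parameters()


@pytest.fixture(scope="session")
def diatom(pset):
    return pset["diatom"]


@pytest.fixture()
def box_config():
    return ColumnConfig(depth=10.0, n_cells=1, closed=True)


@pytest.fixture()
def community(pset):
    return Community(pset)


def euler_steps(community, state, config, nsteps, dt, **forc):
    """Drive the community forward with plain Euler + voiding."""
    forc.setdefault("T", 12.0)
    forc.setdefault("I0", 150.0)
    forc.setdefault("SPM", 2.0)
    forc.setdefault("month", 6)
    for _ in range(nsteps):
        ds, db, _ = community.tendencies(state, config, dt=dt, **forc)
        state.C += dt * ds["C"]
        state.N += dt * ds["N"]
        state.P += dt * ds["P"]
        state.Si += dt * ds["Si"]
        state.Chl += dt * ds["Chl"]
        for k, v in ds["ab"].items():
            getattr(state.ab, k).__iadd__(dt * v)
        for k, v in db.items():
            state.budgets[k] += dt * v
        community.apply_voiding(state)
    return state
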