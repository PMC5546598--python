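import numpy as np
import pytest

from biospice import Model, SpeciesDef, build_system, fixtures


@pytest.fixture(scope="session")
def all_fixtures():
    return fixtures()


@pytest.fixture()
def toggle(all_fixtures):
    return all_fixtures["toggle_switch"]


@pytest.fixture()
def toggle_system(toggle):
    return build_system(toggle)


@pytest.fixture()
def self_inhibited(all_fixtures):
    return all_fixtures["self_inhibited"]


@pytest.fixture()
def decay_model():
    """Single species with pure first-order decay (d = 0.5, X0 = 4)."""
    m = Model(species=[SpeciesDef("X", 4.0, 0.5)], name="decay")
    m.validate()
    return m


@pytest.fixture()
def decay_system(decay_model):
    return build_system(decay_model)


def hand_self_inhibited_rhs(x):
    """Independent hand-coded ODE of the self-inhibited enzymatic loop:
    production alpha, product-inhibited Michaelis-Menten conversion,
    first-order decays (alpha=0.5, Vmax=1, Km=1, Kp=1, nb=2, ds=0.1,
    dp=0.2)."""
    S, P = x
    v = 1.0 * S / (1.0 + S) * 1.0 / (1.0 + P**2)
    return np.array([0.5 - v - 0.1 * S, v - 0.2 * P])
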