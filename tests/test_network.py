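"""Network assembly: rhs structure, source counting, Jacobians,
conservation laws."""

import numpy as np
import pytest

from biospice import (
    Model,
    Reaction,
    SpeciesDef,
    build_system,
    count_sources,
    jacobian,
    prune_inert_model,
)
from biospice.engine import time_course
from biospice.network import fd_jacobian

from conftest import hand_self_inhibited_rhs


def test_self_inhibited_rhs_matches_hand_ode(self_inhibited):
    """The assembled network reproduces the hand-coded two-species ODE at
    100 random states to 1e-12 relative."""
    system = build_system(self_inhibited)
    rng = np.random.default_rng(1)
    for _ in range(100):
        x = rng.uniform(0.0, 10.0, 2)
        got = system.rhs(x)
        want = hand_self_inhibited_rhs(x)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-15)


def test_constant_production_with_decay():
    m = Model(
        species=[SpeciesDef("X", 0.0, 0.25)],
        reactions=[Reaction("C1", products=[("X", 1)], params={"beta": 2.0})],
    )
    s = build_system(m)
    assert s.rhs(np.array([0.0]))[0] == pytest.approx(2.0)
    assert s.rhs(np.array([4.0]))[0] == pytest.approx(2.0 - 1.0)


def test_binding_sign_bookkeeping():
    """A+B <-> C: dA/dt = dB/dt = -v, dC/dt = +v at every state."""
    m = Model(
        species=[SpeciesDef("A", 1.0), SpeciesDef("B", 1.0), SpeciesDef("C", 0.0)],
        reactions=[
            Reaction("B1", reactants=[("A", 1), ("B", 1)], products=[("C", 1)],
                     params={"k_on": 2.0, "k_off": 0.7})
        ],
    )
    s = build_system(m)
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.uniform(0, 5, 3)
        dx = s.rhs(x)
        v = 2.0 * x[0] * x[1] - 0.7 * x[2]
        assert dx[0] == pytest.approx(-v, rel=1e-12)
        assert dx[1] == pytest.approx(-v, rel=1e-12)
        assert dx[2] == pytest.approx(+v, rel=1e-12)


def test_compartment_volume_scales_derivative():
    m = Model(
        species=[SpeciesDef("X", 0.0, 0.0, compartment=2.0)],
        reactions=[Reaction("C1", products=[("X", 1)], params={"beta": 3.0})],
    )
    assert build_system(m).rhs(np.array([0.0]))[0] == pytest.approx(1.5)


def test_fix_directive_clamps_species(toggle):
    from biospice.model import Directive

    m = toggle
    m.directives.append(Directive("FIX", {"species": "R1", "value": 2.5}))
    try:
        s = build_system(m)
        x = s.x0.copy()
        assert x[s.index("R1")] == 2.5
        assert s.rhs(x)[s.index("R1")] == 0.0
    finally:
        m.directives.pop()


# -- source counting -------------------------------------------------------


def test_toggle_source_counts(toggle_system):
    assert count_sources(toggle_system) == 7  # N+M over the 5 reactions
    assert count_sources(toggle_system, prune_inert=True) == 5
    assert toggle_system.inert_species() == {"X1", "X2"}


def test_pruned_toggle_model_keeps_dynamics(toggle):
    pruned = prune_inert_model(toggle)
    assert len(pruned.species) == 5
    s0, s1 = build_system(toggle), build_system(pruned)
    keep = [s0.index(n) for n in s1.species_order]
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.uniform(0, 5, s0.n)
        assert np.allclose(s0.rhs(x)[keep], s1.rhs(x[keep]), rtol=1e-12)


def test_empty_model_has_no_sources():
    assert count_sources(build_system(Model())) == 0


# -- Jacobian --------------------------------------------------------------


def test_jacobian_pure_decay():
    s = build_system(Model(species=[SpeciesDef("X", 1.0, 0.7)]))
    assert jacobian(s, np.array([2.0])) == pytest.approx(np.array([[-0.7]]))


def test_jacobian_diffusion_pair():
    m = Model(
        species=[SpeciesDef("A", 1.0), SpeciesDef("B", 0.0)],
        reactions=[Reaction("F1", reactants=[("A", 1)], products=[("B", 1)],
                            params={"D": 0.4})],
    )
    J = jacobian(build_system(m), np.array([1.0, 0.5]))
    assert J == pytest.approx(np.array([[-0.4, 0.4], [0.4, -0.4]]))


@pytest.mark.parametrize("name", ["self_inhibited", "toggle_switch",
                                  "band_detector", "and_gate"])
def test_analytic_jacobian_agrees_with_finite_differences(all_fixtures, name):
    s = build_system(all_fixtures[name])
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = rng.uniform(0.5, 5.0, s.n)
        Ja = jacobian(s, x)
        Jf = fd_jacobian(s, x)
        scale = np.max(np.abs(Ja)) + 1e-12
        assert np.max(np.abs(Ja - Jf)) / scale < 1e-6


# -- conservation ----------------------------------------------------------


def test_closed_binding_system_conserves_totals():
    """A+B <-> C conserves [A]+[C] and [B]+[C] along trajectories."""
    m = Model(
        species=[SpeciesDef("A", 2.0), SpeciesDef("B", 1.0), SpeciesDef("C", 0.0)],
        reactions=[
            Reaction("B1", reactants=[("A", 1), ("B", 1)], products=[("C", 1)],
                     params={"k_on": 1.0, "k_off": 0.3})
        ],
    )
    res = time_course(build_system(m), None, 20.0, 101)
    tot_ac = res.series["A"] + res.series["C"]
    tot_bc = res.series["B"] + res.series["C"]
    assert np.max(np.abs(tot_ac - 2.0)) < 1e-7
    assert np.max(np.abs(tot_bc - 1.0)) < 1e-7


def test_diffusion_pair_rhs_sums_to_zero_exactly():
    """V_A*d[A]/dt + V_B*d[B]/dt is analytically zero for a closed pair."""
    m = Model(
        species=[SpeciesDef("A", 3.0, 0.0, 1.0), SpeciesDef("B", 0.0, 0.0, 0.5)],
        reactions=[Reaction("F1", reactants=[("A", 1)], products=[("B", 1)],
                            params={"D": 0.8})],
    )
    s = build_system(m)
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.uniform(0, 5, 2)
        dx = s.rhs(x)
        assert 1.0 * dx[0] + 0.5 * dx[1] == 0.0
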