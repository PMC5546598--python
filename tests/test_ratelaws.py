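"""Kinetic rate laws: hand-computed values, identities and guards."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biospice import DomainError, ParameterError, RateContext, Reaction, rate
from biospice.ratelaws import (
    rate_binding,
    rate_custom,
    rate_diffusion,
    rate_enzymatic,
    rate_hill,
    rate_pump,
    rate_transcription,
    rate_translation,
)


def ctx(conc=None, params=None):
    return RateContext(conc or {}, params or {})


# -- binding ---------------------------------------------------------------


def B(reactants, products, k_on, k_off):
    return Reaction("B1", reactants=reactants, products=products,
                    params={"k_on": k_on, "k_off": k_off})


def test_binding_hand_value():
    """k_on=2, [R1]=3, [R2]=4, k_off=1, [P]=5 with stoich 2: 2*12 - 25 = -1."""
    r = B([("R1", 1), ("R2", 1)], [("P", 2)], 2.0, 1.0)
    v = rate_binding(ctx({"R1": 3.0, "R2": 4.0, "P": 5.0}), r)
    assert v == pytest.approx(-1.0, rel=1e-12)


def test_binding_zero_reactant_irreversible_gives_zero():
    r = B([("A", 1), ("B", 1)], [("C", 1)], 5.0, 0.0)
    assert rate_binding(ctx({"A": 0.0, "B": 7.0, "C": 3.0}), r) == 0.0


def test_binding_detailed_balance_zero():
    """At [P]^nP / prod [R]^nR = k_on/k_off the net rate vanishes."""
    r = B([("A", 1)], [("C", 2)], 3.0, 1.0)
    # C^2/A = 3 -> A=3, C=3
    v = rate_binding(ctx({"A": 3.0, "C": 3.0}), r)
    assert v == pytest.approx(0.0, abs=1e-12)


def test_binding_negative_concentration_is_domain_error():
    r = B([("A", 1)], [], 1.0, 0.0)
    with pytest.raises(DomainError):
        rate_binding(ctx({"A": -1.0}), r)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(0, 10), st.floats(0, 10), st.floats(0.01, 10))
def test_binding_irreversible_nonnegative(a, b, kon):
    r = B([("A", 1), ("B", 2)], [("C", 1)], kon, 0.0)
    assert rate_binding(ctx({"A": a, "B": b, "C": 99.0}), r) >= 0.0


# -- enzymatic -------------------------------------------------------------


def E(v_max=2.0, K_m=1.5):
    return Reaction("E1", reactants=[("S", 1)], products=[("P", 1)],
                    modifiers=["Enz"], params={"v_max": v_max, "K_m": K_m})


def test_enzymatic_zero_substrate():
    assert rate_enzymatic(ctx({"S": 0.0, "Enz": 3.0}), E()) == 0.0


def test_enzymatic_half_saturation():
    """[S] = K_m gives exactly v_max*[E]/2."""
    v = rate_enzymatic(ctx({"S": 1.5, "Enz": 3.0}), E())
    assert v == pytest.approx(2.0 * 3.0 / 2.0, rel=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(0.01, 100), st.floats(0.02, 100))
def test_enzymatic_increasing_and_bounded(s1, ds):
    lo = rate_enzymatic(ctx({"S": s1, "Enz": 2.0}), E())
    hi = rate_enzymatic(ctx({"S": s1 + ds, "Enz": 2.0}), E())
    assert lo < hi < 2.0 * 2.0  # v_max * [E]


def test_enzymatic_nonpositive_km_rejected():
    with pytest.raises(ParameterError):
        rate_enzymatic(ctx({"S": 1.0, "Enz": 1.0}), E(K_m=0.0))


# -- diffusion -------------------------------------------------------------


def F(D=0.5):
    return Reaction("F1", reactants=[("Xa", 1)], products=[("Xb", 1)],
                    params={"D": D})


def test_diffusion_values_and_antisymmetry():
    assert rate_diffusion(ctx({"Xa": 4.0, "Xb": 1.0}), F()) == pytest.approx(1.5)
    assert rate_diffusion(ctx({"Xa": 2.0, "Xb": 2.0}), F()) == 0.0
    fwd = rate_diffusion(ctx({"Xa": 4.0, "Xb": 1.0}), F())
    rev = rate_diffusion(ctx({"Xa": 1.0, "Xb": 4.0}), F())
    assert fwd == -rev


# -- Hill ------------------------------------------------------------------


def H(v_max=3.0, K=2.0, n=2.0):
    return Reaction("H1", reactants=[("R", 1)], products=[("P", 1)],
                    params={"v_max": v_max, "K": K, "n": n})


def test_hill_half_max_and_zero():
    assert rate_hill(ctx({"R": 2.0}), H()) == pytest.approx(1.5, rel=1e-12)
    assert rate_hill(ctx({"R": 0.0}), H()) == 0.0


def test_hill_switch_like_at_large_n():
    v = rate_hill(ctx({"R": 3.0}), H(n=40.0))
    assert v == pytest.approx(3.0, rel=1e-6)


def test_hill_invalid_constants_rejected():
    with pytest.raises(ParameterError):
        rate_hill(ctx({"R": 1.0}), H(K=0.0))


# -- translation -----------------------------------------------------------


def test_translation_linear():
    r = Reaction("L1", products=[("Prot", 1)], modifiers=["mRNA"],
                 params={"k_TL": 3.0})
    assert rate_translation(ctx({"mRNA": 0.0}), r) == 0.0
    assert rate_translation(ctx({"mRNA": 2.0}), r) == pytest.approx(6.0)
    assert rate_translation(ctx({"mRNA": 4.0}), r) == pytest.approx(12.0)


# -- pump ------------------------------------------------------------------


def test_pump_empty_regulator_list_gives_vmax():
    r = Reaction("P1", reactants=[("A", 1)], products=[("B", 1)],
                 params={"v_max": 4.0, "regulators": []})
    assert rate_pump(ctx({"A": 1.0, "B": 1.0}), r) == 4.0


def test_pump_half_max_per_regulator_and_zero_gate():
    r = Reaction("P1", reactants=[("A", 1)], products=[("B", 1)],
                 modifiers=["M"], params={"v_max": 4.0, "regulators": [(2.0, 3.0)]})
    assert rate_pump(ctx({"A": 1, "B": 1, "M": 2.0}), r) == pytest.approx(2.0, rel=1e-12)
    assert rate_pump(ctx({"A": 1, "B": 1, "M": 0.0}), r) == 0.0


def test_pump_parameter_count_mismatch():
    r = Reaction("P1", reactants=[("A", 1)], products=[("B", 1)],
                 modifiers=["M1", "M2"], params={"v_max": 1.0,
                                                 "regulators": [(1.0, 1.0)]})
    with pytest.raises(ParameterError):
        rate_pump(ctx({"A": 1, "B": 1, "M1": 1, "M2": 1}), r)


# -- transcription ---------------------------------------------------------


def T(activators, repressors, modifiers, k_TR=6.0):
    return Reaction("T1", products=[("mRNA", 1)], modifiers=modifiers,
                    params={"k_TR": k_TR, "activators": activators,
                            "repressors": repressors})


def test_transcription_constitutive():
    assert rate_transcription(ctx({}), T([], [], [])) == 6.0


def test_transcription_repressor_half_point():
    """No activator, one repressor at its half-point: k_TR / 2."""
    r = T([], [(2.0, 1.0)], ["R"])
    assert rate_transcription(ctx({"R": 2.0}), r) == pytest.approx(3.0, rel=1e-12)


def test_transcription_activator_half_point():
    """One activator at its half-point, no repressor: k_TR * 1/(1+1)."""
    r = T([(2.0, 1.0)], [], ["A"])
    assert rate_transcription(ctx({"A": 2.0}), r) == pytest.approx(3.0, rel=1e-12)


def test_transcription_mixed_additive_denominator():
    r = T([(1.0, 1.0)], [(1.0, 1.0)], ["A", "R"])
    # num = [A], den = 1 + [A] + [R]
    v = rate_transcription(ctx({"A": 2.0, "R": 3.0}), r)
    assert v == pytest.approx(6.0 * 2.0 / 6.0, rel=1e-12)


# -- custom ----------------------------------------------------------------


def test_custom_matches_enzymatic_with_folded_enzyme():
    x = Reaction("X1", reactants=[("S", 1)], products=[("P", 1)],
                 params={"rate": "vmax*[S]/(km+[S])"})
    e = Reaction("E1", reactants=[("S", 1)], products=[("P", 1)],
                 params={"v_max": 2.0, "K_m": 1.5})
    c = ctx({"S": 0.7, "P": 0.0}, {"vmax": 2.0, "km": 1.5})
    assert rate_custom(c, x) == pytest.approx(rate_enzymatic(c, e), rel=1e-12)


def test_custom_constant_zero():
    x = Reaction("X1", reactants=[("S", 1)], products=[],
                 params={"rate": "0"})
    assert rate_custom(ctx({"S": 5.0}), x) == 0.0


def test_custom_inhibition_factor_half_at_kp():
    """The product-inhibition Hill factor halves the rate at [P] = Kp."""
    x = Reaction("X1", reactants=[("S", 1)], products=[("P", 1)],
                 params={"rate": "vmax*[S]/(km+[S])*kp^nb/(kp^nb+[P]^nb)"})
    p = {"vmax": 1.0, "km": 1.0, "kp": 1.0, "nb": 2.0}
    free = rate_custom(ctx({"S": 2.0, "P": 0.0}, p), x)
    inhibited = rate_custom(ctx({"S": 2.0, "P": 1.0}, p), x)
    assert inhibited == pytest.approx(free / 2.0, rel=1e-12)


# -- dispatch & generic invariants ----------------------------------------


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.floats(0, 1e3), st.floats(0, 1e3))
def test_all_rates_finite_on_valid_inputs(a, b):
    import math

    reactions = [
        B([("A", 1)], [("B", 1)], 2.0, 0.5),
        E(),
        F(),
        H(),
        Reaction("L1", products=[("P", 1)], modifiers=["mRNA"], params={"k_TL": 1.0}),
        T([(1.0, 2.0)], [(1.0, 2.0)], ["A", "B"]),
    ]
    conc = {"A": a, "B": b, "S": a, "Enz": b, "Xa": a, "Xb": b, "R": a,
            "P": b, "mRNA": a}
    for r in reactions:
        assert math.isfinite(rate(ctx(conc), r))
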