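"""SBML import/export: hand translations, dynamics round trips, the
supported/dropped partition."""

import numpy as np
import pytest

from biospice import (
    SbmlError,
    build_system,
    export_sbml,
    import_sbml,
)

TINY = """<?xml version="1.0"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="tiny">
  <listOfCompartments><compartment id="c" size="2" constant="true"/></listOfCompartments>
  <listOfSpecies>
    <species id="X" compartment="c" initialConcentration="1"
             constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="r1" reversible="false">
    <listOfReactants><speciesReference species="X" stoichiometry="1" constant="true"/></listOfReactants>
    <kineticLaw>
      <math xmlns="http://www.w3.org/1998/Math/MathML">
        <apply><times/><ci>k</ci><ci>X</ci></apply>
      </math>
      <listOfLocalParameters><localParameter id="k" value="3"/></listOfLocalParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""


def test_local_parameter_substitution_and_compartment_volume():
    """Local k=3 is substituted by value; the compartment size 2 scales the
    derivative: d[X]/dt = -3*[X]/2."""
    model, report = import_sbml(TINY)
    assert model.species[0].compartment == 2.0
    assert "3" in model.reactions[0].params["rate"]
    s = build_system(model)
    assert s.rhs(np.array([1.0]))[0] == pytest.approx(-1.5)
    assert any("local parameter" in item for item in report.supported)


def test_function_definition_inlined():
    doc = TINY.replace(
        "<listOfReactions>",
        """<listOfFunctionDefinitions>
           <functionDefinition id="f">
             <math xmlns="http://www.w3.org/1998/Math/MathML">
               <lambda><bvar><ci>a</ci></bvar>
                 <apply><times/><cn type="integer">2</cn><ci>a</ci></apply>
               </lambda>
             </math>
           </functionDefinition>
         </listOfFunctionDefinitions><listOfReactions>""",
    ).replace(
        "<apply><times/><ci>k</ci><ci>X</ci></apply>",
        "<apply><ci>f</ci><ci>X</ci></apply>",
    )
    model, report = import_sbml(doc)
    s = build_system(model)
    assert s.rhs(np.array([1.0]))[0] == pytest.approx(-2.0 / 2.0)
    assert any("functionDefinition" in item for item in report.supported)


def test_algebraic_rule_dropped_and_strict_raises():
    doc = TINY.replace(
        "<listOfReactions>",
        '<listOfRules><algebraicRule>'
        '<math xmlns="http://www.w3.org/1998/Math/MathML"><ci>X</ci></math>'
        "</algebraicRule></listOfRules><listOfReactions>",
    )
    _, report = import_sbml(doc)
    assert any("algebraic" in c for c, _ in report.dropped)
    with pytest.raises(SbmlError):
        import_sbml(doc, strict=True)


def test_assignment_rule_feeds_rate_expressions():
    doc = TINY.replace(
        "<listOfReactions>",
        """<listOfParameters><parameter id="k2" constant="false"/></listOfParameters>
        <listOfRules><assignmentRule variable="k2">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><plus/><cn type="integer">1</cn><ci>X</ci></apply>
          </math></assignmentRule></listOfRules><listOfReactions>""",
    ).replace("<ci>k</ci>", "<ci>k2</ci>").replace(
        "<listOfLocalParameters><localParameter id=\"k\" value=\"3\"/></listOfLocalParameters>",
        "",
    )
    model, _ = import_sbml(doc)
    s = build_system(model)
    # d[X]/dt = -(1+X)*X / 2
    assert s.rhs(np.array([3.0]))[0] == pytest.approx(-(1 + 3) * 3 / 2.0)


def test_rate_rule_on_species_adds_derivative():
    doc = TINY.replace(
        "<listOfReactions>",
        """<listOfRules><rateRule variable="X">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <cn type="integer">5</cn>
          </math></rateRule></listOfRules><listOfReactions>""",
    )
    model, report = import_sbml(doc)
    s = build_system(model)
    assert s.rhs(np.array([1.0]))[0] == pytest.approx(5.0 - 1.5)
    assert any("rateRule" in item for item in report.supported)


def test_time_triggered_parameter_event():
    doc = TINY.replace(
        "</listOfReactions>",
        """</listOfReactions>
        <listOfEvents><event id="e1"><trigger>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><geq/>
              <csymbol definitionURL="http://www.sbml.org/sbml/symbols/time">t</csymbol>
              <cn type="integer">10</cn>
            </apply></math></trigger>
          <listOfEventAssignments><eventAssignment variable="kglob">
            <math xmlns="http://www.w3.org/1998/Math/MathML"><cn type="integer">7</cn></math>
          </eventAssignment></listOfEventAssignments>
        </event></listOfEvents>""",
    ).replace(
        "<listOfReactions>",
        '<listOfParameters><parameter id="kglob" value="2" constant="false"/>'
        "</listOfParameters><listOfReactions>",
    )
    model, report = import_sbml(doc)
    assert model.param_events == [(10.0, "kglob", 7.0)]
    s = build_system(model)
    assert s.params_at(0.0)["kglob"] == 2.0
    assert s.params_at(10.0)["kglob"] == 7.0


def test_species_event_dropped():
    doc = TINY.replace(
        "</listOfReactions>",
        """</listOfReactions>
        <listOfEvents><event id="e1"><trigger>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><geq/>
              <csymbol definitionURL="http://www.sbml.org/sbml/symbols/time">t</csymbol>
              <cn type="integer">1</cn>
            </apply></math></trigger>
          <listOfEventAssignments><eventAssignment variable="X">
            <math xmlns="http://www.w3.org/1998/Math/MathML"><cn type="integer">9</cn></math>
          </eventAssignment></listOfEventAssignments>
        </event></listOfEvents>""",
    )
    model, report = import_sbml(doc)
    assert model.param_events == []
    assert any("event" in c for c, _ in report.dropped)


def test_import_report_partitions_constructs():
    _, report = import_sbml(TINY)
    assert report.supported and not report.dropped
    names = " ".join(report.supported)
    for construct in ("compartment", "species", "reaction"):
        assert construct in names


# -- export ----------------------------------------------------------------


def test_export_counts_degradation_reactions(toggle):
    """5 reactions + one extra degradation reaction per degrading species
    (all 7 toggle species degrade)."""
    xml = export_sbml(toggle)
    model, _ = import_sbml(xml)
    assert len(model.reactions) == 5 + 7


def test_no_degradation_reaction_for_stable_species():
    from biospice import Model, Reaction, SpeciesDef

    m = Model(
        species=[SpeciesDef("A", 1.0, 0.0)],
        reactions=[Reaction("C1", products=[("A", 1)], params={"beta": 1.0})],
    )
    model, _ = import_sbml(export_sbml(m))
    assert len(model.reactions) == 1


def test_dependent_parameters_become_assignments():
    from biospice import Model, ParameterDef, SpeciesDef

    m = Model(
        parameters=[ParameterDef("a", "2"), ParameterDef("b", "a*3")],
        species=[SpeciesDef("X", 1.0)],
    )
    xml = export_sbml(m)
    assert "assignmentRule" in xml
    model, _ = import_sbml(xml)
    s = build_system(model)
    s.rhs(np.array([1.0]))  # assignment evaluates without error
    assert s._env["b"] == pytest.approx(6.0)


@pytest.mark.parametrize(
    "name", ["self_inhibited", "toggle_switch", "penicillin_bio",
             "band_detector", "and_gate"]
)
def test_dynamics_round_trip(all_fixtures, name):
    """export -> import preserves the rhs to 1e-9 (relative to the rhs
    scale) at 100 random nonnegative states."""
    m = all_fixtures[name]
    m2, report = import_sbml(export_sbml(m))
    s1, s2 = build_system(m), build_system(m2)
    assert s1.species_order == s2.species_order
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.uniform(0.0, 2.0, s1.n) * (np.abs(s1.x0) + 1.0)
        a, b = s1.rhs(x), s2.rhs(x)
        scale = np.max(np.abs(a)) + 1e-300
        assert np.max(np.abs(a - b)) / scale < 1e-9
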