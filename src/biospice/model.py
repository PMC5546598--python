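"""Central in-memory representation of a biochemical system.

A :class:`Model` is the hub object every translator reads or writes: the
netlist parser fills it, the SBML importer fills it, and the simulation
engine, the SBML writer and the NGSPICE writer all consume it.  It holds
named parameters, species, typed reactions, simulation directives and
raw pass-through simulator lines.

Reaction types (first letter of the reaction name):

====== ============================== ===========================
letter mechanism                      kinetic parameters
====== ============================== ===========================
B      mass-action binding            k_on, k_off
C      constant production            beta
D      first-order decay              d
E      Michaelis-Menten enzymatic     v_max, K_m
F      passive diffusion              D
H      Hill-controlled reaction       v_max, K, n
L      translation (per mRNA)         k_TL
P      regulated pump                 v_max + (K_j, n_j) per regulator
T      regulated transcription        k_TR + (KA_j, nA_j) / (KR_j, nR_j)
X      custom rate expression         quoted formula
====== ============================== ===========================

Parameter values inside a reaction may be numeric literals or formulas
over the model's named parameters; they are resolved when the dynamical
system is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .errors import CrossRefError, FormatError, ParameterError

ParamValue = Union[float, str]

REACTION_TYPES = frozenset("BCDEFHLPTX")

#: arity of the species-list arguments for each reaction type
#: (reactants-like, products-like, modifiers-like) -- see the parser for
#: how Table-style argument order maps onto these roles.
DIRECTIVE_KINDS = frozenset(
    {
        "FIX",
        "PULSE",
        "WAVEFORM",
        "TRANSFUNC",
        "TRUTHTABLE",
        "STEADY",
        "SWEEP",
        "TIMECOURSE",
        "PLOT",
        "PLOTALL",
    }
)

ANALYSIS_KINDS = frozenset({"TRANSFUNC", "TRUTHTABLE", "STEADY", "SWEEP", "TIMECOURSE"})


@dataclass
class ParameterDef:
    name: str
    expression: str  # numeric literal or formula over other parameters
    comment: str = ""


@dataclass
class SpeciesDef:
    name: str
    initial_concentration: float = 0.0
    degradation_rate: float = 0.0
    compartment: float = 1.0  # volume; only non-1 for compartmentalised models

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ParameterError(
                f"species {self.name}: initial concentration must be >= 0"
            )
        if self.degradation_rate < 0:
            raise ParameterError(f"species {self.name}: degradation rate must be >= 0")
        if self.compartment <= 0:
            raise ParameterError(f"species {self.name}: compartment volume must be > 0")


@dataclass
class Reaction:
    name: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def rtype(self) -> str:
        return self.name[0].upper()

    # For T reactions, modifiers holds activators first, then repressors.
    @property
    def activators(self) -> list[str]:
        n = len(self.params.get("activators", []))
        return self.modifiers[:n]

    @property
    def repressors(self) -> list[str]:
        n = len(self.params.get("activators", []))
        return self.modifiers[n:]

    def participants(self) -> set[str]:
        out = {s for s, _ in self.reactants} | {s for s, _ in self.products}
        return out | set(self.modifiers)


@dataclass
class Directive:
    kind: str
    args: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DIRECTIVE_KINDS:
            raise FormatError(f"unknown directive kind {self.kind!r}")


@dataclass
class Model:
    parameters: list[ParameterDef] = field(default_factory=list)
    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    directives: list[Directive] = field(default_factory=list)
    passthrough: list[str] = field(default_factory=list)
    # SBML-derived extensions; empty for native netlists.
    assignments: list[tuple[str, str]] = field(default_factory=list)  # target -> formula
    rate_rules: list[tuple[str, str]] = field(default_factory=list)  # species -> formula
    param_events: list[tuple[float, str, float]] = field(default_factory=list)
    name: str = "model"

    # -- lookups ---------------------------------------------------------
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def get_species(self, name: str) -> SpeciesDef:
        for s in self.species:
            if s.name == name:
                return s
        raise CrossRefError(f"unknown species {name!r}")

    def analysis_directive(self) -> Directive | None:
        found = [d for d in self.directives if d.kind in ANALYSIS_KINDS]
        if len(found) > 1:
            raise FormatError(
                "at most one analysis directive per run configuration, found "
                + ", ".join(d.kind for d in found)
            )
        return found[0] if found else None

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check name uniqueness, namespace disjointness and cross-references."""
        snames = self.species_names()
        pnames = self.parameter_names()
        for pool, what in ((snames, "species"), (pnames, "parameter")):
            lowered: dict[str, str] = {}
            for n in pool:
                if n.lower() in lowered:
                    raise FormatError(
                        f"duplicate {what} name {n!r} (case-insensitive clash "
                        f"with {lowered[n.lower()]!r})"
                    )
                lowered[n.lower()] = n
        if set(snames) & set(pnames):
            clash = sorted(set(snames) & set(pnames))
            raise FormatError(f"names used as both species and parameter: {clash}")
        sset = set(snames)
        rnames = set()
        for r in self.reactions:
            if r.name in rnames:
                raise FormatError(f"duplicate reaction name {r.name!r}")
            rnames.add(r.name)
            if r.rtype not in REACTION_TYPES:
                raise FormatError(
                    f"reaction {r.name!r}: unknown type letter {r.rtype!r}"
                )
            for sp in r.participants():
                if sp not in sset:
                    raise CrossRefError(
                        f"reaction {r.name!r} references undeclared species {sp!r}"
                    )
            for sp, st in r.reactants + r.products:
                if not (isinstance(st, int) and st >= 1):
                    raise FormatError(
                        f"reaction {r.name!r}: stoichiometry of {sp!r} must be a "
                        f"positive integer, got {st!r}"
                    )
            validate_reaction_params(r)
        for d in self.directives:
            for key in ("species", "input", "output"):
                if key in d.args and d.args[key] not in sset:
                    raise CrossRefError(
                        f"directive {d.kind} references undeclared species "
                        f"{d.args[key]!r}"
                    )
            for sp in d.args.get("inputs", []) or []:
                if sp not in sset:
                    raise CrossRefError(
                        f"directive {d.kind} references undeclared species {sp!r}"
                    )
        self.analysis_directive()


def validate_reaction_params(r: Reaction) -> None:
    """Ensure the kinetic-parameter map is complete for the reaction's type."""
    t = r.rtype
    p = r.params

    def need(*keys):
        for k in keys:
            if k not in p:
                raise ParameterError(
                    f"reaction {r.name!r} (type {t}): missing parameter {k!r}"
                )

    if t == "B":
        need("k_on", "k_off")
    elif t == "C":
        need("beta")
        if r.reactants:
            raise ParameterError(f"reaction {r.name!r}: constant production has no reactants")
    elif t == "D":
        need("d")
        if len(r.reactants) != 1 or r.products:
            raise ParameterError(f"reaction {r.name!r}: decay takes exactly one species")
    elif t == "E":
        need("v_max", "K_m")
        if len(r.reactants) != 1:
            raise ParameterError(
                f"reaction {r.name!r}: enzymatic reaction supports exactly one substrate"
            )
    elif t == "F":
        need("D")
        if len(r.reactants) != 1 or len(r.products) != 1:
            raise ParameterError(
                f"reaction {r.name!r}: diffusion connects exactly two species"
            )
    elif t == "H":
        need("v_max", "K", "n")
        if len(r.reactants) != 1:
            raise ParameterError(
                f"reaction {r.name!r}: Hill reaction takes exactly one reactant"
            )
    elif t == "L":
        need("k_TL")
        if not r.modifiers:
            raise ParameterError(
                f"reaction {r.name!r}: translation needs at least one mRNA modifier"
            )
    elif t == "P":
        need("v_max")
        regs = p.get("regulators", [])
        if len(regs) != len(r.modifiers):
            raise ParameterError(
                f"reaction {r.name!r}: {len(r.modifiers)} regulator(s) but "
                f"{len(regs)} (K, n) pair(s)"
            )
    elif t == "T":
        need("k_TR")
        act = p.get("activators", [])
        rep = p.get("repressors", [])
        if len(act) + len(rep) != len(r.modifiers):
            raise ParameterError(
                f"reaction {r.name!r}: {len(r.modifiers)} transcription factor(s) "
                f"but {len(act)} activator and {len(rep)} repressor pair(s)"
            )
    elif t == "X":
        need("rate")
        if not isinstance(p["rate"], str):
            raise ParameterError(f"reaction {r.name!r}: custom rate must be a string")
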