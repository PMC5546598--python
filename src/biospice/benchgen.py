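"""Generators for scaling benchmarks and the reference fixture models.

Two families of synthetic models:

* ``gen_repressilator_grn`` — a ring of an odd number of genes, each
  repressing the next, plus a repressed reporter: for every gene one
  transcription (T) reaction producing its mRNA and one translation (L)
  reaction producing its protein, so an n-gene network has 2n+2 species
  and 2n+2 reactions (the +2 being the reporter's mRNA and protein).
  Default kinetics sit at the classic oscillatory operating point of the
  scaled repressilator (maximal transcription / (K * mRNA decay *
  protein decay / translation) = 216, Hill cooperativity 2, protein to
  mRNA lifetime ratio 5).

* ``gen_random_pathway`` — a linear enzymatic chain of N species fed by
  a constant source on species 1 and drained by an enzymatic sink on
  species N, plus M-N randomly drawn feedback/feedforward enzymatic
  reactions; every enzymatic reaction is catalysed by a randomly drawn
  pathway species.  Reproducible from the seed.

``fixtures()`` returns the five reference models used across the test
suite (a self-inhibited enzymatic loop, the genetic toggle switch, a
penicillin-biosensor biochemistry model, a band detector and an AND
gate); all kinetic constants are package defaults documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import Directive, Model, ParameterDef, Reaction, SpeciesDef

__all__ = [
    "GrnSpec",
    "PathwaySpec",
    "gen_repressilator_grn",
    "gen_random_pathway",
    "fixtures",
    "self_inhibited",
    "toggle_switch",
    "penicillin_bio",
    "band_detector",
    "and_gate",
]


@dataclass
class GrnSpec:
    n_genes: int = 3
    k_TR: float = 216.0  # maximal transcription rate
    k_TL: float = 0.2  # translation rate per mRNA
    KR: float = 1.0  # repression half-point
    nR: float = 2.0  # repression cooperativity
    d_mrna: float = 1.0  # mRNA degradation rate
    d_protein: float = 0.2  # protein degradation rate

    def validate(self):
        if self.n_genes < 3 or self.n_genes % 2 == 0:
            raise ParameterError(
                "a repressing ring oscillates only for an odd number of genes >= 3, "
                f"got {self.n_genes}"
            )


@dataclass
class PathwaySpec:
    n_species: int
    n_reactions: int
    seed: int = 0
    beta: float = 0.1  # source rate into species 1
    v_max: float = 1.0
    K_m: float = 1.0

    def validate(self):
        if self.n_species < 2:
            raise ParameterError("pathway needs at least 2 species")
        if self.n_reactions < self.n_species:
            raise ParameterError("n_reactions must be >= n_species")


def gen_repressilator_grn(spec: GrnSpec) -> Model:
    """Ring-of-repressors gene regulatory network with a reporter.

    Species and reaction count are both ``2 * n_genes + 2``.
    """
    spec.validate()
    n = spec.n_genes
    m = Model(name=f"repressilator_grn_{n}")
    m.parameters = [
        ParameterDef("ktr", repr(float(spec.k_TR)), "maximal transcription rate"),
        ParameterDef("ktl", repr(float(spec.k_TL)), "translation rate per mRNA"),
        ParameterDef("kr", repr(float(spec.KR)), "repression half-point"),
        ParameterDef("nr", repr(float(spec.nR)), "repression cooperativity"),
    ]
    for i in range(1, n + 1):
        # a small asymmetric kick on gene 1 keeps the trajectory off the
        # (unstable but invariant) fully symmetric manifold
        m.species.append(SpeciesDef(f"mRNA{i}", 1.0 if i == 1 else 0.0, spec.d_mrna))
        m.species.append(SpeciesDef(f"P{i}", 0.0, spec.d_protein))
    m.species.append(SpeciesDef("mRNArep", 0.0, spec.d_mrna))
    m.species.append(SpeciesDef("Prep", 0.0, spec.d_protein))
    for i in range(1, n + 1):
        prev = n if i == 1 else i - 1
        m.reactions.append(
            Reaction(
                f"T{i}", products=[(f"mRNA{i}", 1)], modifiers=[f"P{prev}"],
                params={"k_TR": "ktr", "activators": [], "repressors": [("kr", "nr")]},
            )
        )
        m.reactions.append(
            Reaction(
                f"L{i}", products=[(f"P{i}", 1)], modifiers=[f"mRNA{i}"],
                params={"k_TL": "ktl"},
            )
        )
    m.reactions.append(
        Reaction(
            "Trep", products=[("mRNArep", 1)], modifiers=["P1"],
            params={"k_TR": "ktr", "activators": [], "repressors": [("kr", "nr")]},
        )
    )
    m.reactions.append(
        Reaction("Lrep", products=[("Prep", 1)], modifiers=["mRNArep"],
                 params={"k_TL": "ktl"})
    )
    m.directives = [
        Directive("TIMECOURSE", {"t_end": 200.0, "npoints": 401}),
        Directive("PLOT", {"species_list": ["P1", "Prep"]}),
    ]
    m.validate()
    return m


def gen_random_pathway(spec: PathwaySpec) -> Model:
    """Random enzymatic pathway: linear chain + random extra edges."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    N, M = spec.n_species, spec.n_reactions
    m = Model(name=f"pathway_N{N}_M{M}_s{spec.seed}")
    m.parameters = [
        ParameterDef("beta", repr(float(spec.beta)), "source rate into the chain head"),
        ParameterDef("vmax", repr(float(spec.v_max))),
        ParameterDef("km", repr(float(spec.K_m))),
    ]
    names = [f"S{i}" for i in range(1, N + 1)]
    for s in names:
        m.species.append(SpeciesDef(s, 1.0, 0.0))
    m.reactions.append(Reaction("Csrc", products=[(names[0], 1)], params={"beta": "beta"}))

    def enzymatic(idx: int, sub: str, prod: str | None):
        cat = names[int(rng.integers(0, N))]
        return Reaction(
            f"E{idx}",
            reactants=[(sub, 1)],
            products=[(prod, 1)] if prod else [],
            modifiers=[cat],
            params={"v_max": "vmax", "K_m": "km"},
        )

    for i in range(1, N):
        m.reactions.append(enzymatic(i, names[i - 1], names[i]))
    m.reactions.append(enzymatic(N, names[-1], None))  # terminal sink
    for j in range(N + 1, M + 1):
        a, b = rng.integers(0, N), rng.integers(0, N)
        while b == a:
            b = rng.integers(0, N)
        m.reactions.append(enzymatic(j, names[int(a)], names[int(b)]))
    m.directives = [Directive("STEADY"), Directive("PLOTALL")]
    m.validate()
    return m


# ---------------------------------------------------------------------------
# fixtures


def self_inhibited() -> Model:
    """Constant production of a substrate S plus an enzymatic conversion to
    P, the conversion carrying a Hill-type product-inhibition factor:

        dS/dt = alpha - Vmax*S/(Km+S) * Kp^nb/(Kp^nb+P^nb) - ds*S
        dP/dt =         Vmax*S/(Km+S) * Kp^nb/(Kp^nb+P^nb) - dp*P
    """
    m = Model(name="self_inhibited")
    m.parameters = [
        ParameterDef("alpha", "0.5", "constant substrate production"),
        ParameterDef("vmax", "1", "maximal enzymatic rate"),
        ParameterDef("km", "1", "Michaelis constant"),
        ParameterDef("kp", "1", "inhibition half-point"),
        ParameterDef("nb", "2", "inhibition cooperativity"),
    ]
    m.species = [SpeciesDef("S", 0.0, 0.1), SpeciesDef("P", 0.0, 0.2)]
    m.reactions = [
        Reaction("C1", products=[("S", 1)], params={"beta": "alpha"}),
        Reaction(
            "X1", reactants=[("S", 1)], products=[("P", 1)],
            params={"rate": "vmax*[S]/(km+[S])*kp^nb/(kp^nb+[P]^nb)"},
        ),
    ]
    m.directives = [
        Directive("TIMECOURSE", {"t_end": 100.0, "npoints": 201}),
        Directive("PLOTALL"),
    ]
    m.validate()
    return m


def toggle_switch() -> Model:
    """Mutually repressing pair (R1, R2) with enzymatic clearance of each
    repressor (catalysed by inducer enzymes I1/I2, yielding inert X1/X2)
    and a GFP reporter repressed by R1 — 7 species, 5 reactions.

    Symmetric bistable parameterisation: cooperativity 2 and maximal
    production / (degradation * half-point) = 10.  Initial conditions
    start the system in its R1-high state (GFP dark); the pulse on I1
    clears R1 and flips it to the R2/GFP-high state.
    """
    m = Model(name="toggle_switch")
    m.parameters = [
        ParameterDef("ktr", "1", "maximal production rate of each repressor"),
        ParameterDef("kr", "1", "repression half-point"),
        ParameterDef("nr", "2", "repression cooperativity"),
        ParameterDef("d", "0.1", "repressor/reporter degradation rate"),
        ParameterDef("vmax", "1", "enzymatic clearance rate per enzyme"),
        ParameterDef("km", "1", "Michaelis constant of the clearance"),
    ]
    m.species = [
        SpeciesDef("R1", 10.0, 0.1),
        SpeciesDef("R2", 0.0, 0.1),
        SpeciesDef("I1", 0.0, 0.2),
        SpeciesDef("I2", 0.0, 0.2),
        SpeciesDef("X1", 0.0, 0.05),
        SpeciesDef("X2", 0.0, 0.05),
        SpeciesDef("GFP", 0.0, 0.1),
    ]
    m.reactions = [
        Reaction("T1", products=[("R2", 1)], modifiers=["R1"],
                 params={"k_TR": "ktr", "activators": [], "repressors": [("kr", "nr")]}),
        Reaction("T2", products=[("R1", 1)], modifiers=["R2"],
                 params={"k_TR": "ktr", "activators": [], "repressors": [("kr", "nr")]}),
        Reaction("E3", reactants=[("R2", 1)], products=[("X2", 1)], modifiers=["I2"],
                 params={"v_max": "vmax", "K_m": "km"}),
        Reaction("E4", reactants=[("R1", 1)], products=[("X1", 1)], modifiers=["I1"],
                 params={"v_max": "vmax", "K_m": "km"}),
        Reaction("T5", products=[("GFP", 1)], modifiers=["R1"],
                 params={"k_TR": "ktr", "activators": [], "repressors": [("kr", "nr")]}),
    ]
    m.directives = [
        Directive("PULSE", {"species": "I1", "delay": 25.0, "length": 10.0,
                            "height": 1.0, "frequency": 0.0}),
        Directive("TIMECOURSE", {"t_end": 200.0, "npoints": 401}),
        Directive("PLOT", {"species_list": ["R1", "R2", "GFP"]}),
    ]
    m.validate()
    return m


def penicillin_bio() -> Model:
    """Biochemical half of a penicillin biosensor.

    A reaction chamber is separated from the surfaces of two sensing
    gates by a permeable gel; penicillinase coats surface 1.  Five
    species (penicillin Pen, hydrolysis product Pal, protons H, and the
    two phosphate-buffer forms HPO4/H2PO4) live in all three
    compartments and diffuse across both membranes (5 x 2 = 10 diffusion
    reactions); the buffer binding H + HPO4 <-> H2PO4 runs in each
    compartment (3 binding reactions); the enzymatic hydrolysis
    Pen -> Pal + H runs at surface 1 only.  16 species, 14 reactions.

    pH is a derived output: pH = -log10([H]).
    """
    m = Model(name="penicillin_bio")
    m.parameters = [
        ParameterDef("vmaxp", "50", "hydrolysis rate per enzyme"),
        ParameterDef("kmp", "5e-3", "hydrolysis Michaelis constant (mol/l)"),
        ParameterDef("dg", "0.05", "gel membrane diffusion constant"),
        ParameterDef("konb", "100", "buffer protonation rate (finite: buffering lags a fast proton burst)"),
        ParameterDef("kab", "6.31e-8", "buffer acid dissociation constant (pKa 7.2)"),
        ParameterDef("koffb", "konb*kab"),
        ParameterDef("pen0", "0.02", "initial penicillin dose (mol/l)"),
        ParameterDef("buf0", "0.05", "phosphate buffer concentration (mol/l)"),
        ParameterDef("h0", "6.31e-8", "initial free proton level (pH 7.2)"),
        ParameterDef("vsurf", "0.01", "surface compartment volume fraction"),
    ]
    comps = [("ch", 1.0), ("s1", 0.01), ("s2", 0.01)]
    diffusing = ["Pen", "Pal", "H", "HPO4", "H2PO4"]
    init = {"Pen": {"ch": 0.02, "s1": 0.0, "s2": 0.0},
            "Pal": {"ch": 0.0, "s1": 0.0, "s2": 0.0},
            "H": {c: 6.31e-8 for c, _ in comps},
            "HPO4": {c: 0.05 for c, _ in comps},
            "H2PO4": {c: 0.05 for c, _ in comps}}
    for sp in diffusing:
        for c, vol in comps:
            m.species.append(SpeciesDef(f"{sp}_{c}", init[sp][c], 0.0, vol))
    m.species.append(SpeciesDef("Enz_s1", 1e-3, 0.0, 0.01))

    m.reactions.append(
        Reaction("E1", reactants=[("Pen_s1", 1)],
                 products=[("Pal_s1", 1), ("H_s1", 1)], modifiers=["Enz_s1"],
                 params={"v_max": "vmaxp", "K_m": "kmp"})
    )
    for sp in diffusing:
        for surf in ("s1", "s2"):
            m.reactions.append(
                Reaction(f"F{sp}{surf}", reactants=[(f"{sp}_ch", 1)],
                         products=[(f"{sp}_{surf}", 1)], params={"D": "dg"})
            )
    for c, _ in comps:
        m.reactions.append(
            Reaction(f"B{c}", reactants=[(f"H_{c}", 1), (f"HPO4_{c}", 1)],
                     products=[(f"H2PO4_{c}", 1)],
                     params={"k_on": "konb", "k_off": "koffb"})
        )
    m.directives = [
        Directive("TIMECOURSE", {"t_end": 200.0, "npoints": 401}),
        Directive("PLOT", {"species_list": ["H_s1", "H_ch", "Pen_ch"]}),
    ]
    m.validate()
    return m


def band_detector() -> Model:
    """Incoherent feed-forward loop: the input AHL drives a sensitive
    activator branch (half-point 0.1) and an insensitive repressor branch
    (half-point 10); the reporter is activated by the first and sharply
    repressed by the second, so GFP is produced only at intermediate AHL
    levels."""
    m = Model(name="band_detector")
    m.parameters = [
        ParameterDef("ktr", "1", "maximal production rate"),
        ParameterDef("d", "0.1", "degradation rate"),
    ]
    m.species = [
        SpeciesDef("AHL", 0.0, 0.0),
        SpeciesDef("Act", 0.0, 0.1),
        SpeciesDef("R", 0.0, 0.1),
        SpeciesDef("GFP", 0.0, 0.1),
    ]
    m.reactions = [
        Reaction("TA", products=[("Act", 1)], modifiers=["AHL"],
                 params={"k_TR": "ktr", "activators": [(0.1, 2.0)], "repressors": []}),
        Reaction("TR", products=[("R", 1)], modifiers=["AHL"],
                 params={"k_TR": "ktr", "activators": [(10.0, 2.0)], "repressors": []}),
        Reaction("TG", products=[("GFP", 1)], modifiers=["Act", "R"],
                 params={"k_TR": "ktr", "activators": [(1.0, 2.0)],
                         "repressors": [(1.0, 4.0)]}),
    ]
    m.directives = [
        Directive("SWEEP", {"species": "AHL", "start": 1e-3, "stop": 1e3,
                            "npoints": 61, "scale": "log"}),
        Directive("PLOT", {"species_list": ["GFP"]}),
    ]
    m.validate()
    return m


def and_gate() -> Model:
    """Two-input AND: a pump transfers substrate from a clamped reservoir
    to the output, gated by the product of two Hill terms; the output is
    high only when both inputs are present."""
    m = Model(name="and_gate")
    m.parameters = [
        ParameterDef("vmax", "1", "maximal pump rate"),
        ParameterDef("ka", "1", "input half-point"),
        ParameterDef("na", "2", "input cooperativity"),
    ]
    m.species = [
        SpeciesDef("SRC", 10.0, 0.0),
        SpeciesDef("OUT", 0.0, 0.1),
        SpeciesDef("A", 0.0, 0.2),
        SpeciesDef("B", 0.0, 0.2),
    ]
    m.reactions = [
        Reaction("P1", reactants=[("SRC", 1)], products=[("OUT", 1)],
                 modifiers=["A", "B"],
                 params={"v_max": "vmax",
                         "regulators": [("ka", "na"), ("ka", "na")]}),
    ]
    m.directives = [
        Directive("FIX", {"species": "SRC", "value": 10.0}),
        Directive("TRUTHTABLE", {"inputs": ["A", "B"], "on_level": 1.0,
                                 "segment": 40.0}),
        Directive("PLOT", {"species_list": ["OUT"]}),
    ]
    m.validate()
    return m


def fixtures() -> dict[str, Model]:
    """The named reference models used throughout the test suite."""
    return {
        "self_inhibited": self_inhibited(),
        "toggle_switch": toggle_switch(),
        "penicillin_bio": penicillin_bio(),
        "band_detector": band_detector(),
        "and_gate": and_gate(),
    }
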