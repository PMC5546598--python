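"""NGSPICE netlist generation from a Model.

Device mapping (the circuit analogy, applied literally):

* species  -> node named after the species; a capacitor to ground whose
  value is the compartment volume, with ``ic=`` the initial
  concentration; a resistor to ground of value 1/d when the degradation
  rate d is nonzero;
* reaction with N reactants and M products -> N+M behavioral current
  sources (B devices) carrying the rate expression, connected so that a
  positive rate drains each reactant node and feeds each product node;
* passive diffusion -> a single resistor of value 1/D between the two
  nodes; decay reactions -> a leak resistor; constant production -> a
  fixed DC current source per product;
* FIX -> DC voltage source; PULSE / TRUTHTABLE -> pulsed current
  sources; WAVEFORM -> piecewise-linear current source;
* TIMECOURSE / TRUTHTABLE -> ``.tran``, SWEEP -> ``.dc``, TRANSFUNC ->
  ``.ac``, STEADY -> ``.op``; PLOT/PLOTALL -> control-block plot
  statements; pass-through lines are echoed verbatim.

Behavioral sources use the B-device expression dialect of the
open-source simulator; node voltages stand for concentrations
(``v(X)``).  The exact operator/function spelling is centralised in one
table so the dialect can be retargeted in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SpiceDialectError
from .expr import format_number, parse_expr
from .model import Directive, Model, Reaction
from .netlist import resolve_parameters

__all__ = ["SpiceDeck", "to_spice", "deck_lint"]

#: spelling of operators/functions in the target behavioral dialect
_DIALECT = {
    "+": "+",
    "-": "-",
    "*": "*",
    "/": "/",
    "^": "pow",  # emitted as pow(a,b)
    "exp": "exp",
    "ln": "ln",
    "sqrt": "sqrt",
    "min": "min",
    "max": "max",
    "pow": "pow",
    # log10 is not portable across distributions; expand via ln
    "log10": None,
}

_LN10 = "2.302585092994046"

_RESERVED_NODES = {"0", "gnd", "vdd", "vss", "time", "temp"}


@dataclass
class SpiceDeck:
    lines: list[str] = field(default_factory=list)
    nodes: list[str] = field(default_factory=list)
    reaction_source_count: int = 0

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _node(name: str) -> str:
    up = name.upper()
    return f"N_{up}" if up.lower() in _RESERVED_NODES else up


def _expr_to_spice(node) -> str:
    op = node[0]
    if op == "num":
        return format_number(node[1])
    if op == "param":
        return node[1]
    if op == "species":
        return f"v({_node(node[1])})"
    if op == "neg":
        return f"(-{_expr_to_spice(node[1])})"
    if op == "bin":
        a, b = _expr_to_spice(node[2]), _expr_to_spice(node[3])
        if node[1] == "^":
            return f"{_DIALECT['^']}({a},{b})"
        return f"({a}{_DIALECT[node[1]]}{b})"
    if op == "call":
        fn = node[1]
        args = [_expr_to_spice(a) for a in node[2]]
        if fn == "log10":
            return f"(ln({args[0]})/{_LN10})"
        spelled = _DIALECT.get(fn)
        if spelled is None:
            raise SpiceDialectError(
                f"function {fn!r} has no spelling in the target dialect"
            )
        return f"{spelled}({','.join(args)})"
    raise SpiceDialectError(f"cannot serialise {node!r}")


def _spice_expr(text: str) -> str:
    return _expr_to_spice(parse_expr(text))


def _pref(value) -> str:
    """A kinetic parameter reference inside a braced expression."""
    if isinstance(value, (int, float)):
        return format_number(value)
    return f"({_spice_expr(value)})" if not str(value).isidentifier() else str(value)


def _rate_expr(r: Reaction) -> str:
    """Rate expression of the reaction in behavioral-source syntax."""
    p = r.params
    t = r.rtype

    def V(sp):
        return f"v({_node(sp)})"

    def hill(sp, K, n):
        Ks, ns = _pref(K), _pref(n)
        return f"(pow({V(sp)},{ns})/(pow({Ks},{ns})+pow({V(sp)},{ns})))"

    if t == "B":
        fwd = "*".join([_pref(p["k_on"])] +
                       [f"pow({V(s)},{st})" if st != 1 else V(s) for s, st in r.reactants])
        rev = "*".join([_pref(p["k_off"])] +
                       [f"pow({V(s)},{st})" if st != 1 else V(s) for s, st in r.products])
        return f"{fwd}-{rev}"
    if t == "C":
        return _pref(p["beta"])
    if t == "D":
        return f"{_pref(p['d'])}*{V(r.reactants[0][0])}"
    if t == "E":
        S = V(r.reactants[0][0])
        E = "(" + "+".join(V(m) for m in r.modifiers) + ")" if r.modifiers else "1"
        return f"{_pref(p['v_max'])}*{E}*{S}/({_pref(p['K_m'])}+{S})"
    if t == "H":
        return f"{_pref(p['v_max'])}*{hill(r.reactants[0][0], p['K'], p['n'])}"
    if t == "L":
        mrna = "(" + "+".join(V(m) for m in r.modifiers) + ")"
        return f"{_pref(p['k_TL'])}*{mrna}"
    if t == "P":
        parts = [_pref(p["v_max"])]
        parts += [hill(m, K, n) for m, (K, n) in zip(r.modifiers, p["regulators"])]
        return "*".join(parts)
    if t == "T":
        na = len(p["activators"])
        a_terms = [f"pow({V(m)}/{_pref(K)},{_pref(n)})"
                   for m, (K, n) in zip(r.modifiers[:na], p["activators"])]
        r_terms = [f"pow({V(m)}/{_pref(K)},{_pref(n)})"
                   for m, (K, n) in zip(r.modifiers[na:], p["repressors"])]
        num = "+".join(a_terms) if a_terms else "1"
        den = "+".join(["1"] + a_terms + r_terms)
        return f"{_pref(p['k_TR'])}*({num})/({den})"
    if t == "X":
        return _spice_expr(p["rate"])
    raise SpiceDialectError(f"unknown reaction type {t!r}")


def to_spice(model: Model, title: str | None = None) -> SpiceDeck:
    """Generate the equivalent simulator deck (deterministic: the same
    Model always yields byte-identical text)."""
    model.validate()
    resolve_parameters(model)  # fail early on unresolvable parameters
    deck = SpiceDeck()
    out = deck.lines.append
    out(f"* {title or model.name}")

    if model.parameters:
        out("* parameters")
        for p in model.parameters:
            out(f".param {p.name}={{{_spice_expr(p.expression)}}}")

    remapped = [s.name for s in model.species if _node(s.name) != s.name.upper()]
    if remapped:
        out("* node-name remapping (reserved words prefixed with N_):")
        for name in remapped:
            out(f"*   {name} -> {_node(name)}")

    out("* species nodes: capacitor (compartment volume) + leak (1/degradation)")
    for s in model.species:
        nd = _node(s.name)
        deck.nodes.append(nd)
        out(f"C{nd} {nd} 0 {format_number(s.compartment)} "
            f"ic={format_number(s.initial_concentration)}")
        if s.degradation_rate > 0:
            out(f"R{nd} {nd} 0 {format_number(1.0 / s.degradation_rate)}")

    out("* reactions")
    for r in model.reactions:
        if r.rtype == "F":
            D = r.params["D"]
            a, b = _node(r.reactants[0][0]), _node(r.products[0][0])
            if isinstance(D, (int, float)):
                val = format_number(1.0 / float(D))
            else:
                val = f"{{1/({_spice_expr(D)})}}"
            out(f"R{r.name} {a} {b} {val}")
            continue
        if r.rtype == "D":
            d = r.params["d"]
            nd = _node(r.reactants[0][0])
            if isinstance(d, (int, float)):
                val = format_number(1.0 / float(d))
            else:
                val = f"{{1/({_spice_expr(d)})}}"
            out(f"R{r.name} {nd} 0 {val}")
            continue
        if r.rtype == "C":
            beta = _pref(r.params["beta"])
            for sp, st in r.products:
                pre = f"{st}*" if st != 1 else ""
                out(f"I{r.name}_{_node(sp)} 0 {_node(sp)} DC {{{pre}{beta}}}")
                deck.reaction_source_count += 1
            continue
        expr = _rate_expr(r)
        for sp, st in r.reactants:
            pre = f"{st}*" if st != 1 else ""
            out(f"B{r.name}_{_node(sp)} {_node(sp)} 0 I={{{pre}({expr})}}")
            deck.reaction_source_count += 1
        for sp, st in r.products:
            pre = f"{st}*" if st != 1 else ""
            out(f"B{r.name}_{_node(sp)} 0 {_node(sp)} I={{{pre}({expr})}}")
            deck.reaction_source_count += 1

    # stimuli
    analysis: Directive | None = model.analysis_directive()
    plots: list[list[str]] = []
    for d in model.directives:
        a = d.args
        if d.kind == "FIX":
            nd = _node(a["species"])
            out(f"VFIX_{nd} {nd} 0 DC {format_number(a['value'])}")
        elif d.kind == "PULSE":
            nd = _node(a["species"])
            period = 1.0 / a["frequency"] if a["frequency"] > 0 else 1e30
            out(f"ISTIM_{nd} 0 {nd} PULSE(0 {format_number(a['height'])} "
                f"{format_number(a['delay'])} 0 0 {format_number(a['length'])} "
                f"{format_number(period)})")
        elif d.kind == "WAVEFORM":
            nd = _node(a["species"])
            out(f"ISTIM_{nd} 0 {nd} PWL({_pwl(a['points'])})")
        elif d.kind == "TRUTHTABLE":
            seg = a["segment"]
            # binary-order periodic drive: bit b toggles every 2^b segments
            for b, sp in enumerate(a["inputs"]):
                nd = _node(sp)
                width = (2**b) * seg
                out(f"ISTIM_{nd} 0 {nd} PULSE(0 {format_number(a['on_level'])} "
                    f"{format_number(width)} 0 0 {format_number(width)} "
                    f"{format_number(2 * width)})")
        elif d.kind == "TRANSFUNC":
            nd = _node(a["input"])
            out(f"IAC_{nd} 0 {nd} DC 0 AC 1")
        elif d.kind == "PLOT":
            plots.append([_node(s) for s in a["species_list"]])
        elif d.kind == "PLOTALL":
            plots.append([_node(s.name) for s in model.species])

    if analysis is not None:
        a = analysis.args
        if analysis.kind == "TIMECOURSE":
            step = a["t_end"] / max(a["npoints"] - 1, 1)
            out(f".tran {format_number(step)} {format_number(a['t_end'])} uic")
        elif analysis.kind == "TRUTHTABLE":
            total = (2 ** len(a["inputs"])) * a["segment"]
            out(f".tran {format_number(total / 400.0)} {format_number(total)} uic")
        elif analysis.kind == "SWEEP":
            nd = _node(a["species"])
            out(f"VSWEEP_{nd} {nd} 0 DC {format_number(a['start'])}")
            step = (a["stop"] - a["start"]) / max(a["npoints"] - 1, 1)
            out(f".dc VSWEEP_{nd} {format_number(a['start'])} "
                f"{format_number(a['stop'])} {format_number(step)}")
        elif analysis.kind == "TRANSFUNC":
            out(f".ac dec 10 {format_number(a['fmin'])} {format_number(a['fmax'])}")
        elif analysis.kind == "STEADY":
            out(".op")

    for raw in model.passthrough:
        out(raw)

    if plots:
        out(".control")
        out("run")
        for group in plots:
            out("plot " + " ".join(f"v({nd})" for nd in group))
        out(".endc")
    out(".end")
    return deck


def _pwl(points: list[tuple[float, float]]) -> str:
    """Piecewise-constant levels as a PWL sequence with sharp steps."""
    out = []
    level = 0.0
    eps = 1e-9
    for t, v in points:
        if t > 0:
            out.append((t, level))
            out.append((t + eps, v))
        else:
            out.append((0.0, v))
        level = v
    return " ".join(f"{format_number(t)} {format_number(v)}" for t, v in out)


# ---------------------------------------------------------------------------
# lint


def deck_lint(deck: SpiceDeck) -> list[str]:
    """Static checks on a generated deck: `.end` present, exactly one
    analysis directive, no device attached to an undeclared node."""
    findings: list[str] = []
    code = [ln for ln in deck.lines if ln and not ln.startswith("*")]
    if not code or code[-1].lower() != ".end":
        findings.append("missing .end (must be the last statement)")
    analyses = [ln for ln in code
                if ln.lower().split()[0] in (".tran", ".dc", ".ac", ".op")]
    if len(analyses) > 1:
        findings.append(f"multiple analyses: {len(analyses)} directives found")
    declared = {n.lower() for n in deck.nodes} | {"0"}
    in_control = False
    used: set[str] = set()
    for ln in code:
        tok = ln.split()
        head = tok[0].lower()
        if head == ".control":
            in_control = True
            continue
        if head == ".endc":
            in_control = False
            continue
        if in_control or head.startswith("."):
            continue
        if head[0] in "crbivg" and len(tok) >= 3:
            for nd in tok[1:3]:
                used.add(nd.lower())
                if nd.lower() not in declared:
                    findings.append(
                        f"device {tok[0]} attached to undeclared node {nd}"
                    )
    floating = declared - used - {"0"}
    for nd in sorted(floating):
        findings.append(f"node {nd} has no attached device")
    return findings
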