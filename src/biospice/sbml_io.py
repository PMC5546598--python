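"""SBML (Systems Biology Markup Language) import and export.

Import accepts Level 2 and Level 3 core documents and maps them onto the
package's :class:`~biospice.model.Model`:

* global parameters -> named parameters;
* species -> species, with the compartment size recorded as the node's
  volume (the capacitor value in the circuit analogy); boundary-condition
  and constant species become FIX clamps;
* every reaction -> one custom-rate (X) reaction whose formula is the
  kinetic law with reaction-local parameters substituted by value and
  user-defined function calls inlined;
* assignment rules -> algebraic assignments re-evaluated at every rhs
  call; rate rules on species -> extra derivative contributions;
* events that are triggered purely by time and assign constant values to
  parameters -> piecewise-in-time parameter steps.

Everything else (algebraic rules, species-targeted or
concentration-triggered events, unit definitions, SBML packages) is
recorded in the :class:`ImportReport`'s ``dropped`` list, or raised in
strict mode.

Export writes Level 3 Version 1: literal parameters become SBML
parameters, dependent parameters become assignment rules, each typed
reaction is emitted with a kinetic-law formula built from its rate law
(numeric kinetic constants become global parameters named
``<reaction>_<param>``), and each species with a nonzero degradation
rate gains one extra first-order degradation reaction (SBML has no
native degradation field).  Simulation directives have no SBML
counterpart and are omitted.

Kinetic-law convention: the formula equals the package's reaction flux,
so that d[X]/dt = (sum of signed stoichiometry-weighted laws) /
compartment size on both sides of a round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from lxml import etree

from .errors import CycleError, SbmlError
from .expr import format_number, free_symbols, parse_expr, substitute, to_text
from .model import Directive, Model, ParameterDef, Reaction, SpeciesDef

__all__ = ["ImportReport", "import_sbml", "export_sbml"]

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


@dataclass
class ImportReport:
    """Partition of the source document's constructs into those that were
    translated and those that were dropped (with a reason)."""

    supported: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(el, name):
    return [c for c in el if _local(c.tag) == name]


def _child(el, name):
    found = _children(el, name)
    return found[0] if found else None


# ---------------------------------------------------------------------------
# MathML -> AST

_BINARY = {"divide": "/", "power": "^"}


def _mathml_to_ast(el, species: set[str], functions: dict, compartments: dict):
    """Convert a content-MathML element into the package expression AST.

    ``functions`` maps function-definition ids to (argument names, body
    AST); invocations are inlined.  Compartment references become their
    numeric size.
    """
    tag = _local(el.tag)
    if tag == "math":
        kids = [c for c in el if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise SbmlError("math element must contain exactly one expression")
        return _mathml_to_ast(kids[0], species, functions, compartments)
    if tag == "cn":
        return ("num", _parse_cn(el))
    if tag == "ci":
        name = (el.text or "").strip()
        if name in species:
            return ("species", name)
        if name in compartments:
            return ("num", float(compartments[name]))
        return ("param", name)
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        raise SbmlError(f"csymbol {url!r} (e.g. time/delay) is not supported "
                        "inside kinetic formulas")
    if tag == "pi":
        return ("num", 3.141592653589793)
    if tag == "exponentiale":
        return ("num", 2.718281828459045)
    if tag == "piecewise":
        raise SbmlError("piecewise expressions are not supported")
    if tag != "apply":
        raise SbmlError(f"unsupported MathML element <{tag}>")

    kids = [c for c in el if isinstance(c.tag, str)]
    head, args_el = kids[0], kids[1:]
    op = _local(head.tag)
    if op == "ci":  # user-defined function call
        fname = (head.text or "").strip()
        if fname not in functions:
            raise SbmlError(f"call to undefined function {fname!r}")
        argnames, body = functions[fname]
        if len(args_el) != len(argnames):
            raise SbmlError(f"function {fname!r} arity mismatch")
        args = [_mathml_to_ast(a, species, functions, compartments) for a in args_el]
        return substitute(body, params=dict(zip(argnames, args)))
    args = [_mathml_to_ast(a, species, functions, compartments) for a in args_el]
    if op == "plus":
        if not args:
            return ("num", 0.0)
        node = args[0]
        for a in args[1:]:
            node = ("bin", "+", node, a)
        return node
    if op == "times":
        if not args:
            return ("num", 1.0)
        node = args[0]
        for a in args[1:]:
            node = ("bin", "*", node, a)
        return node
    if op == "minus":
        if len(args) == 1:
            return ("neg", args[0])
        return ("bin", "-", args[0], args[1])
    if op in _BINARY:
        if len(args) != 2:
            raise SbmlError(f"<{op}> takes two operands")
        return ("bin", _BINARY[op], args[0], args[1])
    if op == "exp":
        return ("call", "exp", (args[0],))
    if op == "ln":
        return ("call", "ln", (args[0],))
    if op == "log":
        # optional <logbase>; MathML default base is 10
        base_el = _child(el, "logbase")
        if base_el is not None:
            base_kids = [c for c in base_el if isinstance(c.tag, str)]
            base = _mathml_to_ast(base_kids[0], species, functions, compartments)
            val = args[-1]
            return ("bin", "/", ("call", "ln", (val,)), ("call", "ln", (base,)))
        return ("call", "log10", (args[-1],))
    if op == "root":
        deg_el = _child(el, "degree")
        if deg_el is None:
            return ("call", "sqrt", (args[-1],))
        deg_kids = [c for c in deg_el if isinstance(c.tag, str)]
        deg = _mathml_to_ast(deg_kids[0], species, functions, compartments)
        return ("bin", "^", args[-1], ("bin", "/", ("num", 1.0), deg))
    if op in ("min", "max"):
        if len(args) != 2:
            raise SbmlError(f"<{op}> supported with two operands only")
        return ("call", op, (args[0], args[1]))
    raise SbmlError(f"unsupported MathML operator <{op}>")


def _parse_cn(el) -> float:
    ctype = el.get("type", "real")
    if ctype == "e-notation":
        parts = [el.text or "0"]
        for c in el:
            if _local(c.tag) == "sep":
                parts.append(c.tail or "0")
        return float(parts[0].strip()) * 10.0 ** float(parts[1].strip())
    if ctype == "rational":
        parts = [el.text or "0"]
        for c in el:
            if _local(c.tag) == "sep":
                parts.append(c.tail or "1")
        return float(parts[0].strip()) / float(parts[1].strip())
    return float((el.text or "0").strip())


# ---------------------------------------------------------------------------
# AST -> MathML


def _ast_to_mathml(node, parent):
    op = node[0]
    M = lambda tag: etree.SubElement(parent, f"{{{MATHML_NS}}}{tag}")  # noqa: E731
    if op == "num":
        v = float(node[1])
        cn = M("cn")
        if v == int(v) and abs(v) < 1e15:
            cn.set("type", "integer")
            cn.text = str(int(v))
        else:
            cn.text = repr(v)
        return
    if op in ("param", "species"):
        ci = M("ci")
        ci.text = node[1]
        return
    if op == "neg":
        ap = M("apply")
        etree.SubElement(ap, f"{{{MATHML_NS}}}minus")
        _ast_to_mathml(node[1], ap)
        return
    if op == "bin":
        opname = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
                  "^": "power"}[node[1]]
        ap = M("apply")
        etree.SubElement(ap, f"{{{MATHML_NS}}}{opname}")
        _ast_to_mathml(node[2], ap)
        _ast_to_mathml(node[3], ap)
        return
    if op == "call":
        fn = node[1]
        ap = M("apply")
        if fn == "log10":
            etree.SubElement(ap, f"{{{MATHML_NS}}}log")
        elif fn == "sqrt":
            etree.SubElement(ap, f"{{{MATHML_NS}}}root")
        elif fn == "pow":
            etree.SubElement(ap, f"{{{MATHML_NS}}}power")
        else:
            etree.SubElement(ap, f"{{{MATHML_NS}}}{fn}")
        for a in node[2]:
            _ast_to_mathml(a, ap)
        return
    raise SbmlError(f"cannot serialise AST node {node!r}")


# ---------------------------------------------------------------------------
# import


def import_sbml(document: str | bytes, strict: bool = False) -> tuple[Model, ImportReport]:
    """Read an SBML document (XML text/bytes or a file path) into a Model.

    Returns ``(model, report)``; in strict mode any dropped construct
    raises :class:`~biospice.errors.SbmlError` instead.
    """
    if isinstance(document, str) and "<" not in document:
        with open(document, "rb") as fh:
            data = fh.read()
    else:
        data = document.encode() if isinstance(document, str) else document
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"not well-formed XML: {exc}") from None
    if _local(root.tag) != "sbml":
        raise SbmlError("root element is not <sbml>")
    model_el = _child(root, "model")
    if model_el is None:
        raise SbmlError("document has no <model>")

    report = ImportReport()
    model = Model(name=model_el.get("id") or model_el.get("name") or "sbml_model")

    def drop(construct: str, reason: str):
        if strict:
            raise SbmlError(f"{construct}: {reason}")
        report.dropped.append((construct, reason))

    if _children(model_el, "listOfUnitDefinitions"):
        for u in _children(_child(model_el, "listOfUnitDefinitions"), "unitDefinition"):
            drop(f"unitDefinition {u.get('id')!r}", "units are ignored")

    compartments: dict[str, float] = {}
    lo = _child(model_el, "listOfCompartments")
    for c in _children(lo, "compartment") if lo is not None else []:
        size = float(c.get("size", c.get("volume", "1") or "1"))
        compartments[c.get("id")] = size
        report.supported.append(f"compartment {c.get('id')!r}")

    species_ids: set[str] = set()
    boundary: list[tuple[str, float]] = []
    lo = _child(model_el, "listOfSpecies")
    for s in _children(lo, "species") if lo is not None else []:
        sid = s.get("id")
        vol = compartments.get(s.get("compartment"), 1.0)
        if s.get("initialConcentration") is not None:
            conc = float(s.get("initialConcentration"))
        elif s.get("initialAmount") is not None:
            conc = float(s.get("initialAmount")) / vol
        else:
            conc = 0.0
        model.species.append(SpeciesDef(sid, conc, 0.0, vol))
        species_ids.add(sid)
        if s.get("boundaryCondition") == "true" or s.get("constant") == "true":
            boundary.append((sid, conc))
        report.supported.append(f"species {sid!r}")

    lo = _child(model_el, "listOfParameters")
    for p in _children(lo, "parameter") if lo is not None else []:
        value = p.get("value")
        model.parameters.append(
            ParameterDef(p.get("id"), format_number(float(value)) if value is not None else "0")
        )
        report.supported.append(f"parameter {p.get('id')!r}")

    functions: dict[str, tuple[list[str], tuple]] = {}
    lo = _child(model_el, "listOfFunctionDefinitions")
    for f in _children(lo, "functionDefinition") if lo is not None else []:
        fid = f.get("id")
        math = _child(f, "math")
        lam = _child(math, "lambda") if math is not None else None
        if lam is None:
            drop(f"functionDefinition {fid!r}", "no lambda body")
            continue
        argnames = []
        body = None
        for c in lam:
            if _local(c.tag) == "bvar":
                ci = _child(c, "ci")
                argnames.append((ci.text or "").strip())
            else:
                body = _mathml_to_ast(c, species_ids, functions, compartments)
        functions[fid] = (argnames, body)
        report.supported.append(f"functionDefinition {fid!r} (inlined)")

    lo = _child(model_el, "listOfRules")
    assignments: list[tuple[str, str]] = []
    for rule in lo if lo is not None else []:
        tag = _local(rule.tag)
        if tag == "algebraicRule":
            drop("algebraicRule", "algebraic rules are not supported")
            continue
        var = rule.get("variable")
        try:
            ast = _mathml_to_ast(_child(rule, "math"), species_ids, functions, compartments)
        except SbmlError as exc:
            drop(f"{tag} for {var!r}", str(exc))
            continue
        if tag == "assignmentRule":
            assignments.append((var, to_text(ast)))
            report.supported.append(f"assignmentRule {var!r}")
        elif tag == "rateRule":
            if var in species_ids:
                model.rate_rules.append((var, to_text(ast)))
                report.supported.append(f"rateRule {var!r}")
            else:
                drop(f"rateRule for {var!r}",
                     "rate rules on parameters are not supported")
    model.assignments = _order_assignments(assignments)

    lo = _child(model_el, "listOfReactions")
    for rx in _children(lo, "reaction") if lo is not None else []:
        rid = rx.get("id")
        r = Reaction(name=f"X_{rid}" if rid[0].upper() != "X" else rid)
        for role, attr in (("reactants", "listOfReactants"),
                           ("products", "listOfProducts")):
            lst = _child(rx, attr)
            for sr in _children(lst, "speciesReference") if lst is not None else []:
                st = float(sr.get("stoichiometry", "1") or "1")
                if st != int(st):
                    drop(f"reaction {rid!r}", f"non-integer stoichiometry {st}")
                    st = round(st)
                getattr(r, role).append((sr.get("species"), max(int(st), 1)))
        lst = _child(rx, "listOfModifiers")
        for mr in _children(lst, "modifierSpeciesReference") if lst is not None else []:
            r.modifiers.append(mr.get("species"))
        kl = _child(rx, "kineticLaw")
        if kl is None:
            drop(f"reaction {rid!r}", "no kinetic law; flux assumed 0")
            r.params = {"rate": "0"}
            model.reactions.append(r)
            continue
        locals_map: dict[str, float] = {}
        for lname in ("listOfLocalParameters", "listOfParameters"):
            lst = _child(kl, lname)
            for lp in (list(lst) if lst is not None else []):
                if _local(lp.tag) in ("localParameter", "parameter"):
                    locals_map[lp.get("id")] = float(lp.get("value", "0") or "0")
        try:
            ast = _mathml_to_ast(_child(kl, "math"), species_ids, functions, compartments)
        except SbmlError as exc:
            drop(f"reaction {rid!r} kinetic law", str(exc))
            ast = ("num", 0.0)
        if locals_map:
            ast = substitute(ast, params=locals_map)
            report.supported.append(
                f"reaction {rid!r}: {len(locals_map)} local parameter(s) substituted"
            )
        r.params = {"rate": to_text(ast)}
        model.reactions.append(r)
        report.supported.append(f"reaction {rid!r}")

    lo = _child(model_el, "listOfEvents")
    for ev in _children(lo, "event") if lo is not None else []:
        eid = ev.get("id") or "event"
        parsed = _parse_time_event(ev, species_ids)
        if parsed is None:
            drop(f"event {eid!r}",
                 "only time-triggered events assigning constants to parameters "
                 "are supported")
            continue
        t_ev, targets = parsed
        ok = True
        for target, value in targets:
            if target in species_ids:
                drop(f"event {eid!r}", "events modifying species are not supported")
                ok = False
                break
        if ok:
            for target, value in targets:
                model.param_events.append((t_ev, target, value))
            report.supported.append(f"event {eid!r} (time-triggered parameter step)")

    for sid, conc in boundary:
        model.directives.append(Directive("FIX", {"species": sid, "value": conc}))
        report.supported.append(f"boundary species {sid!r} clamped")

    # referenced-but-undeclared parameter symbols (e.g. compartments already
    # substituted) would surface at build time; validate structure now
    model.validate()
    return model, report


def _order_assignments(assignments: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Topologically order chained assignment rules; reject cycles."""
    if not assignments:
        return []
    targets = {t for t, _ in assignments}
    deps = {}
    for t, formula in assignments:
        deps[t] = free_symbols(parse_expr(formula)) & targets
    ordered: list[tuple[str, str]] = []
    done: set[str] = set()
    remaining = dict(assignments)
    while remaining:
        ready = [t for t in remaining if deps[t] <= done]
        if not ready:
            raise CycleError(remaining.keys())
        for t in ready:
            ordered.append((t, remaining.pop(t)))
            done.add(t)
    return ordered


def _parse_time_event(ev, species_ids):
    """Recognise trigger `time >= T` (or >) with constant parameter
    assignments; returns (T, [(target, value), ...]) or None."""
    trig = _child(ev, "trigger")
    math = _child(trig, "math") if trig is not None else None
    if math is None:
        return None
    kids = [c for c in math if isinstance(c.tag, str)]
    if len(kids) != 1 or _local(kids[0].tag) != "apply":
        return None
    apply_kids = [c for c in kids[0] if isinstance(c.tag, str)]
    if len(apply_kids) != 3 or _local(apply_kids[0].tag) not in ("geq", "gt"):
        return None
    lhs, rhs = apply_kids[1], apply_kids[2]
    if not (_local(lhs.tag) == "csymbol" and "time" in (lhs.get("definitionURL") or "")):
        return None
    if _local(rhs.tag) != "cn":
        return None
    t_ev = _parse_cn(rhs)
    targets = []
    lst = _child(ev, "listOfEventAssignments")
    for ea in _children(lst, "eventAssignment") if lst is not None else []:
        m = _child(ea, "math")
        mkids = [c for c in m if isinstance(c.tag, str)] if m is not None else []
        if len(mkids) != 1 or _local(mkids[0].tag) != "cn":
            return None
        targets.append((ea.get("variable"), _parse_cn(mkids[0])))
    if not targets:
        return None
    return t_ev, targets


# ---------------------------------------------------------------------------
# export


def _sanitize_sid(name: str, taken: set[str]) -> str:
    out = "".join(c if (c.isalnum() or c == "_") else "_" for c in name)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    base = out
    k = 1
    while out in taken:
        out = f"{base}_{k}"
        k += 1
    taken.add(out)
    return out


def _bracket(name: str) -> str:
    return f"[{name}]"


def _pname(r: Reaction, key: str, extra_params: dict, value) -> str:
    """Reference a kinetic parameter in a formula: bare parameter names pass
    through, numbers become a reaction-scoped global parameter, and other
    formulas are inlined in parentheses."""
    if isinstance(value, str):
        try:
            float(value)
        except ValueError:
            if value.isidentifier():
                return value
            return f"({value})"
        value = float(value)
    name = f"{r.name}_{key}"
    extra_params[name] = float(value)
    return name


def _rate_formula(r: Reaction, extra: dict) -> str:
    """Netlist-expression form of the reaction's rate law."""
    t = r.rtype
    p = r.params
    if t == "B":
        kon = _pname(r, "k_on", extra, p["k_on"])
        koff = _pname(r, "k_off", extra, p["k_off"])
        fwd = "*".join([kon] + [f"{_bracket(s)}^{st}" if st != 1 else _bracket(s)
                                for s, st in r.reactants]) or kon
        rev = "*".join([koff] + [f"{_bracket(s)}^{st}" if st != 1 else _bracket(s)
                                 for s, st in r.products]) or koff
        return f"{fwd}-{rev}"
    if t == "C":
        return _pname(r, "beta", extra, p["beta"])
    if t == "D":
        return f"{_pname(r, 'd', extra, p['d'])}*{_bracket(r.reactants[0][0])}"
    if t == "E":
        v = _pname(r, "v_max", extra, p["v_max"])
        km = _pname(r, "K_m", extra, p["K_m"])
        S = _bracket(r.reactants[0][0])
        E = "(" + "+".join(_bracket(m) for m in r.modifiers) + ")" if r.modifiers else "1"
        return f"{v}*{E}*{S}/({km}+{S})"
    if t == "F":
        D = _pname(r, "D", extra, p["D"])
        return f"{D}*({_bracket(r.reactants[0][0])}-{_bracket(r.products[0][0])})"
    if t == "H":
        v = _pname(r, "v_max", extra, p["v_max"])
        K = _pname(r, "K", extra, p["K"])
        n = _pname(r, "n", extra, p["n"])
        R = _bracket(r.reactants[0][0])
        return f"{v}*{R}^{n}/({K}^{n}+{R}^{n})"
    if t == "L":
        k = _pname(r, "k_TL", extra, p["k_TL"])
        mrna = "(" + "+".join(_bracket(m) for m in r.modifiers) + ")"
        return f"{k}*{mrna}"
    if t == "P":
        v = _pname(r, "v_max", extra, p["v_max"])
        factors = [v]
        for j, (m, (K, n)) in enumerate(zip(r.modifiers, p["regulators"]), 1):
            Kr = _pname(r, f"K{j}", extra, K)
            nr = _pname(r, f"n{j}", extra, n)
            M = _bracket(m)
            factors.append(f"({M}^{nr}/({Kr}^{nr}+{M}^{nr}))")
        return "*".join(factors)
    if t == "T":
        k = _pname(r, "k_TR", extra, p["k_TR"])
        na = len(p["activators"])
        a_terms, r_terms = [], []
        for j, (m, (K, n)) in enumerate(zip(r.modifiers[:na], p["activators"]), 1):
            Ka = _pname(r, f"KA{j}", extra, K)
            nn = _pname(r, f"nA{j}", extra, n)
            a_terms.append(f"({_bracket(m)}/{Ka})^{nn}")
        for j, (m, (K, n)) in enumerate(zip(r.modifiers[na:], p["repressors"]), 1):
            Kr = _pname(r, f"KR{j}", extra, K)
            nn = _pname(r, f"nR{j}", extra, n)
            r_terms.append(f"({_bracket(m)}/{Kr})^{nn}")
        num = "+".join(a_terms) if a_terms else "1"
        den = "+".join(["1"] + a_terms + r_terms)
        return f"{k}*({num})/({den})"
    if t == "X":
        return p["rate"]
    raise SbmlError(f"cannot export reaction type {t!r}")


def export_sbml(model: Model) -> str:
    """Serialise the Model as an SBML Level 3 Version 1 document (str)."""
    model.validate()
    if model.passthrough:
        warnings.warn(
            "raw simulator pass-through lines are not representable in SBML "
            "and were omitted",
            stacklevel=2,
        )
    nsmap = {None: SBML_L3_NS}
    sbml = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    taken: set[str] = set()
    mel = etree.SubElement(sbml, f"{{{SBML_L3_NS}}}model")
    mel.set("id", _sanitize_sid(model.name, taken))

    E = lambda parent, tag: etree.SubElement(parent, f"{{{SBML_L3_NS}}}{tag}")  # noqa: E731

    # compartments: one per distinct volume, in order of first appearance
    vols: dict[float, str] = {}
    for s in model.species:
        if s.compartment not in vols:
            vols[s.compartment] = (
                "cell" if s.compartment == 1.0 else f"comp{len(vols) + 1}"
            )
    if not vols:
        vols[1.0] = "cell"
    lc = E(mel, "listOfCompartments")
    for vol, cid in vols.items():
        c = E(lc, "compartment")
        c.set("id", cid)
        c.set("size", format_number(vol))
        c.set("spatialDimensions", "3")
        c.set("constant", "true")

    # FIX-clamped species survive the round trip as boundary species
    fixed = {d.args["species"]: d.args["value"]
             for d in model.directives if d.kind == "FIX"}
    ls = E(mel, "listOfSpecies")
    for s in model.species:
        el = E(ls, "species")
        el.set("id", s.name)
        el.set("compartment", vols[s.compartment])
        el.set(
            "initialConcentration",
            format_number(fixed.get(s.name, s.initial_concentration)),
        )
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "true" if s.name in fixed else "false")
        el.set("constant", "false")

    literal: list[tuple[str, float]] = []
    dependent: list[tuple[str, str]] = []
    for p in model.parameters:
        node = parse_expr(p.expression)
        if free_symbols(node):
            dependent.append((p.name, p.expression))
        else:
            from .expr import eval_expr

            literal.append((p.name, eval_expr(node, {})))

    extra_params: dict[str, float] = {}
    formulas: list[tuple[Reaction, str]] = []
    for r in model.reactions:
        formulas.append((r, _rate_formula(r, extra_params)))
    deg_reactions: list[tuple[str, str]] = []
    for s in model.species:
        if s.degradation_rate > 0:
            pname = f"deg_{s.name}_d"
            extra_params[pname] = s.degradation_rate
            deg_reactions.append((s.name, pname))

    lp = E(mel, "listOfParameters")
    for name, value in literal + sorted(extra_params.items()):
        el = E(lp, "parameter")
        el.set("id", name)
        el.set("value", format_number(value))
        el.set("constant", "true")
    for name, _ in dependent:
        el = E(lp, "parameter")
        el.set("id", name)
        el.set("constant", "false")

    if dependent:
        lr = E(mel, "listOfRules")
        for name, expression in dependent:
            rule = E(lr, "assignmentRule")
            rule.set("variable", name)
            math = etree.SubElement(rule, f"{{{MATHML_NS}}}math")
            _ast_to_mathml(parse_expr(expression), math)

    lrx = E(mel, "listOfReactions")

    def emit_reaction(rid, reactants, products, modifiers, formula):
        rx = E(lrx, "reaction")
        rx.set("id", rid)
        rx.set("reversible", "false")
        rx.set("fast", "false")
        if reactants:
            lst = E(rx, "listOfReactants")
            for sp, st in reactants:
                sr = E(lst, "speciesReference")
                sr.set("species", sp)
                sr.set("stoichiometry", str(st))
                sr.set("constant", "true")
        if products:
            lst = E(rx, "listOfProducts")
            for sp, st in products:
                sr = E(lst, "speciesReference")
                sr.set("species", sp)
                sr.set("stoichiometry", str(st))
                sr.set("constant", "true")
        if modifiers:
            lst = E(rx, "listOfModifiers")
            for sp in modifiers:
                mr = E(lst, "modifierSpeciesReference")
                mr.set("species", sp)
        kl = E(rx, "kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        _ast_to_mathml(parse_expr(formula), math)

    for r, formula in formulas:
        emit_reaction(r.name, r.reactants, r.products, r.modifiers, formula)
    for sp, pname in deg_reactions:
        emit_reaction(f"deg_{sp}", [(sp, 1)], [], [], f"{pname}*[{sp}]")

    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
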