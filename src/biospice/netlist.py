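"""Reader and writer for the SPICE-style biochemical netlist format.

A netlist is a line-oriented UTF-8 text file with four sections opened
by dot-keyword headers (case-insensitive)::

    .parameters
    vmax 1.2        ; maximal enzymatic rate
    km   vmax/2
    .species
    S 10 0.1        ; name, initial concentration, degradation rate
    P
    .reactions
    E1 {S} {P} {Enz} {vmax,km}
    .simulation
    TIMECOURSE 100 501
    PLOT {S,P}

Conventions (SPICE idiom):

* lines starting with ``*`` are comments; text after ``;`` is a comment;
* a line starting with ``$`` is passed through verbatim to the external
  simulator netlist (collected, never interpreted here);
* multi-valued arguments are comma-separated lists between braces; a
  literal ``0`` stands for an absent list;
* species inside brace lists may carry an integer stoichiometry prefix,
  ``2*A``;
* numeric literals accept scientific notation and engineering suffixes
  (``1.5k`` = 1500).

Reaction argument order follows the type table in :mod:`biospice.model`;
e.g. ``E1 {S} {P} {Enz} {vmax,km}`` declares substrate, product, enzyme
and the (v_max, K_m) pair, while ``T1 {mRNA} 0 {R} {ktr,kr,nr}``
declares a transcription with no activator and one repressor.
"""

from __future__ import annotations

from .errors import CrossRefError, CycleError, FormatError
from .expr import ExprError, eval_expr, format_number, free_symbols, parse_expr, parse_number
from .model import Directive, Model, ParameterDef, Reaction, SpeciesDef

__all__ = ["parse_netlist", "write_netlist", "resolve_parameters"]

_SECTIONS = {".parameters", ".species", ".reactions", ".simulation"}

# fields after the reaction name: species-list roles then the parameter list
_REACTION_LAYOUT = {
    "B": ("reactants", "products"),
    "C": ("products",),
    "D": ("reactants",),
    "E": ("reactants", "products", "modifiers"),
    "F": ("reactants", "products"),
    "H": ("reactants", "products"),
    "L": ("products", "modifiers"),
    "P": ("reactants", "products", "modifiers"),
    "T": ("products", "modifiers_act", "modifiers_rep"),
    "X": ("reactants", "products", "modifiers"),
}

_FLAT_PARAMS = {
    "B": ("k_on", "k_off"),
    "C": ("beta",),
    "D": ("d",),
    "E": ("v_max", "K_m"),
    "F": ("D",),
    "H": ("v_max", "K", "n"),
    "L": ("k_TL",),
}


def _split_fields(line: str, lineno: int) -> list[str]:
    """Split a line into blank-separated fields; ``{...}`` and ``'...'``
    groups count as single fields and may contain blanks."""
    fields: list[str] = []
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c.isspace():
            i += 1
            continue
        if c == "{":
            j = line.find("}", i)
            if j < 0:
                raise FormatError("unterminated '{' list", lineno)
            fields.append(line[i : j + 1])
            i = j + 1
        elif c == "'":
            j = line.find("'", i + 1)
            if j < 0:
                raise FormatError("unterminated quoted expression", lineno)
            fields.append(line[i : j + 1])
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            fields.append(line[i:j])
            i = j
    return fields


def _split_comment(line: str) -> tuple[str, str]:
    # ';' starts an inline comment unless it sits inside a quoted expression
    in_quote = False
    for i, c in enumerate(line):
        if c == "'":
            in_quote = not in_quote
        elif c == ";" and not in_quote:
            return line[:i], line[i + 1 :].strip()
    return line, ""


def _strip_comment(line: str) -> str:
    return _split_comment(line)[0]


def _parse_list(field: str, lineno: int, what: str) -> list[str]:
    if field == "0":
        return []
    if not (field.startswith("{") and field.endswith("}")):
        raise FormatError(f"{what}: expected a brace list or 0, got {field!r}", lineno)
    inner = field[1:-1].strip()
    if not inner:
        return []
    return [item.strip() for item in inner.split(",")]


def _parse_species_list(field: str, lineno: int, what: str) -> list[tuple[str, int]]:
    out = []
    for item in _parse_list(field, lineno, what):
        if "*" in item:
            pre, _, name = item.partition("*")
            try:
                stoich = int(pre)
            except ValueError:
                raise FormatError(
                    f"{what}: bad stoichiometry prefix in {item!r}", lineno
                ) from None
            if stoich < 1:
                raise FormatError(f"{what}: stoichiometry must be >= 1 in {item!r}", lineno)
        else:
            name, stoich = item, 1
        out.append((name.strip(), stoich))
    return out


def _parse_value(token: str):
    """A parameter-list entry: numeric literal -> float, else expression text."""
    try:
        return parse_number(token)
    except ExprError:
        return token


def _number(token: str, lineno: int, what: str) -> float:
    try:
        return parse_number(token)
    except ExprError:
        raise FormatError(f"{what}: expected a number, got {token!r}", lineno) from None


def _parse_reaction(fields: list[str], lineno: int) -> Reaction:
    name = fields[0]
    letter = name[0].upper()
    if letter not in _REACTION_LAYOUT:
        raise FormatError(
            f"unknown reaction-type letter {letter!r} in reaction {name!r}", lineno
        )
    layout = _REACTION_LAYOUT[letter]
    expected = len(layout) + 1
    args = fields[1:]
    if len(args) != expected:
        raise FormatError(
            f"reaction {name!r} (type {letter}) takes {expected} argument(s), "
            f"got {len(args)}",
            lineno,
        )
    r = Reaction(name=name)
    act_names: list[str] = []
    rep_names: list[str] = []
    for role, field in zip(layout, args[:-1]):
        pairs = _parse_species_list(field, lineno, f"reaction {name}")
        if role == "reactants":
            r.reactants = pairs
        elif role == "products":
            r.products = pairs
        elif role == "modifiers":
            r.modifiers = [s for s, _ in pairs]
        elif role == "modifiers_act":
            act_names = [s for s, _ in pairs]
        elif role == "modifiers_rep":
            rep_names = [s for s, _ in pairs]

    last = args[-1]
    if letter == "X":
        if not (last.startswith("'") and last.endswith("'") and len(last) >= 2):
            raise FormatError(
                f"reaction {name!r}: custom rate must be quoted between simple quotes",
                lineno,
            )
        r.params = {"rate": last[1:-1]}
        return r

    values = [_parse_value(v) for v in _parse_list(last, lineno, f"reaction {name}")]
    if letter in _FLAT_PARAMS:
        keys = _FLAT_PARAMS[letter]
        if len(values) != len(keys):
            raise FormatError(
                f"reaction {name!r} (type {letter}) needs {len(keys)} kinetic "
                f"parameter(s) {keys}, got {len(values)}",
                lineno,
            )
        r.params = dict(zip(keys, values))
    elif letter == "P":
        nmod = len(r.modifiers)
        if len(values) != 1 + 2 * nmod:
            raise FormatError(
                f"reaction {name!r}: pump with {nmod} regulator(s) needs "
                f"{1 + 2 * nmod} parameters (v_max then K_j, n_j pairs), got {len(values)}",
                lineno,
            )
        r.params = {
            "v_max": values[0],
            "regulators": [(values[1 + 2 * j], values[2 + 2 * j]) for j in range(nmod)],
        }
    elif letter == "T":
        na, nr = len(act_names), len(rep_names)
        r.modifiers = act_names + rep_names
        if len(values) != 1 + 2 * na + 2 * nr:
            raise FormatError(
                f"reaction {name!r}: transcription with {na} activator(s) and {nr} "
                f"repressor(s) needs {1 + 2 * na + 2 * nr} parameters, got {len(values)}",
                lineno,
            )
        r.params = {
            "k_TR": values[0],
            "activators": [
                (values[1 + 2 * j], values[2 + 2 * j]) for j in range(na)
            ],
            "repressors": [
                (values[1 + 2 * na + 2 * j], values[2 + 2 * na + 2 * j])
                for j in range(nr)
            ],
        }
    return r


def _parse_directive(fields: list[str], lineno: int) -> Directive:
    kind = fields[0].upper()
    args = fields[1:]

    def arity(n_min, n_max=None):
        n_max = n_min if n_max is None else n_max
        if not (n_min <= len(args) <= n_max):
            raise FormatError(
                f"directive {kind} takes {n_min}"
                + (f"..{n_max}" if n_max != n_min else "")
                + f" argument(s), got {len(args)}",
                lineno,
            )

    if kind == "FIX":
        arity(2)
        return Directive("FIX", {"species": args[0], "value": _number(args[1], lineno, kind)})
    if kind == "PULSE":
        arity(5)
        delay, length, height, freq = (_number(a, lineno, kind) for a in args[1:])
        return Directive(
            "PULSE",
            {"species": args[0], "delay": delay, "length": length,
             "height": height, "frequency": freq},
        )
    if kind == "WAVEFORM":
        arity(2)
        vals = [_number(v, lineno, kind) for v in _parse_list(args[1], lineno, kind)]
        if len(vals) % 2 or not vals:
            raise FormatError(
                f"{kind}: expected an even-length list of time,value pairs", lineno
            )
        points = [(vals[i], vals[i + 1]) for i in range(0, len(vals), 2)]
        times = [t for t, _ in points]
        if any(t < 0 for t in times) or times != sorted(set(times)):
            raise FormatError(f"{kind}: times must be nonnegative and increasing", lineno)
        return Directive("WAVEFORM", {"species": args[0], "points": points})
    if kind == "TRANSFUNC":
        arity(2, 5)
        d = {"input": args[0], "output": args[1], "fmin": 1e-3, "fmax": 1e3, "npoints": 121}
        if len(args) >= 4:
            d["fmin"] = _number(args[2], lineno, kind)
            d["fmax"] = _number(args[3], lineno, kind)
        if len(args) == 5:
            d["npoints"] = int(_number(args[4], lineno, kind))
        return Directive("TRANSFUNC", d)
    if kind == "TRUTHTABLE":
        arity(3)
        inputs = [s for s, _ in _parse_species_list(args[0], lineno, kind)]
        if not inputs:
            raise FormatError(f"{kind}: needs at least one input species", lineno)
        return Directive(
            "TRUTHTABLE",
            {"inputs": inputs, "on_level": _number(args[1], lineno, kind),
             "segment": _number(args[2], lineno, kind)},
        )
    if kind == "STEADY":
        arity(0)
        return Directive("STEADY")
    if kind == "SWEEP":
        arity(4, 5)
        scale = args[4].lower() if len(args) == 5 else "lin"
        if scale not in ("lin", "log"):
            raise FormatError(f"{kind}: scale must be lin or log, got {args[4]!r}", lineno)
        return Directive(
            "SWEEP",
            {"species": args[0], "start": _number(args[1], lineno, kind),
             "stop": _number(args[2], lineno, kind),
             "npoints": int(_number(args[3], lineno, kind)), "scale": scale},
        )
    if kind == "TIMECOURSE":
        arity(1, 2)
        npoints = int(_number(args[1], lineno, kind)) if len(args) == 2 else 201
        return Directive(
            "TIMECOURSE", {"t_end": _number(args[0], lineno, kind), "npoints": npoints}
        )
    if kind == "PLOT":
        arity(1)
        return Directive(
            "PLOT", {"species_list": [s for s, _ in _parse_species_list(args[0], lineno, kind)]}
        )
    if kind == "PLOTALL":
        arity(0)
        return Directive("PLOTALL")
    raise FormatError(f"unknown simulation directive {kind!r}", lineno)


def parse_netlist(text: str, name: str = "model") -> Model:
    """Parse netlist ``text`` into a validated :class:`~biospice.model.Model`."""
    model = Model(name=name)
    section = None
    raw_species: list[tuple[list[str], int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.lstrip().startswith("$"):
            model.passthrough.append(raw.lstrip()[1:].strip())
            continue
        line, comment = _split_comment(raw)
        line = line.strip()
        if not line or line.startswith("*"):
            continue
        if line.lower() in _SECTIONS:
            section = line.lower()
            continue
        if line.startswith("."):
            raise FormatError(f"unknown section header {line!r}", lineno)
        if section is None:
            raise FormatError("content before the first section header", lineno)
        fields = _split_fields(line, lineno)
        if section == ".parameters":
            model.parameters.append(
                ParameterDef(
                    name=fields[0], expression=" ".join(fields[1:]), comment=comment
                )
            )
            if len(fields) < 2:
                raise FormatError(f"parameter {fields[0]!r}: missing value", lineno)
        elif section == ".species":
            if len(fields) > 4:
                raise FormatError(
                    f"species {fields[0]!r}: at most 3 arguments "
                    "(initial, degradation, volume)", lineno
                )
            raw_species.append((fields, lineno))
        elif section == ".reactions":
            model.reactions.append(_parse_reaction(fields, lineno))
        elif section == ".simulation":
            model.directives.append(_parse_directive(fields, lineno))

    # species attribute values may reference parameters; evaluate them now
    env = resolve_parameters(model)
    for fields, lineno in raw_species:
        vals = []
        for tok in fields[1:]:
            try:
                vals.append(eval_expr(parse_expr(tok), env))
            except ExprError as exc:
                raise FormatError(f"species {fields[0]!r}: {exc}", lineno) from None
        model.species.append(
            SpeciesDef(
                name=fields[0],
                initial_concentration=vals[0] if len(vals) > 0 else 0.0,
                degradation_rate=vals[1] if len(vals) > 1 else 0.0,
                compartment=vals[2] if len(vals) > 2 else 1.0,
            )
        )
    model.validate()
    return model


def resolve_parameters(model: Model) -> dict[str, float]:
    """Evaluate every parameter to a number, in dependency (topological)
    order, so declaration order does not matter for acyclic sets."""
    exprs: dict[str, tuple] = {}
    for p in model.parameters:
        if p.name in exprs:
            raise FormatError(f"duplicate parameter name {p.name!r}")
        try:
            exprs[p.name] = parse_expr(p.expression)
        except ExprError as exc:
            raise FormatError(f"parameter {p.name!r}: {exc}") from None
    deps = {}
    for name, node in exprs.items():
        refs = free_symbols(node)
        unknown = refs - exprs.keys()
        if unknown:
            raise CrossRefError(
                f"parameter {name!r} references undefined name(s): {sorted(unknown)}"
            )
        deps[name] = refs

    values: dict[str, float] = {}
    remaining = dict(deps)
    while remaining:
        ready = [n for n, d in remaining.items() if d <= values.keys()]
        if not ready:
            raise CycleError(remaining.keys())
        # preserve declaration order among ready names for reproducibility
        for n in [p.name for p in model.parameters if p.name in ready]:
            values[n] = eval_expr(exprs[n], values)
            if not _finite(values[n]):
                raise FormatError(f"parameter {n!r} evaluates to a non-finite value")
            del remaining[n]
    return values


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


# ---------------------------------------------------------------------------
# writer


def _fmt_value(v) -> str:
    return format_number(v) if isinstance(v, (int, float)) else str(v)


def _fmt_species_list(pairs: list[tuple[str, int]]) -> str:
    if not pairs:
        return "0"
    items = [(f"{st}*{sp}" if st != 1 else sp) for sp, st in pairs]
    return "{" + ",".join(items) + "}"


def _fmt_plain_list(names: list[str]) -> str:
    return "{" + ",".join(names) + "}" if names else "0"


def _reaction_line(r: Reaction) -> str:
    t = r.rtype
    mods = [(m, 1) for m in r.modifiers]
    if t == "X":
        return " ".join(
            [r.name, _fmt_species_list(r.reactants), _fmt_species_list(r.products),
             _fmt_species_list(mods), f"'{r.params['rate']}'"]
        )
    if t in _FLAT_PARAMS:
        values = [r.params[k] for k in _FLAT_PARAMS[t]]
    elif t == "P":
        values = [r.params["v_max"]]
        for K, n in r.params["regulators"]:
            values += [K, n]
    elif t == "T":
        values = [r.params["k_TR"]]
        for K, n in r.params["activators"]:
            values += [K, n]
        for K, n in r.params["repressors"]:
            values += [K, n]
    plist = "{" + ",".join(_fmt_value(v) for v in values) + "}"

    if t in ("B", "F", "H"):
        fields = [_fmt_species_list(r.reactants), _fmt_species_list(r.products)]
    elif t == "C":
        fields = [_fmt_species_list(r.products)]
    elif t == "D":
        fields = [_fmt_species_list(r.reactants)]
    elif t in ("E", "P"):
        fields = [_fmt_species_list(r.reactants), _fmt_species_list(r.products),
                  _fmt_species_list(mods)]
    elif t == "L":
        fields = [_fmt_species_list(r.products), _fmt_species_list(mods)]
    elif t == "T":
        na = len(r.params["activators"])
        fields = [
            _fmt_species_list(r.products),
            _fmt_plain_list(r.modifiers[:na]),
            _fmt_plain_list(r.modifiers[na:]),
        ]
    return " ".join([r.name] + fields + [plist])


def _directive_line(d: Directive) -> str:
    a = d.args
    f = format_number
    if d.kind == "FIX":
        return f"FIX {a['species']} {f(a['value'])}"
    if d.kind == "PULSE":
        return (f"PULSE {a['species']} {f(a['delay'])} {f(a['length'])} "
                f"{f(a['height'])} {f(a['frequency'])}")
    if d.kind == "WAVEFORM":
        flat = ",".join(f(x) for tv in a["points"] for x in tv)
        return f"WAVEFORM {a['species']} {{{flat}}}"
    if d.kind == "TRANSFUNC":
        return (f"TRANSFUNC {a['input']} {a['output']} {f(a['fmin'])} "
                f"{f(a['fmax'])} {a['npoints']}")
    if d.kind == "TRUTHTABLE":
        return (f"TRUTHTABLE {_fmt_plain_list(a['inputs'])} {f(a['on_level'])} "
                f"{f(a['segment'])}")
    if d.kind == "STEADY":
        return "STEADY"
    if d.kind == "SWEEP":
        return (f"SWEEP {a['species']} {f(a['start'])} {f(a['stop'])} "
                f"{a['npoints']} {a['scale']}")
    if d.kind == "TIMECOURSE":
        return f"TIMECOURSE {f(a['t_end'])} {a['npoints']}"
    if d.kind == "PLOT":
        return f"PLOT {_fmt_plain_list(a['species_list'])}"
    return "PLOTALL"


def write_netlist(model: Model) -> str:
    """Serialise a Model; ``parse_netlist(write_netlist(m))`` is structurally
    equal to ``m``."""
    lines = [f"* {model.name}", ".parameters"]
    for p in model.parameters:
        lines.append(f"{p.name} {p.expression}" + (f" ; {p.comment}" if p.comment else ""))
    lines.append(".species")
    for s in model.species:
        entry = f"{s.name} {format_number(s.initial_concentration)} " \
                f"{format_number(s.degradation_rate)}"
        if s.compartment != 1.0:
            entry += f" {format_number(s.compartment)}"
        lines.append(entry)
    lines.append(".reactions")
    for r in model.reactions:
        lines.append(_reaction_line(r))
    lines.append(".simulation")
    for d in model.directives:
        lines.append(_directive_line(d))
    for raw in model.passthrough:
        lines.append(f"$ {raw}")
    return "\n".join(lines) + "\n"
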