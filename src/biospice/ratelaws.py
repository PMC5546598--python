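"""Kinetic rate laws for every reaction type.

Each public ``rate_*`` function evaluates one reaction's flux (in
concentration/time for a unit compartment) at a :class:`RateContext`.
The laws:

* binding (B):        v = k_on * prod [R_k]^nR_k  -  k_off * prod [P_k]^nP_k
* constant (C):       v = beta
* decay (D):          v = d * [X]
* enzymatic (E):      v = v_max * [E] * [S] / (K_m + [S])
* diffusion (F):      v = D * ([X]_A - [X]_B)     (positive: flux A -> B)
* Hill (H):           v = v_max * [R]^n / (K^n + [R]^n)
* translation (L):    v = k_TL * [mRNA]
* pump (P):           v = v_max * prod_j [M_j]^n_j / (K_j^n_j + [M_j]^n_j)
* transcription (T):  v = k_TR * num / (1 + sum_a + sum_r), where
  sum_a = sum_j ([A_j]/KA_j)^nA_j over activators, sum_r likewise over
  repressors, and num = sum_a when at least one activator is declared,
  else 1 (constitutive promoter with pure repression).
* custom (X):         the quoted expression, evaluated verbatim.

With no activators a literal sum-form numerator would be identically
zero and the promoter could never fire; the num=1 convention makes the
law collapse to the standard repressor-only Hill form that toggle-switch
style circuits use.

``compile_rate`` turns a reaction into closures over the state vector
(flux and analytic partial derivatives) for the network assembler; the
custom type falls back to central finite differences for its partials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, ParameterError
from .expr import ExprError, eval_expr, free_species, parse_expr
from .model import Reaction

__all__ = [
    "RateContext",
    "rate",
    "rate_binding",
    "rate_constant",
    "rate_decay",
    "rate_enzymatic",
    "rate_diffusion",
    "rate_hill",
    "rate_translation",
    "rate_pump",
    "rate_transcription",
    "rate_custom",
    "resolve_reaction_params",
    "compile_rate",
]


@dataclass
class RateContext:
    concentrations: dict[str, float] = field(default_factory=dict)
    parameters: dict[str, float] = field(default_factory=dict)

    def conc(self, name: str) -> float:
        try:
            x = self.concentrations[name]
        except KeyError:
            raise DomainError(f"no concentration provided for species {name!r}") from None
        if x < 0:
            raise DomainError(f"negative concentration for species {name!r}: {x}")
        return float(x)


def _pval(v, params: dict[str, float]) -> float:
    """Resolve a reaction parameter entry: number or formula over parameters."""
    if isinstance(v, (int, float)):
        return float(v)
    try:
        return eval_expr(parse_expr(v), params)
    except ExprError as exc:
        raise ParameterError(f"cannot resolve kinetic parameter {v!r}: {exc}") from None


def resolve_reaction_params(r: Reaction, params: dict[str, float]) -> dict:
    """Numeric copy of ``r.params`` with formulas evaluated."""
    out = {}
    for k, v in r.params.items():
        if k == "rate":
            out[k] = v
        elif k in ("regulators", "activators", "repressors"):
            out[k] = [(_pval(K, params), _pval(n, params)) for K, n in v]
        else:
            out[k] = _pval(v, params)
    return out


def _hill(x: float, K: float, n: float) -> float:
    """x^n / (K^n + x^n), with the x=0 guard (0 for n>0)."""
    if x <= 0.0:
        return 0.0
    return x**n / (K**n + x**n)


def _dhill(x: float, K: float, n: float) -> float:
    """d/dx of the Hill term; returns the one-sided value at x=0."""
    if x <= 0.0:
        if n > 1.0:
            return 0.0
        if n == 1.0:
            return 1.0 / K
        return 0.0  # n<1: slope diverges; clamp (documented numerical choice)
    Kn, xn = K**n, x**n
    return n * Kn * x ** (n - 1.0) / (Kn + xn) ** 2


# ---------------------------------------------------------------------------
# individual laws


def rate_binding(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    k_on, k_off = p["k_on"], p["k_off"]
    if k_on < 0 or k_off < 0:
        raise ParameterError(f"reaction {r.name!r}: k_on and k_off must be >= 0")
    fwd = k_on
    for s, st in r.reactants:
        fwd *= ctx.conc(s) ** float(st)
    rev = 0.0
    if k_off:
        rev = k_off
        for s, st in r.products:
            rev *= ctx.conc(s) ** float(st)
    return fwd - rev


def rate_constant(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    return p["beta"]


def rate_decay(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    return p["d"] * ctx.conc(r.reactants[0][0])


def rate_enzymatic(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    if p["K_m"] <= 0:
        raise ParameterError(f"reaction {r.name!r}: K_m must be > 0")
    S = ctx.conc(r.reactants[0][0])
    # effective enzyme level: sum of listed enzymes; 1 when none is listed
    # (enzyme folded into v_max)
    E = sum(ctx.conc(m) for m in r.modifiers) if r.modifiers else 1.0
    return p["v_max"] * E * S / (p["K_m"] + S)


def rate_diffusion(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    if p["D"] < 0:
        raise ParameterError(f"reaction {r.name!r}: diffusion constant must be >= 0")
    return p["D"] * (ctx.conc(r.reactants[0][0]) - ctx.conc(r.products[0][0]))


def rate_hill(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    if p["K"] <= 0:
        raise ParameterError(f"reaction {r.name!r}: Hill constant K must be > 0")
    if p["n"] <= 0:
        raise ParameterError(f"reaction {r.name!r}: Hill number n must be > 0")
    return p["v_max"] * _hill(ctx.conc(r.reactants[0][0]), p["K"], p["n"])


def rate_translation(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    return p["k_TL"] * sum(ctx.conc(m) for m in r.modifiers)


def rate_pump(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    regs = p["regulators"]
    if len(regs) != len(r.modifiers):
        raise ParameterError(
            f"reaction {r.name!r}: regulator/parameter count mismatch"
        )
    v = p["v_max"]
    for m, (K, n) in zip(r.modifiers, regs):
        if K <= 0 or n <= 0:
            raise ParameterError(f"reaction {r.name!r}: Hill constants must be > 0")
        v *= _hill(ctx.conc(m), K, n)
    return v


def rate_transcription(ctx: RateContext, r: Reaction) -> float:
    p = resolve_reaction_params(r, ctx.parameters)
    act, rep = p["activators"], p["repressors"]
    if len(act) + len(rep) != len(r.modifiers):
        raise ParameterError(f"reaction {r.name!r}: factor/parameter count mismatch")
    for K, n in act + rep:
        if K <= 0 or n <= 0:
            raise ParameterError(f"reaction {r.name!r}: Hill constants must be > 0")
    a_terms = [
        (ctx.conc(m) / K) ** n if ctx.conc(m) > 0 else 0.0
        for m, (K, n) in zip(r.activators, act)
    ]
    r_terms = [
        (ctx.conc(m) / K) ** n if ctx.conc(m) > 0 else 0.0
        for m, (K, n) in zip(r.repressors, rep)
    ]
    num = sum(a_terms) if act else 1.0
    return p["k_TR"] * num / (1.0 + sum(a_terms) + sum(r_terms))


def rate_custom(ctx: RateContext, r: Reaction) -> float:
    node = parse_expr(r.params["rate"])
    for s in free_species(node):
        ctx.conc(s)  # domain check
    return eval_expr(node, ctx.parameters, ctx.concentrations)


_DISPATCH = {
    "B": rate_binding,
    "C": rate_constant,
    "D": rate_decay,
    "E": rate_enzymatic,
    "F": rate_diffusion,
    "H": rate_hill,
    "L": rate_translation,
    "P": rate_pump,
    "T": rate_transcription,
    "X": rate_custom,
}


def rate(ctx: RateContext, r: Reaction) -> float:
    """Dispatch on the reaction's type letter."""
    return _DISPATCH[r.rtype](ctx, r)


# ---------------------------------------------------------------------------
# compiled form (state-vector closures with analytic partials)


def compile_rate(r: Reaction, params: dict[str, float], index_of: dict[str, int]):
    """Compile a reaction into ``(flux(x), partials(x))`` closures over the
    state vector (concentrations assumed already clipped to >= 0).

    ``partials(x)`` returns a list of ``(state_index, d flux / d x_i)``.
    Analytic derivatives for the typed laws; central finite differences
    for custom expressions.
    """
    p = resolve_reaction_params(r, params)
    t = r.rtype

    if t == "B":
        k_on, k_off = p["k_on"], p["k_off"]
        if k_on < 0 or k_off < 0:
            raise ParameterError(f"reaction {r.name!r}: k_on and k_off must be >= 0")
        ri = [(index_of[s], st) for s, st in r.reactants]
        pi = [(index_of[s], st) for s, st in r.products]

        def flux(x):
            # left-folded so the result is bit-identical to the serialised
            # formula k_on*[R1]^n1*[R2]^n2-... evaluated left to right
            fwd = k_on
            for i, st in ri:
                fwd *= x[i] ** float(st)
            rev = 0.0
            if k_off:
                rev = k_off
                for i, st in pi:
                    rev *= x[i] ** float(st)
            return fwd - rev

        def partials(x):
            out = []
            for j, (i, st) in enumerate(ri):
                d = k_on * st * x[i] ** (st - 1)
                for k, (i2, st2) in enumerate(ri):
                    if k != j:
                        d *= x[i2] ** st2
                out.append((i, d))
            if k_off:
                for j, (i, st) in enumerate(pi):
                    d = -k_off * st * x[i] ** (st - 1)
                    for k, (i2, st2) in enumerate(pi):
                        if k != j:
                            d *= x[i2] ** st2
                    out.append((i, d))
            return out

        return flux, partials

    if t == "C":
        beta = p["beta"]
        return (lambda x: beta), (lambda x: [])

    if t == "D":
        d0 = p["d"]
        i = index_of[r.reactants[0][0]]
        return (lambda x: d0 * x[i]), (lambda x: [(i, d0)])

    if t == "E":
        v_max, K_m = p["v_max"], p["K_m"]
        if K_m <= 0:
            raise ParameterError(f"reaction {r.name!r}: K_m must be > 0")
        si = index_of[r.reactants[0][0]]
        ei = [index_of[m] for m in r.modifiers]

        def flux(x):
            E = sum(x[i] for i in ei) if ei else 1.0
            return v_max * E * x[si] / (K_m + x[si])

        def partials(x):
            E = sum(x[i] for i in ei) if ei else 1.0
            sat = x[si] / (K_m + x[si])
            out = [(si, v_max * E * K_m / (K_m + x[si]) ** 2)]
            out += [(i, v_max * sat) for i in ei]
            return out

        return flux, partials

    if t == "F":
        D = p["D"]
        if D < 0:
            raise ParameterError(f"reaction {r.name!r}: diffusion constant must be >= 0")
        ai, bi = index_of[r.reactants[0][0]], index_of[r.products[0][0]]
        return (lambda x: D * (x[ai] - x[bi])), (lambda x: [(ai, D), (bi, -D)])

    if t == "H":
        v_max, K, n = p["v_max"], p["K"], p["n"]
        if K <= 0 or n <= 0:
            raise ParameterError(f"reaction {r.name!r}: K and n must be > 0")
        i = index_of[r.reactants[0][0]]
        return (
            lambda x: v_max * _hill(x[i], K, n),
            lambda x: [(i, v_max * _dhill(x[i], K, n))],
        )

    if t == "L":
        k_TL = p["k_TL"]
        mi = [index_of[m] for m in r.modifiers]
        return (
            lambda x: k_TL * sum(x[i] for i in mi),
            lambda x: [(i, k_TL) for i in mi],
        )

    if t == "P":
        v_max = p["v_max"]
        regs = [(index_of[m], K, n) for m, (K, n) in zip(r.modifiers, p["regulators"])]
        for _, K, n in regs:
            if K <= 0 or n <= 0:
                raise ParameterError(f"reaction {r.name!r}: Hill constants must be > 0")

        def flux(x):
            v = v_max
            for i, K, n in regs:
                v *= _hill(x[i], K, n)
            return v

        def partials(x):
            hs = [_hill(x[i], K, n) for i, K, n in regs]
            out = []
            for j, (i, K, n) in enumerate(regs):
                rest = v_max
                for k, h in enumerate(hs):
                    if k != j:
                        rest *= h
                out.append((i, rest * _dhill(x[i], K, n)))
            return out

        return flux, partials

    if t == "T":
        k_TR = p["k_TR"]
        na = len(p["activators"])
        act = [(index_of[m], K, n) for m, (K, n) in zip(r.modifiers[:na], p["activators"])]
        rep = [(index_of[m], K, n) for m, (K, n) in zip(r.modifiers[na:], p["repressors"])]
        for _, K, n in act + rep:
            if K <= 0 or n <= 0:
                raise ParameterError(f"reaction {r.name!r}: Hill constants must be > 0")

        def _terms(x, group):
            return [((x[i] / K) ** n if x[i] > 0 else 0.0) for i, K, n in group]

        def _dterm(x, i, K, n):
            if x[i] <= 0:
                if n > 1:
                    return 0.0
                if n == 1:
                    return 1.0 / K
                return 0.0
            return n * (x[i] / K) ** (n - 1.0) / K

        def flux(x):
            a = _terms(x, act)
            rr = _terms(x, rep)
            num = sum(a) if act else 1.0
            return k_TR * num / (1.0 + sum(a) + sum(rr))

        def partials(x):
            a = _terms(x, act)
            rr = _terms(x, rep)
            num = sum(a) if act else 1.0
            den = 1.0 + sum(a) + sum(rr)
            out = []
            for (i, K, n) in act:
                da = _dterm(x, i, K, n)
                out.append((i, k_TR * da * (den - num) / den**2))
            for (i, K, n) in rep:
                dr = _dterm(x, i, K, n)
                out.append((i, -k_TR * num * dr / den**2))
            return out

        return flux, partials

    if t == "X":
        node = parse_expr(p["rate"])
        names = sorted(free_species(node))
        for s in names:
            if s not in index_of:
                raise ParameterError(
                    f"reaction {r.name!r}: expression references unknown species {s!r}"
                )
        idx = [index_of[s] for s in names]

        def flux(x):
            species = {s: x[i] for s, i in zip(names, idx)}
            return eval_expr(node, params, species)

        def partials(x):
            out = []
            species = {s: x[i] for s, i in zip(names, idx)}
            for s, i in zip(names, idx):
                h = max(1e-8, 1e-6 * abs(x[i]))
                hi = dict(species, **{s: x[i] + h})
                lo = dict(species, **{s: max(x[i] - h, 0.0)})
                step = hi[s] - lo[s]
                out.append((i, (eval_expr(node, params, hi) - eval_expr(node, params, lo)) / step))
            return out

        return flux, partials

    raise ParameterError(f"reaction {r.name!r}: unknown type {t!r}")
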