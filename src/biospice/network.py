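"""Assembly of a Model into its equivalent dynamical network.

The electronics analogy: every species is a node whose "voltage" is its
concentration; accumulation is a capacitor whose value is the
compartment volume; first-order degradation is a leak resistor; and each
reaction with N reactants and M products contributes N+M signed
controlled-source terms (one per participant, negative on the reactant
side, positive on the product side).  Passive diffusion contributes one
antisymmetric pair, decay one leak and constant production one fixed
source per product.  Modifiers (enzymes, transcription factors, pump
regulators) steer rates but carry no flux.

The resulting ODE for species X with volume V and degradation rate d is

    d[X]/dt = ( sum_reactions sign * stoich * v_reaction  -  d * [X] ) / V

Species clamped by FIX directives are held at their clamp value with a
zero derivative (the ideal-voltage-source analog).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BiospiceError, CrossRefError
from .expr import eval_expr, free_species, parse_expr
from .model import Model, Reaction
from .netlist import resolve_parameters
from .ratelaws import compile_rate

__all__ = ["OdeSystem", "build_system", "count_sources", "jacobian"]


@dataclass
class OdeSystem:
    model: Model
    species_order: list[str]
    volumes: np.ndarray
    degradation: np.ndarray
    x0: np.ndarray
    parameters: dict[str, float]
    clamped: dict[str, float] = field(default_factory=dict)
    #: per-species list of (reaction name, sign, stoichiometry)
    source_terms: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    # compiled internals; _env is the live parameter environment shared with
    # the compiled rate closures (updated in place by _prepare when the model
    # carries assignment rules or timed parameter events)
    _terms: list = field(default_factory=list, repr=False)
    _assignments: list = field(default_factory=list, repr=False)
    _rate_rules: list = field(default_factory=list, repr=False)
    _env: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.species_order)

    def index(self, name: str) -> int:
        try:
            return self.species_order.index(name)
        except ValueError:
            raise CrossRefError(f"unknown species {name!r}") from None

    # -- time-dependent parameter environment ---------------------------
    def params_at(self, t: float) -> dict[str, float]:
        """Parameter values at time ``t`` (left-continuous step changes at
        each time-triggered event)."""
        if not self.model.param_events:
            return self.parameters
        env = dict(self.parameters)
        for t_ev, target, value in sorted(self.model.param_events):
            if t >= t_ev:
                env[target] = value
        return env

    def event_times(self) -> list[float]:
        return sorted({t for t, _, _ in self.model.param_events})

    # -- state preparation ----------------------------------------------
    def _prepare(self, x: np.ndarray, t: float):
        """Clip negatives, apply clamps and assignment rules; returns the
        working state and the parameter environment."""
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)
        for name, value in self.clamped.items():
            xc[self.index(name)] = value
        env = self._env
        if self._assignments or self.model.param_events:
            # refresh the live environment the rate closures are bound to
            env.clear()
            env.update(self.params_at(t))
            if self._assignments:
                species = {s: xc[i] for i, s in enumerate(self.species_order)}
                for target, node, is_species, idx in self._assignments:
                    val = eval_expr(node, env, species)
                    if is_species:
                        xc[idx] = val
                        species[target] = val
                    else:
                        env[target] = val
        return xc, env

    # -- dynamics --------------------------------------------------------
    def rhs(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        xc, env = self._prepare(x, t)
        dx = -self.degradation * xc
        for flux, _, targets in self._terms:
            v = flux(xc)
            if not np.isfinite(v):
                raise BiospiceError(
                    f"non-finite reaction rate encountered at state {xc!r}"
                )
            for i, c in targets:
                dx[i] += c * v
        dx /= self.volumes
        if self._rate_rules:
            species = {s: xc[i] for i, s in enumerate(self.species_order)}
            for idx, node in self._rate_rules:
                dx[idx] += eval_expr(node, env, species)
        for name in self.clamped:
            dx[self.index(name)] = 0.0
        for target, _, is_species, idx in self._assignments:
            if is_species:
                dx[idx] = 0.0
        return dx

    def jac(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        return jacobian(self, x, t)

    def free_indices(self) -> np.ndarray:
        """Indices of species actually integrated (not clamped, not set by
        an assignment rule)."""
        fixed = {self.index(n) for n in self.clamped}
        fixed |= {idx for _, _, is_sp, idx in self._assignments if is_sp}
        return np.array([i for i in range(self.n) if i not in fixed], dtype=int)

    def with_clamp(self, species: str, value: float) -> "OdeSystem":
        """A copy of the system with one more species held fixed."""
        clamped = dict(self.clamped)
        clamped[species] = float(value)
        out = OdeSystem(
            model=self.model,
            species_order=self.species_order,
            volumes=self.volumes,
            degradation=self.degradation,
            x0=self.x0.copy(),
            parameters=self.parameters,
            clamped=clamped,
            source_terms=self.source_terms,
            _terms=self._terms,
            _assignments=self._assignments,
            _rate_rules=self._rate_rules,
            _env=self._env,
        )
        out.x0[out.index(species)] = float(value)
        return out

    # -- structure -------------------------------------------------------
    def rate_dependencies(self) -> set[str]:
        """Names of species whose concentration enters at least one rate law
        (or rule)."""
        deps: set[str] = set()
        for r in self.model.reactions:
            deps |= _rate_deps(r)
        for _, node, _, _ in self._assignments:
            deps |= free_species(node)
        for _, node in self._rate_rules:
            deps |= free_species(node)
        return deps

    def inert_species(self) -> set[str]:
        """Species feeding no rate law anywhere: their nodes (and attached
        sources) can be pruned without changing anyone else's dynamics."""
        deps = self.rate_dependencies()
        deps |= set(self.clamped)
        for d in self.model.directives:
            if "species" in d.args:
                deps.add(d.args["species"])
            deps.update(d.args.get("inputs", []))
            deps.update(d.args.get("species_list", []))  # plotted outputs stay
            for key in ("input", "output"):
                if key in d.args:
                    deps.add(d.args[key])
        return {s for s in self.species_order if s not in deps}


def _rate_deps(r: Reaction) -> set[str]:
    """Species whose concentration the reaction's rate depends on."""
    t = r.rtype
    if t == "B":
        deps = {s for s, _ in r.reactants}
        k_off = r.params.get("k_off", 0)
        if not (isinstance(k_off, (int, float)) and k_off == 0):
            deps |= {s for s, _ in r.products}
        return deps
    if t == "C":
        return set()
    if t in ("D", "H"):
        return {s for s, _ in r.reactants}
    if t == "E":
        return {r.reactants[0][0]} | set(r.modifiers)
    if t == "F":
        return {r.reactants[0][0], r.products[0][0]}
    if t == "L":
        return set(r.modifiers)
    if t in ("P", "T"):
        return set(r.modifiers)
    if t == "X":
        return free_species(parse_expr(r.params["rate"]))
    return set()


def _term_targets(r: Reaction, index_of: dict[str, int]):
    """Signed participant list for one reaction: -1 per reactant, +1 per
    product, scaled by stoichiometry."""
    out = []
    for s, st in r.reactants:
        out.append((index_of[s], -st))
    for s, st in r.products:
        out.append((index_of[s], +st))
    return out


def build_system(model: Model) -> OdeSystem:
    """Validate the model, resolve parameters and compile the ODE system."""
    model.validate()
    params = resolve_parameters(model)
    order = model.species_names()
    index_of = {s: i for i, s in enumerate(order)}

    system = OdeSystem(
        model=model,
        species_order=order,
        volumes=np.array([s.compartment for s in model.species], dtype=float),
        degradation=np.array([s.degradation_rate for s in model.species], dtype=float),
        x0=np.array([s.initial_concentration for s in model.species], dtype=float),
        parameters=params,
        source_terms={s: [] for s in order},
        _env=dict(params),
    )

    for r in model.reactions:
        flux, partials = compile_rate(r, system._env, index_of)
        targets = _term_targets(r, index_of)
        system._terms.append((flux, partials, targets))
        for i, c in targets:
            system.source_terms[order[i]].append(
                (r.name, 1 if c > 0 else -1, abs(c))
            )

    for target, formula in model.assignments:
        node = parse_expr(formula)
        if target in index_of:
            system._assignments.append((target, node, True, index_of[target]))
        else:
            system._assignments.append((target, node, False, -1))
    for target, formula in model.rate_rules:
        if target not in index_of:
            raise CrossRefError(f"rate rule targets unknown species {target!r}")
        system._rate_rules.append((index_of[target], parse_expr(formula)))

    for d in model.directives:
        if d.kind == "FIX":
            sp = d.args["species"]
            system.clamped[sp] = d.args["value"]
            system.x0[index_of[sp]] = d.args["value"]
    return system


def prune_inert_model(model: Model) -> Model:
    """Copy of the model with inert species (nodes feeding no rate law and
    not requested by any directive) removed, along with the source terms
    attached to them.  The retained species' dynamics are unchanged."""
    import copy

    system = build_system(model)
    inert = system.inert_species()
    out = copy.deepcopy(model)
    out.species = [s for s in out.species if s.name not in inert]
    for r in out.reactions:
        r.reactants = [(s, st) for s, st in r.reactants if s not in inert]
        r.products = [(s, st) for s, st in r.products if s not in inert]
    out.reactions = [
        r for r in out.reactions
        if r.reactants or r.products or r.rtype not in ("D", "F")
    ]
    out.validate()
    return out


def count_sources(system: OdeSystem, prune_inert: bool = False) -> int:
    """Number of controlled/fixed source terms in the equivalent circuit.

    Diffusion maps to a resistor and decay to a leak, so neither counts;
    every other reaction contributes one source per (non-pruned)
    reactant/product participant.
    """
    inert = system.inert_species() if prune_inert else set()
    count = 0
    for r in system.model.reactions:
        if r.rtype in ("F", "D"):
            continue
        participants = [s for s, _ in r.reactants] + [s for s, _ in r.products]
        count += sum(1 for s in participants if s not in inert)
    return count


def jacobian(system: OdeSystem, state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """J_ij = d(d[X_i]/dt)/d[X_j], analytic per rate law (finite differences
    inside custom-expression terms); clamped/rule-driven rows are zero."""
    xc, env = system._prepare(np.asarray(state, dtype=float), t)
    if not np.all(np.isfinite(system.rhs(state, t))):
        raise BiospiceError("non-finite rhs at the requested state")
    n = system.n
    J = np.diag(-system.degradation.astype(float))
    for flux, partials, targets in system._terms:
        for jdx, dv in partials(xc):
            for i, c in targets:
                J[i, jdx] += c * dv
    J /= system.volumes[:, None]
    if system._rate_rules:
        species = {s: xc[i] for i, s in enumerate(system.species_order)}
        for idx, node in system._rate_rules:
            for s in free_species(node):
                jdx = system.index(s)
                h = max(1e-8, 1e-6 * abs(xc[jdx]))
                hi = dict(species, **{s: species[s] + h})
                lo = dict(species, **{s: species[s] - h})
                J[idx, jdx] += (eval_expr(node, env, hi) - eval_expr(node, env, lo)) / (2 * h)
    zero_rows = [system.index(nm) for nm in system.clamped]
    zero_rows += [idx for _, _, is_sp, idx in system._assignments if is_sp]
    for i in zero_rows:
        J[i, :] = 0.0
    return J


def fd_jacobian(system: OdeSystem, state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Central finite-difference Jacobian; the independent cross-check for
    the analytic assembly."""
    x = np.asarray(state, dtype=float)
    n = system.n
    J = np.empty((n, n))
    for j in range(n):
        h = max(1e-8, 1e-6 * abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (system.rhs(xp, t) - system.rhs(xm, t)) / (2 * h)
    return J
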