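"""Analyses over an assembled :class:`~biospice.network.OdeSystem`.

Implements the directive set of the netlist language: operating-point
(steady-state) solving with a damped Newton iteration and a
pseudo-transient fallback, multistart stable-state search, stiff
transient integration with time-dependent stimuli, DC sweep by
continuation, small-signal transfer functions (Bode data) around an
operating point, and truth-table (Boolean stimulus) runs.

Numerical defaults: implicit stiff integrator (BDF) with rtol 1e-8 /
atol 1e-12, Newton convergence at ||rhs||_inf <= 1e-10.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, CrossRefError, IntegrationError
from .network import OdeSystem, jacobian

__all__ = [
    "Stimulus",
    "SimResult",
    "steady_state",
    "find_stable_states",
    "time_course",
    "dc_sweep",
    "transfer_function",
    "truth_table",
]

RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-12


@dataclass
class Stimulus:
    """A time-dependent input applied to one species.

    ``fixed`` clamps the concentration; ``pulse`` and ``waveform`` are
    additive molecule sources (amount/time, divided by the target
    compartment volume inside the rhs).  A pulse with frequency 0 fires
    once; a positive frequency repeats with period 1/frequency.
    """

    species: str
    shape: str  # fixed | pulse | waveform
    value: float = 0.0  # fixed level
    delay: float = 0.0
    length: float = 0.0
    height: float = 0.0
    frequency: float = 0.0
    points: list[tuple[float, float]] = field(default_factory=list)

    def source(self, t: float) -> float:
        if self.shape == "fixed":
            return 0.0
        if self.shape == "pulse":
            if t < self.delay:
                return 0.0
            tau = t - self.delay
            if self.frequency > 0:
                tau %= 1.0 / self.frequency
            return self.height if tau < self.length else 0.0
        if self.shape == "waveform":
            level = 0.0
            for tk, vk in self.points:
                if t >= tk:
                    level = vk
                else:
                    break
            return level
        raise ValueError(f"unknown stimulus shape {self.shape!r}")

    def discontinuities(self, t_end: float) -> list[float]:
        if self.shape == "fixed":
            return []
        if self.shape == "waveform":
            return [t for t, _ in self.points if 0.0 < t < t_end]
        out = []
        if self.frequency > 0:
            period = 1.0 / self.frequency
            k = 0
            while self.delay + k * period < t_end:
                start = self.delay + k * period
                out += [start, start + self.length]
                k += 1
        else:
            out = [self.delay, self.delay + self.length]
        return [t for t in out if 0.0 < t < t_end]


@dataclass
class SimResult:
    """Labelled series over a time, sweep or frequency axis."""

    axis: np.ndarray
    series: dict[str, np.ndarray]
    axis_kind: str  # time | sweep | frequency
    axis_label: str = ""
    failed_points: list[int] = field(default_factory=list)

    def __post_init__(self):
        for name, arr in self.series.items():
            if len(arr) != len(self.axis):
                raise ValueError(f"series {name!r} length mismatch with axis")

    def to_csv(self, path_or_buf) -> None:
        """Write axis + one column per series (deterministic formatting)."""
        close = False
        if isinstance(path_or_buf, (str, bytes)):
            fh = open(path_or_buf, "w", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow([self.axis_label or self.axis_kind] + list(self.series))
            cols = list(self.series.values())
            for i, a in enumerate(self.axis):
                w.writerow([repr(float(a))] + [repr(float(c[i])) for c in cols])
        finally:
            if close:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# steady state


def _clamped_state(system: OdeSystem, x: np.ndarray) -> np.ndarray:
    x = np.array(x, dtype=float)
    for name, value in system.clamped.items():
        x[system.index(name)] = value
    return x


def steady_state(
    system: OdeSystem,
    x0: np.ndarray | None = None,
    atol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Operating point: solve rhs(x*) = 0 by damped Newton from ``x0``
    (default: the model's initial concentrations), falling back to
    pseudo-transient integration when Newton stalls."""
    x = _clamped_state(system, system.x0 if x0 is None else x0)
    free = system.free_indices()
    if free.size == 0:
        return x

    def resid(xx):
        return system.rhs(xx)[free]

    best = np.inf
    for attempt in range(3):
        x, res = _newton(system, x, free, atol, max_iter)
        best = min(best, res)
        if res <= atol:
            return x
        # pseudo-transient fallback: relax toward an attractor, then retry
        x, ok = _pseudo_transient(system, x, free, atol)
        if ok and np.max(np.abs(resid(x))) <= atol:
            return x
    res = float(np.max(np.abs(resid(x))))
    if res <= atol:
        return x
    raise ConvergenceError(
        "steady-state search did not converge", residual=min(best, res), state=x
    )


def _newton(system, x, free, atol, max_iter):
    x = x.copy()
    fx = system.rhs(x)[free]
    norm = np.max(np.abs(fx))
    for _ in range(max_iter):
        if norm <= atol:
            return x, norm
        J = jacobian(system, x)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            J = J + 1e-12 * np.eye(len(free))
            try:
                step = np.linalg.solve(J, -fx)
            except np.linalg.LinAlgError:
                return x, norm
        lam = 1.0
        while lam > 1e-12:
            xt = x.copy()
            xt[free] = np.maximum(x[free] + lam * step, 0.0)
            try:
                ft = system.rhs(xt)[free]
            except Exception:
                lam /= 2
                continue
            nt = np.max(np.abs(ft)) if ft.size else 0.0
            if nt < norm or nt <= atol:
                x, fx, norm = xt, ft, nt
                break
            lam /= 2
        else:
            return x, norm  # stalled
    return x, norm


def _pseudo_transient(system, x, free, atol):
    horizon = 1.0
    for _ in range(9):
        try:
            sol = solve_ivp(
                lambda t, y: system.rhs(y, t),
                (0.0, horizon),
                x,
                method="BDF",
                jac=lambda t, y: jacobian(system, y, t),
                rtol=1e-8,
                atol=1e-10,
            )
        except Exception:
            return x, False
        if not sol.success:
            return x, False
        x = np.maximum(sol.y[:, -1], 0.0)
        x = _clamped_state(system, x)
        if np.max(np.abs(system.rhs(x)[free])) <= max(atol, 1e-9):
            return x, True
        horizon *= 10.0
    return x, False


def find_stable_states(
    system: OdeSystem,
    n_starts: int = 32,
    seed: int = 0,
    atol: float = 1e-10,
) -> list[np.ndarray]:
    """Multistart search for locally stable operating points.

    Starts are drawn log-uniformly over [1e-3, 1e3] x scale (scale = max
    initial concentration or 1), plus the model's own initial state.
    Solutions are deduplicated at relative distance < 1e-6 and kept only
    when every Jacobian eigenvalue (over the free coordinates) has a
    negative real part.
    """
    rng = np.random.default_rng(seed)
    free = system.free_indices()
    scale = max(float(np.max(system.x0)) if system.n else 1.0, 1.0)
    starts = [system.x0.copy()]
    for _ in range(n_starts):
        x = system.x0.copy()
        x[free] = scale * 10.0 ** rng.uniform(-3.0, 3.0, size=free.size)
        starts.append(x)

    solutions: list[np.ndarray] = []
    for x0 in starts:
        try:
            x = steady_state(system, x0, atol=atol)
        except ConvergenceError:
            continue
        if any(
            np.max(np.abs(x - s) / (1.0 + np.abs(s))) < 1e-6 for s in solutions
        ):
            continue
        solutions.append(x)

    stable = []
    for x in solutions:
        J = jacobian(system, x)[np.ix_(free, free)]
        lam = np.linalg.eigvals(J)
        thresh = -1e-9 * max(np.linalg.norm(J), 1.0)
        if np.all(lam.real < thresh):
            stable.append(x)
    stable.sort(key=lambda s: tuple(np.round(s, 9)))
    return stable


# ---------------------------------------------------------------------------
# transient


def time_course(
    system: OdeSystem,
    stimuli: list[Stimulus] | None = None,
    t_end: float = 100.0,
    n_points: int = 201,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    x0: np.ndarray | None = None,
) -> SimResult:
    """Integrate the stiff ODE from the initial concentrations with the
    given stimuli; the integrator restarts at every stimulus
    discontinuity and parameter-event time."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    stimuli = list(stimuli or [])
    sys_run = system
    sources = []
    for st in stimuli:
        if st.shape == "fixed":
            sys_run = sys_run.with_clamp(st.species, st.value)
        else:
            sources.append(st)
    src_idx = [(sys_run.index(s.species), s) for s in sources]
    vol = sys_run.volumes

    def rhs(t, y):
        dy = sys_run.rhs(y, t)
        for i, s in src_idx:
            dy[i] += s.source(t) / vol[i]
        return dy

    def jac(t, y):
        return jacobian(sys_run, y, t)

    breaks = set()
    for s in sources:
        breaks.update(s.discontinuities(t_end))
    breaks.update(t for t in sys_run.event_times() if 0.0 < t < t_end)
    if len(breaks) > 10_000:
        raise IntegrationError("too many stimulus discontinuities to resolve")
    edges = [0.0] + sorted(breaks) + [t_end]

    grid = np.linspace(0.0, t_end, n_points)
    out = np.empty((sys_run.n, n_points))
    x = _clamped_state(sys_run, sys_run.x0 if x0 is None else np.asarray(x0, float))
    filled = 0
    if grid[0] == 0.0:
        out[:, 0] = x
        filled = 1
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        sol = solve_ivp(
            rhs, (a, b), x, method="BDF", jac=jac,
            rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed: {sol.message}", t_last=float(sol.t[-1])
            )
        while filled < n_points and grid[filled] <= b + 1e-12 * max(b, 1.0):
            tq = min(grid[filled], sol.t[-1])
            out[:, filled] = sol.sol(tq)
            filled += 1
        x = sol.y[:, -1]
    series = {s: out[i, :] for i, s in enumerate(sys_run.species_order)}
    # clamped species read back as their clamp value
    for name, value in sys_run.clamped.items():
        series[name] = np.full(n_points, value)
    return SimResult(axis=grid, series=series, axis_kind="time", axis_label="time")


# ---------------------------------------------------------------------------
# sweep


def dc_sweep(system: OdeSystem, input_species: str, grid) -> SimResult:
    """Steady state vs a clamped input over ``grid``, by continuation:
    each point warm-starts from the previous solution."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("sweep grid values must be >= 0")
    system.index(input_species)
    out = np.full((system.n, grid.size), np.nan)
    failed: list[int] = []
    warm = None
    for k, v in enumerate(grid):
        clamped = system.with_clamp(input_species, float(v))
        try:
            x = steady_state(clamped, warm)
            out[:, k] = x
            warm = x
        except ConvergenceError:
            failed.append(k)
    series = {s: out[i, :] for i, s in enumerate(system.species_order)}
    return SimResult(
        axis=grid, series=series, axis_kind="sweep",
        axis_label=input_species, failed_points=failed,
    )


# ---------------------------------------------------------------------------
# small signal


def transfer_function(
    system: OdeSystem,
    input_species: str,
    output_species: str,
    omega_grid,
    x0: np.ndarray | None = None,
    input_mode: str = "source",
) -> SimResult:
    """Frequency response around the operating point.

    ``source`` mode (default, the electrical small-signal analog): a
    unit molecule source drives the input node, H(jw) =
    e_out^T (jwI - J)^{-1} e_in / V_in.  ``concentration`` mode instead
    treats the input species' concentration as the forced variable.
    """
    omega = np.asarray(omega_grid, dtype=float)
    xstar = steady_state(system, x0)
    J = jacobian(system, xstar)
    free = system.free_indices()
    pos = {int(i): k for k, i in enumerate(free)}
    i_out = system.index(output_species)
    i_in = system.index(input_species)
    if i_out not in pos:
        raise CrossRefError(f"output species {output_species!r} is clamped")

    mag = np.full(omega.size, np.nan)
    phase = np.full(omega.size, np.nan)
    failed: list[int] = []
    if input_mode == "source":
        if i_in not in pos:
            raise CrossRefError(f"input species {input_species!r} is clamped")
        Jf = J[np.ix_(free, free)]
        e_in = np.zeros(free.size)
        e_in[pos[i_in]] = 1.0 / system.volumes[i_in]
        for k, w in enumerate(omega):
            A = 1j * w * np.eye(free.size) - Jf
            try:
                h = np.linalg.solve(A, e_in)[pos[i_out]]
            except np.linalg.LinAlgError:
                failed.append(k)
                continue
            mag[k] = abs(h)
            phase[k] = math.atan2(h.imag, h.real)
    elif input_mode == "concentration":
        others = np.array([i for i in free if i != i_in], dtype=int)
        opos = {int(i): k for k, i in enumerate(others)}
        if i_out == i_in:
            raise ValueError("output must differ from the forced input")
        Jff = J[np.ix_(others, others)]
        Jfi = J[others, i_in]
        for k, w in enumerate(omega):
            A = 1j * w * np.eye(others.size) - Jff
            try:
                h = np.linalg.solve(A, Jfi)[opos[i_out]]
            except np.linalg.LinAlgError:
                failed.append(k)
                continue
            mag[k] = abs(h)
            phase[k] = math.atan2(h.imag, h.real)
    else:
        raise ValueError("input_mode must be 'source' or 'concentration'")
    return SimResult(
        axis=omega,
        series={"magnitude": mag, "phase": phase},
        axis_kind="frequency",
        axis_label="omega",
        failed_points=failed,
    )


# ---------------------------------------------------------------------------
# truth table


def _gray(k: int, n_bits: int) -> tuple[int, ...]:
    g = k ^ (k >> 1)
    return tuple((g >> b) & 1 for b in range(n_bits))


def truth_table(
    system: OdeSystem,
    inputs: list[str],
    on_level: float,
    segment: float,
    outputs: list[str] | None = None,
    points_per_segment: int = 25,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
):
    """Drive every Boolean combination of the input sources, one segment
    each in Gray-code order (one input flips per segment boundary), in a
    single continuous transient; report each output at each segment end.

    Returns ``(SimResult, table)`` with ``table`` a list of
    ``(combination, {output: end_value})``.
    """
    k = len(inputs)
    if not (1 <= k <= 16):
        raise ValueError("truth table supports 1..16 inputs")
    n_seg = 2**k
    combos = [_gray(s, k) for s in range(n_seg)]
    stimuli = []
    for b, sp in enumerate(inputs):
        pts = [(i * segment, on_level * combos[i][b]) for i in range(n_seg)]
        stimuli.append(Stimulus(species=sp, shape="waveform", points=pts))
    n_points = n_seg * points_per_segment + 1
    res = time_course(
        system, stimuli, t_end=n_seg * segment, n_points=n_points,
        rtol=rtol, atol=atol,
    )
    outputs = outputs or system.species_order
    table = []
    for i, combo in enumerate(combos):
        end = (i + 1) * points_per_segment
        table.append((combo, {o: float(res.series[o][end]) for o in outputs}))
    return res, table
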