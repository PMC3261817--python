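"""Intracellular apoptosis-switch modules and their analysis.

Two alternative switch modules map the intracellular drug concentration ``I``
(in units of 1 ng per 10^5 cells) onto the activity ``R`` of a signalling
intermediate, which drives an apoptosis effector ``R1``:

* monostable: a Hill-type first-order response, fully reversible in ``I``,
  paired with an *irreversible* population-level trigger (a latch);
* bistable: positive feedback with saturated degradation, which is itself
  hysteretic, paired with a *reversible* population-level trigger.

Cell death is triggered when ``R1`` crosses the threshold ``R1_th``.

Rate constants are in 1/hr and all state variables are normalized fractions
in [0, 1]; the functions here are used both standalone (bifurcation analysis,
calibration) and, rescaled by the diffusion time, inside the spatial
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .parameters import SignallingParameters

__all__ = [
    "SwitchState",
    "SteadyStateBranch",
    "TriggerStatus",
    "FoldReport",
    "CalibrationReport",
    "monostable_rate",
    "effector_rate",
    "bistable_rate",
    "bistable_rate_dR",
    "monostable_steady_state",
    "monostable_transient",
    "bistable_steady_states",
    "bistable_fold_inputs",
    "bistable_basal_state",
    "basal_switch_state",
    "apoptosis_trigger",
    "integrate_switch",
    "time_to_kill",
    "monostable_switching_threshold",
    "calibrate_module_match",
]

SwitchModule = Literal["monostable", "bistable"]

#: |d(rate)/dR| below this at a root is reported as degenerate (fold point).
_DEGENERATE_SLOPE = 1e-10


@dataclass(frozen=True)
class SwitchState:
    """Joint state of the switch intermediate and the apoptosis effector."""

    R: float
    R1: float


@dataclass(frozen=True)
class SteadyStateBranch:
    """One steady state of the bistable module at a fixed input ``I``."""

    I: float
    R_star: float
    stability: Literal["stable", "unstable", "degenerate"]


@dataclass(frozen=True)
class TriggerStatus:
    """Per-cell apoptosis trigger bookkeeping.

    ``monostable_latch`` mode is irreversible (fired only transitions
    False -> True); ``bistable_reversible`` tracks ``R1 >= R1_th``
    instantaneously.
    """

    fired: bool = False
    mode: Literal["monostable_latch", "bistable_reversible"] = "monostable_latch"
    time_fired: float | None = None


@dataclass(frozen=True)
class FoldReport:
    """Saddle-node (fold) inputs of the bistable module over ``I in [0, I_max]``.

    ``folds`` holds ``(I, n_before, n_after)`` triples where the steady-state
    branch count changes, ascending in I.  With the default parameters the
    module is already bistable at zero input (the lower saddle-node lies at
    negative, unphysical input), so the only fold in range is the *upper*
    one — the switching threshold above which only the high branch survives.
    An empty tuple means the branch count is constant over the whole range.
    """

    folds: tuple[tuple[float, int, int], ...]
    I_max: float

    @property
    def is_bistable(self) -> bool:
        """True if more than one steady state coexists somewhere in range."""
        return bool(self.folds) and max(max(f[1], f[2]) for f in self.folds) > 1

    @property
    def lower(self) -> float | None:
        """Fold where the branch count increases with I (None if out of range)."""
        for I, n_before, n_after in self.folds:
            if n_after > n_before:
                return I
        return None

    @property
    def upper(self) -> float | None:
        """Fold where the branch count drops with I: the switching threshold."""
        for I, n_before, n_after in reversed(self.folds):
            if n_after < n_before:
                return I
        return None

    def describe(self) -> str:
        if not self.folds:
            return f"monostable for all I in [0, {self.I_max:g}]"
        return (f"branch-count changes at I = "
                f"{', '.join(f'{f[0]:.6g} ({f[1]}->{f[2]})' for f in self.folds)}; "
                f"switching threshold (upper fold) at I = {self.upper:.6g}")


def _hill(I, k_h: float, n: float):
    I = np.asarray(I, dtype=float)
    if np.any(I < 0.0):
        raise ValueError("intracellular drug concentration I must be >= 0")
    with np.errstate(over="ignore"):
        num = np.power(I, n)
        out = num / (k_h**n + num)
    # I**n overflows for large I; the Hill term saturates at 1 there
    out = np.where(np.isfinite(num), out, 1.0)
    return out if out.ndim else float(out)


def monostable_rate(R, I, p: SignallingParameters):
    """dR/dt of the monostable switch, 1/hr: ``k*(I^n/(k_h^n+I^n) - R)``."""
    m = p.monostable
    return m.k * (_hill(I, m.k_h, m.n) - np.asarray(R, dtype=float))


def effector_rate(R1, R, p: SignallingParameters):
    """dR1/dt of the apoptosis effector, 1/hr: ``k_f*R*(1-R1) - k_r*R1``."""
    R1 = np.asarray(R1, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any((R1 < -1e-12) | (R1 > 1.0 + 1e-12)) or np.any((R < -1e-12) | (R > 1.0 + 1e-12)):
        raise ValueError("R and R1 must lie in [0, 1]")
    e = p.effector
    out = e.k_f * R * (1.0 - R1) - e.k_r * R1
    return out if out.ndim else float(out)


def bistable_rate(R, I, p: SignallingParameters):
    """dR/dt of the bistable switch, 1/hr.

    ``V_f*(1-R)/(K_m1+(1-R)) + (p+q*I)*k_fb*R*(1-R) - V_r*R/(K_m2+R)``
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0.0):
        raise ValueError("intracellular drug concentration I must be >= 0")
    R = np.asarray(R, dtype=float)
    b = p.bistable
    out = (b.V_f * (1.0 - R) / (b.K_m1 + (1.0 - R))
           + (b.p + b.q * I) * b.k_fb * R * (1.0 - R)
           - b.V_r * R / (b.K_m2 + R))
    return out if out.ndim else float(out)


def bistable_rate_dR(R, I, p: SignallingParameters):
    """Partial derivative of :func:`bistable_rate` with respect to ``R``."""
    R = np.asarray(R, dtype=float)
    b = p.bistable
    out = (-b.V_f * b.K_m1 / (b.K_m1 + (1.0 - R)) ** 2
           + (b.p + b.q * np.asarray(I, dtype=float)) * b.k_fb * (1.0 - 2.0 * R)
           - b.V_r * b.K_m2 / (b.K_m2 + R) ** 2)
    return out if out.ndim else float(out)


def monostable_steady_state(I: float, p: SignallingParameters) -> SwitchState:
    """Unique steady state of the monostable cascade at constant input.

    ``R* = I^n/(k_h^n + I^n)`` and ``R1* = R*/(R* + k_r/k_f)``.
    """
    m = p.monostable
    e = p.effector
    R = float(_hill(I, m.k_h, m.n))
    R1 = R / (R + e.k_r / e.k_f) if R > 0.0 else 0.0
    return SwitchState(R=R, R1=R1)


def monostable_transient(
    I_path: Callable[[float], float],
    t: float,
    p: SignallingParameters,
    R0: float = 0.0,
    breakpoints: Sequence[float] | None = None,
) -> float:
    """Closed-form response of the monostable switch to a time-varying input.

    ``R(t) = R0*exp(-k t) + int_0^t k*H(I(w)) * exp(-k (t-w)) dw`` with
    ``H`` the Hill function; the exponential is kept in the shifted form
    ``exp(-k(t-w))`` so the quadrature never overflows.  ``breakpoints``
    (e.g. pulse edges) are forwarded to the quadrature to keep piecewise
    inputs accurate.
    """
    k = p.monostable.k
    m = p.monostable
    if t == 0.0:
        return float(R0)

    def integrand(w: float) -> float:
        return k * float(_hill(I_path(w), m.k_h, m.n)) * np.exp(-k * (t - w))

    points = [b for b in (breakpoints or ()) if 0.0 < b < t] or None
    val, _ = quad(integrand, 0.0, t, points=points, limit=200,
                  epsabs=1e-12, epsrel=1e-10)
    return float(R0 * np.exp(-k * t) + val)


def _classify(slope: float) -> Literal["stable", "unstable", "degenerate"]:
    if abs(slope) < _DEGENERATE_SLOPE:
        return "degenerate"
    return "stable" if slope < 0.0 else "unstable"


def bistable_steady_states(
    I: float,
    p: SignallingParameters,
    n_grid: int = 4001,
) -> list[SteadyStateBranch]:
    """All steady states of the bistable module in [0, 1] at input ``I``.

    Roots are bracketed by sign changes of the rate on a fixed fine grid and
    polished with Brent's method; the fine grid guards against the thin
    boundary layer near ``R ~ K_m2``.  Branches are sorted ascending in R and
    labelled by the sign of d(rate)/dR.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    f = np.asarray(bistable_rate(grid, I, p))
    roots: list[float] = []
    for j in range(n_grid - 1):
        a, b = f[j], f[j + 1]
        if a == 0.0:
            roots.append(float(grid[j]))
        elif a * b < 0.0:
            roots.append(brentq(lambda R: bistable_rate(R, I, p),
                                grid[j], grid[j + 1], xtol=1e-14, rtol=8.9e-16))
    if f[-1] == 0.0:
        roots.append(1.0)
    # merge near-duplicates from exact-zero grid hits
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-10:
            merged.append(r)
    return [
        SteadyStateBranch(I=float(I), R_star=r,
                          stability=_classify(float(bistable_rate_dR(r, I, p))))
        for r in merged
    ]


def bistable_fold_inputs(
    p: SignallingParameters,
    I_max: float = 5.0,
    n_scan: int = 501,
    xtol: float = 1e-9,
) -> FoldReport:
    """Locate the saddle-node inputs of the bistable module by bisection.

    Scans the steady-state branch count over ``I`` in [0, I_max] and bisects
    each interval where the count changes.  Each fold is reported as the
    midpoint of the final bracket (width ``xtol``).
    """
    I_grid = np.linspace(0.0, I_max, n_scan)
    counts = [len(bistable_steady_states(I, p)) for I in I_grid]
    folds: list[tuple[float, int, int]] = []
    for j in range(len(I_grid) - 1):
        if counts[j] == counts[j + 1]:
            continue
        lo, hi = float(I_grid[j]), float(I_grid[j + 1])
        c_lo, c_hi = counts[j], counts[j + 1]
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if len(bistable_steady_states(mid, p)) == c_lo:
                lo = mid
            else:
                hi = mid
        folds.append((0.5 * (lo + hi), c_lo, c_hi))
    return FoldReport(folds=tuple(folds), I_max=I_max)


def bistable_basal_state(p: SignallingParameters, I_basal: float = 0.0) -> SwitchState:
    """Lower stable steady state of the bistable cascade at basal input."""
    branches = [b for b in bistable_steady_states(I_basal, p) if b.stability == "stable"]
    if not branches:
        raise RuntimeError("bistable module has no stable steady state at basal input")
    R = branches[0].R_star
    e = p.effector
    R1 = R / (R + e.k_r / e.k_f) if R > 0.0 else 0.0
    return SwitchState(R=R, R1=R1)


def basal_switch_state(module: SwitchModule, p: SignallingParameters) -> SwitchState:
    """Pre-treatment (I = 0) state of the chosen module, used as initial data."""
    if module == "monostable":
        return monostable_steady_state(0.0, p)
    if module == "bistable":
        return bistable_basal_state(p)
    raise ValueError(f"unknown signalling module {module!r}")


def apoptosis_trigger(
    R1: float,
    status: TriggerStatus,
    p: SignallingParameters,
    t: float | None = None,
) -> TriggerStatus:
    """Advance the apoptosis trigger given the current effector level.

    In ``monostable_latch`` mode a crossing of ``R1_th`` is permanent; in
    ``bistable_reversible`` mode the trigger simply tracks ``R1 >= R1_th``.
    """
    th = p.effector.R1_th
    above = R1 >= th
    if status.mode == "monostable_latch":
        if status.fired:
            return status
        if above:
            return replace(status, fired=True, time_fired=t)
        return status
    if status.mode == "bistable_reversible":
        if above and not status.fired:
            return replace(status, fired=True, time_fired=t)
        if not above and status.fired:
            return replace(status, fired=False, time_fired=None)
        return status
    raise ValueError(f"unknown trigger mode {status.mode!r}")


def _switch_rhs(module: SwitchModule, p: SignallingParameters):
    if module == "monostable":
        def rhs(t, y, I_fn):
            R, R1 = y
            return [float(monostable_rate(R, I_fn(t), p)),
                    p.effector.k_f * R * (1.0 - R1) - p.effector.k_r * R1]
    elif module == "bistable":
        def rhs(t, y, I_fn):
            R, R1 = y
            return [float(bistable_rate(R, I_fn(t), p)),
                    p.effector.k_f * R * (1.0 - R1) - p.effector.k_r * R1]
    else:
        raise ValueError(f"unknown signalling module {module!r}")
    return rhs


def integrate_switch(
    module: SwitchModule,
    I_fn: Callable[[float], float],
    t_end: float,
    p: SignallingParameters,
    y0: SwitchState | None = None,
    t_eval: Sequence[float] | None = None,
    breakpoints: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the (R, R1) cascade under a prescribed input, time in hours.

    The integration restarts at each breakpoint so pulse edges are not
    smoothed over.  Returns ``(t, R, R1)`` arrays.
    """
    y0 = y0 or basal_switch_state(module, p)
    rhs = _switch_rhs(module, p)
    edges = sorted({0.0, float(t_end), *(b for b in (breakpoints or ())
                                         if 0.0 < b < t_end)})
    want = np.asarray(t_eval if t_eval is not None
                      else np.linspace(0.0, t_end, 401), dtype=float)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = np.array([y0.R, y0.R1])
    for a, b in zip(edges[:-1], edges[1:]):
        seg_eval = np.unique(np.append(want[(want >= a) & (want <= b)], b))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", args=(I_fn,),
                        t_eval=seg_eval, rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"switch integration failed: {sol.message}")
        y = sol.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y)
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    # drop duplicated segment-edge samples
    if t.size:
        keep = np.concatenate([[True], np.diff(t) > 0])
        t, Y = t[keep], Y[:, keep]
    return t, Y[0], Y[1]


def time_to_kill(
    module: SwitchModule,
    I_const: float,
    p: SignallingParameters,
    t_max: float = 200.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> float:
    """Hours for ``R1`` to first reach ``R1_th`` under a constant input.

    Starts from the module's basal state; returns ``inf`` if the threshold is
    never reached before ``t_max``.
    """
    y0 = basal_switch_state(module, p)
    rhs = _switch_rhs(module, p)
    th = p.effector.R1_th

    def crossed(t, y, I_fn):
        return y[1] - th
    crossed.terminal = True
    crossed.direction = 1.0

    sol = solve_ivp(rhs, (0.0, t_max), [y0.R, y0.R1], method="LSODA",
                    args=(lambda t: I_const,), events=crossed,
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"switch integration failed: {sol.message}")
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return float("inf")


@dataclass(frozen=True)
class CalibrationReport:
    """How closely the two switch modules are matched.

    ``threshold_*``: input level at which a sustained signal eventually kills
    (monostable: steady ``R1`` crosses ``R1_th``; bistable: upper fold).
    ``time_*``: hours for ``R1`` to reach the threshold under the common
    reference input.  Ratios are monostable/bistable.
    """

    threshold_monostable: float
    threshold_bistable: float | None
    threshold_ratio: float | None
    reference_input: float
    time_monostable: float
    time_bistable: float
    time_ratio: float
    tolerance: float

    @property
    def matched(self) -> bool:
        if self.threshold_ratio is None:
            return False
        return (abs(self.threshold_ratio - 1.0) <= self.tolerance
                and abs(self.time_ratio - 1.0) <= self.tolerance)


def monostable_switching_threshold(p: SignallingParameters) -> float:
    """Input above which the monostable steady state fires the trigger.

    Inverts ``R1* = R*/(R* + k_r/k_f)`` and the Hill curve at ``R1* = R1_th``.
    """
    e = p.effector
    m = p.monostable
    R_needed = e.R1_th * (e.k_r / e.k_f) / (1.0 - e.R1_th)
    if R_needed >= 1.0:
        return float("inf")
    return m.k_h * (R_needed / (1.0 - R_needed)) ** (1.0 / m.n)


def calibrate_module_match(
    p: SignallingParameters,
    reference_input: float = 2.0,
    tolerance: float = 0.25,
) -> CalibrationReport:
    """Check that the two modules share a switching threshold and time scale.

    The modules are deliberately parameterized so that (a) the input threshold
    for eventual killing is the same and (b) the time for ``R1`` to reach
    ``R1_th`` under a common reference input (default: twice the threshold)
    is comparable.  Mismatch beyond ``tolerance`` (relative) is flagged via
    ``matched``.
    """
    th_mono = monostable_switching_threshold(p)
    fold = bistable_fold_inputs(p)
    th_bi = fold.upper
    ratio = th_mono / th_bi if th_bi else None
    t_mono = time_to_kill("monostable", reference_input, p)
    t_bi = time_to_kill("bistable", reference_input, p)
    return CalibrationReport(
        threshold_monostable=th_mono,
        threshold_bistable=th_bi,
        threshold_ratio=ratio,
        reference_input=reference_input,
        time_monostable=t_mono,
        time_bistable=t_bi,
        time_ratio=t_mono / t_bi if t_bi > 0 else float("inf"),
        tolerance=tolerance,
    )
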