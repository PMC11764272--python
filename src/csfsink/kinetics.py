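"""Soluble CSF amyloid-beta kinetics under anti-amyloid antibody therapy.

The soluble pool is a single well-mixed compartment with zero-order
production P (pg/mL/month) and first-order clearance k (1/month):

    dA/dt = P - k(t) * A,    A(t) = (A_i - P/k) exp(-k t_rel) + P/k

Continuous intrathecal pseudodelivery adds a clearance term
(k = c_nat + c_it while on therapy); intravenous dosing instead applies
an instantaneous fractional reduction (1 - e_dose) at each dose instant,
with natural kinetics (k = c_nat) in between. After discontinuation the
intrathecal effect washes out as c_it * exp(-w (t - t_stop)); IV dosing
simply ceases.

Simulation is piecewise closed-form between events. The only segment
without an elementary solution is the intrathecal washout (time-varying
clearance), which is evaluated exactly up to quadrature through the
integrating factor; :func:`ode_reference_solve` provides an independent
adaptive-step numerical oracle for all regimes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp
from scipy.optimize import brentq

from .params import IMMEDIATE, KineticParams, TherapySchedule
from .trajectories import SolubleTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "soluble_closed_form",
    "apply_dose",
    "steady_state_soluble",
    "simulate_soluble",
    "ode_reference_solve",
    "percent_reduction",
    "reaccumulation_time",
]


@dataclass(frozen=True)
class GridSpec:
    """Output grid: simulate on [0, t_end] with nominal step dt (months)."""

    t_end: float = 220.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be positive")

    def times(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.linspace(0.0, self.t_end, n + 1)


def soluble_closed_form(
    t_rel: float,
    a_init: float,
    params: KineticParams,
    therapy_on: bool = False,
):
    """Closed-form soluble concentration ``t_rel`` months after ``a_init``.

    Uses total clearance k = c_nat + c_it when ``therapy_on`` (continuous
    intrathecal regime) and k = c_nat otherwise; the latter is also the
    inter-dose segment of the IV regime.

    Accepts scalar or array ``t_rel``; exact at machine precision.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    if np.any(t_rel < 0):
        raise ValueError("t_rel must be >= 0")
    if a_init < 0:
        raise ValueError("a_init must be >= 0")
    k = params.c_nat + (params.c_it if therapy_on else 0.0)
    s = params.p_prod / k
    out = s + (a_init - s) * np.exp(-k * t_rel)
    return float(out) if out.ndim == 0 else out


def apply_dose(a_pre: float, e_dose: float) -> float:
    """Concentration immediately after an IV dose: (1 - e_dose) * a_pre."""
    if a_pre < 0:
        raise ValueError("a_pre must be >= 0")
    if not (0.0 <= e_dose < 1.0):
        raise ValueError("e_dose must be in [0, 1)")
    return (1.0 - e_dose) * a_pre


def steady_state_soluble(params: KineticParams, mode: str = "untreated") -> float:
    """Long-run soluble level for a maintained regime.

    ``untreated`` and ``intrathecal`` are the ODE equilibria P/k. For
    periodic IV dosing the pre-dose (trough) limit is the fixed point of
    the one-cycle decay-then-dose map,

        A_trough = P (1 - exp(-C tau)) / (C (1 - (1-E) exp(-C tau))),

    and the post-dose (peak) limit is (1 - E) * A_trough.
    """
    p, c = params.p_prod, params.c_nat
    if mode == "untreated":
        return p / c
    if mode == "intrathecal":
        return p / (c + params.c_it)
    if mode in ("iv_trough", "iv_peak"):
        decay = math.exp(-c * params.tau_dose)
        trough = p * (1.0 - decay) / (c * (1.0 - (1.0 - params.e_dose) * decay))
        return trough if mode == "iv_trough" else (1.0 - params.e_dose) * trough
    raise ValueError(f"unknown mode {mode!r}")


def _washout_profile(
    t_rel: np.ndarray, a_start: float, params: KineticParams, w: float
) -> np.ndarray:
    """Soluble concentration during intrathecal washout.

    Solves dA/dt = P - (C + c_it e^{-w t}) A exactly via the integrating
    factor exp(K), K(t) = C t + (c_it/w)(1 - e^{-w t}); the production
    integral is evaluated by trapezoid quadrature on a fine subgrid.
    """
    t_end = float(t_rel[-1])
    if t_end == 0.0:
        return np.full_like(t_rel, a_start)
    fine = np.union1d(np.linspace(0.0, t_end, max(2, int(t_end / 0.002) + 1)), t_rel)
    bigk = params.c_nat * fine + (params.c_it / w) * (1.0 - np.exp(-w * fine))
    # factor out exp(bigk[-1]) to keep the quadrature well-scaled
    integ = cumulative_simpson(np.exp(bigk - bigk[-1]), x=fine, initial=0.0)
    a_fine = np.exp(-bigk) * a_start + params.p_prod * np.exp(bigk[-1] - bigk) * integ
    return np.interp(t_rel, fine, a_fine)


def _segment_regime(t0: float, schedule: TherapySchedule, t_start: Optional[float],
                    t_stop: Optional[float]) -> str:
    """Regime governing the segment starting at t0: off / it_on / washout."""
    # 1e-9 tolerance: breakpoints are rounded to 9 decimals when merged
    if schedule.arm != "intrathecal" or t_start is None or t0 < t_start - 1e-9:
        return "off"
    if t_stop is not None and t0 >= t_stop - 1e-9:
        return "immediate_off" if schedule.immediate_washout else "washout"
    return "it_on"


def simulate_soluble(
    schedule: TherapySchedule,
    params: KineticParams,
    grid: Union[GridSpec, dict, None] = None,
) -> SolubleTrajectory:
    """Simulate the soluble pool on [0, t_end] under a therapy schedule.

    Piecewise closed-form evaluation between events (therapy start, each
    IV dose, discontinuation); at each dose instant both the pre- and
    post-dose values are recorded at the same time stamp.
    """
    if grid is None:
        grid = GridSpec()
    elif isinstance(grid, dict):
        grid = GridSpec(**grid)
    t_end = grid.t_end
    base = grid.times()

    # --- validate / filter events -------------------------------------
    t_start: Optional[float] = schedule.t_start
    if schedule.arm == "untreated":
        t_start = None
    elif not (0.0 <= schedule.t_start <= t_end):
        logger.warning(
            "therapy start %.3f outside [0, %.3f]; arm simulated untreated",
            schedule.t_start, t_end,
        )
        t_start = None
    t_stop: Optional[float] = schedule.t_stop
    if t_stop is not None and (t_stop > t_end or t_start is None):
        if t_start is not None:
            logger.warning("t_stop %.3f beyond horizon %.3f; ignored", t_stop, t_end)
        t_stop = None

    doses = np.array(schedule.dose_times(params, t_end) if t_start is not None else [])
    if len(np.unique(np.round(doses, 9))) != len(doses):
        raise ValueError("duplicate IV dose times in schedule")

    # --- breakpoints and merged grid ----------------------------------
    events: dict = {}
    if t_start is not None and schedule.arm == "intrathecal":
        events[round(t_start, 9)] = "start"
    for d in doses:
        events[round(float(d), 9)] = "dose"
    if t_stop is not None:
        events[round(t_stop, 9)] = "stop" if events.get(round(t_stop, 9)) != "dose" else "dose"

    bps = sorted(set([0.0, t_end]) | set(events))
    all_t = np.unique(np.concatenate([base, np.array(bps)]))

    out_t: list = []
    out_c: list = []
    out_e: list = []
    a_cur = params.a0
    pending_label = ""
    for j in range(len(bps) - 1):
        t0, t1 = bps[j], bps[j + 1]
        mask = (all_t >= t0 - 1e-12) & (all_t < t1 - 1e-12)
        pts = all_t[mask]
        regime = _segment_regime(t0, schedule, t_start, t_stop)
        rel = np.append(pts, t1) - t0
        if regime == "washout":
            vals = _washout_profile(rel, a_cur, params, float(schedule.washout_rate))
        else:
            vals = soluble_closed_form(rel, a_cur, params, therapy_on=(regime == "it_on"))
        labels = [pending_label] + [""] * (len(pts) - 1)
        out_t.append(pts)
        out_c.append(vals[:-1])
        out_e.extend(labels)
        a_end = float(vals[-1])
        kind = events.get(round(t1, 9))
        if kind == "dose":
            out_t.append([t1])
            out_c.append([a_end])
            out_e.append("dose_pre")
            a_cur = apply_dose(a_end, params.e_dose)
            pending_label = "dose_post"
        else:
            a_cur = a_end
            pending_label = {"start": "start", "stop": "stop"}.get(kind, "")
    out_t.append([t_end])
    out_c.append([a_cur])
    out_e.append(pending_label if pending_label not in ("",) else "")

    times = np.concatenate([np.asarray(x, dtype=float) for x in out_t])
    conc = np.concatenate([np.asarray(x, dtype=float) for x in out_c])
    return SolubleTrajectory(times, np.maximum(conc, 0.0), doses, out_e)


def ode_reference_solve(
    schedule: TherapySchedule,
    params: KineticParams,
    grid: Union[GridSpec, dict, None] = None,
    tol: float = 1e-10,
) -> SolubleTrajectory:
    """Independent numerical oracle for :func:`simulate_soluble`.

    Integrates dA/dt = P - k(t) A with an adaptive Runge-Kutta scheme
    (applying instantaneous dose multiplications between integration
    legs) and samples the dense output on the same grid. Agreement
    contract with the closed-form path: max relative deviation
    <= max(10 * tol, 1e-6).
    """
    if grid is None:
        grid = GridSpec()
    elif isinstance(grid, dict):
        grid = GridSpec(**grid)
    t_end = grid.t_end

    t_start = schedule.t_start if schedule.arm != "untreated" else None
    if t_start is not None and not (0.0 <= t_start <= t_end):
        t_start = None
    t_stop = schedule.t_stop
    if t_stop is not None and (t_stop > t_end or t_start is None):
        t_stop = None

    def k_of_t(t: float) -> float:
        if schedule.arm != "intrathecal" or t_start is None or t < t_start:
            return params.c_nat
        if t_stop is not None and t >= t_stop:
            if schedule.immediate_washout:
                return params.c_nat
            w = float(schedule.washout_rate)
            return params.c_nat + params.c_it * math.exp(-w * (t - t_stop))
        return params.c_nat + params.c_it

    def rhs(t, a):
        return params.p_prod - k_of_t(t) * a

    doses = schedule.dose_times(params, t_end) if t_start is not None else []
    legs = sorted(set([0.0, t_end] + ([t_start] if t_start is not None else [])
                      + ([t_stop] if t_stop is not None else []) + list(doses)))
    base = grid.times()
    out_t, out_c, out_e = [], [], []
    a_cur = params.a0
    for j in range(len(legs) - 1):
        t0, t1 = legs[j], legs[j + 1]
        pts = base[(base >= t0 - 1e-12) & (base < t1 - 1e-12)]
        pts = np.unique(np.concatenate([[t0], pts]))
        sol = solve_ivp(rhs, (t0, t1), [a_cur], method="RK45", rtol=tol,
                        atol=tol * max(1.0, params.a0, params.p_prod / params.c_nat),
                        dense_output=True, max_step=1.0)
        if not sol.success:  # pragma: no cover - integrator diagnostics
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        out_t.append(pts)
        out_c.append(sol.sol(pts)[0])
        out_e.extend([""] * len(pts))
        a_end = float(sol.sol(t1)[0])
        if t1 in doses:
            out_t.append([t1])
            out_c.append([a_end])
            out_e.append("dose_pre")
            a_cur = apply_dose(a_end, params.e_dose)
        else:
            a_cur = a_end
    out_t.append([t_end])
    out_c.append([a_cur])
    out_e.append("")
    times = np.concatenate([np.asarray(x, dtype=float) for x in out_t])
    conc = np.concatenate([np.asarray(x, dtype=float) for x in out_c])
    return SolubleTrajectory(times, np.maximum(conc, 0.0), np.asarray(doses), out_e)


def percent_reduction(
    traj: SolubleTrajectory,
    baseline: float,
    t_eval: float,
    convention: str = "instant",
) -> float:
    """Fractional reduction 1 - A(t_eval)/baseline.

    Under the ``pre_dose`` convention the trough value is used when
    ``t_eval`` lands on an IV dose instant. May be negative if the
    concentration rose above baseline.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 1.0 - traj.value_at(t_eval, convention=convention) / baseline


def reaccumulation_time(
    params: KineticParams,
    a_start: float,
    target_fraction: float,
    washout: Union[float, str] = IMMEDIATE,
    horizon: float = 600.0,
) -> Optional[float]:
    """Months after discontinuation until A reaches a fraction of P/C.

    With immediate washout the crossing time is the closed-form
    inversion of the natural-recovery exponential; with a finite washout
    rate the residual intrathecal clearance delays recovery and the
    crossing is found by root-finding. Returns 0 if already at or above
    target, None if the target is not reached within ``horizon``.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    s = params.p_prod / params.c_nat
    target = target_fraction * s
    if a_start >= target:
        return 0.0
    if washout == IMMEDIATE:
        t = math.log((s - a_start) / (s - target)) / params.c_nat
        return t if t <= horizon else None
    w = float(washout)
    grid = np.linspace(0.0, horizon, int(horizon / 0.01) + 1)
    vals = _washout_profile(grid, a_start, params, w)
    above = np.nonzero(vals >= target)[0]
    if len(above) == 0:
        return None
    i = above[0]
    if i == 0:
        return 0.0
    f = lambda t: _washout_profile(np.array([0.0, t]), a_start, params, w)[-1] - target
    return float(brentq(f, grid[i - 1], grid[i], xtol=1e-8))
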