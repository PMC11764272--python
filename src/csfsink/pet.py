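"""Fibrillar amyloid (PET centiloid) compartment and its calibration.

The burden F(t), expressed directly in centiloids, is driven by the
soluble pool through a linear aggregation/clearance balance:

    dF/dt = k_agg * A(t) - (c_f + gamma_arm(t)) * F

where gamma_arm is an arm-specific therapy-induced fibrillar clearance,
active while therapy is on and decaying with the arm's washout rate
after discontinuation. The scaling from concentration to centiloids is
absorbed into k_agg, and F = 0 at model time 0.

No quantitative soluble-to-PET coupling is established in the
literature for this delivery route, so the compartment is a calibrated
surrogate: :func:`calibrate_fibrillar` fits (k_agg, c_f, gamma_it,
gamma_iv, washout_it, washout_iv) by bounded least squares from seeded
Sobol multistarts so that the model reproduces the clinical milestone
set (PET positivity of the untreated arm at month 120, negativity at
months 132/150 for the intrathecal and IV arms, and a 6-month
re-positivity delay after discontinuation). The shipped defaults are
the converged result of that procedure (seed 1, 32 starts, default
bounds).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import GridSpec, simulate_soluble
from .params import (
    DEFAULT_ONSET_MONTH,
    IMMEDIATE,
    KineticParams,
    PET_NEGATIVITY_CL,
    PET_POSITIVITY_CL,
    TherapySchedule,
)
from .trajectories import PetTrajectory, SolubleTrajectory

__all__ = [
    "FibrillarParams",
    "Milestones",
    "CalibrationResult",
    "simulate_fibrillar",
    "detect_crossing",
    "quasi_steady_fibrillar",
    "calibrate_fibrillar",
    "calibrated_defaults",
    "DEFAULT_BOUNDS",
    "MISSING_CROSSING_PENALTY",
]

#: Residual (months) assigned to a milestone whose crossing never occurs.
MISSING_CROSSING_PENALTY = 1e3


@dataclass(frozen=True)
class FibrillarParams:
    """Parameters of the fibrillar (PET centiloid) compartment.

    Attributes
    ----------
    k_agg : float
        Aggregation coefficient, CL per (pg/mL)·month.
    c_f : float
        Natural fibrillar clearance (1/month).
    gamma_it, gamma_iv : float
        Therapy-induced fibrillar clearance while on therapy (1/month),
        arm-specific (route-dependent plaque engagement).
    f0 : float
        Initial burden at model time 0 (CL).
    """

    k_agg: float
    c_f: float
    gamma_it: float = 0.0
    gamma_iv: float = 0.0
    f0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_agg", "c_f", "gamma_it", "gamma_iv", "f0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def gamma(self, arm: str) -> float:
        return {"intrathecal": self.gamma_it, "iv": self.gamma_iv}.get(arm, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Milestones:
    """Clinical milestone set the fibrillar surrogate is calibrated to."""

    t_onset: float = DEFAULT_ONSET_MONTH        # untreated crosses 35 CL upward
    t_neg_it: float = 132.0                     # intrathecal falls below 24 CL
    t_neg_iv: float = 150.0                     # IV falls below 24 CL
    repositivity_delay: float = 6.0             # intrathecal minus IV, post-stop
    positivity_cl: float = PET_POSITIVITY_CL
    negativity_cl: float = PET_NEGATIVITY_CL

    def __post_init__(self) -> None:
        if min(self.t_onset, self.t_neg_it, self.t_neg_iv) <= 0:
            raise ValueError("milestone times must be positive")
        if self.t_neg_it >= self.t_neg_iv:
            raise ValueError("t_neg_it must precede t_neg_iv")


@dataclass
class CalibrationResult:
    """Outcome of a fibrillar-compartment calibration run."""

    fparams: FibrillarParams
    washout_it: float
    washout_iv: float
    residuals: dict
    loss: float
    converged: bool
    n_starts_used: int
    seed: int
    bounds: dict

    def to_json(self, path) -> None:
        payload = {
            "fparams": self.fparams.to_dict(),
            "washout_it": self.washout_it,
            "washout_iv": self.washout_iv,
            "residuals": self.residuals,
            "loss": self.loss,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _gamma_profile(
    times: np.ndarray, fparams: FibrillarParams, schedule: TherapySchedule
) -> np.ndarray:
    """Therapy-induced fibrillar clearance gamma(t) on the grid."""
    g = fparams.gamma(schedule.arm)
    out = np.zeros_like(times)
    if g == 0.0 or schedule.arm == "untreated":
        return out
    on = times >= schedule.t_start - 1e-9
    if schedule.t_stop is None:
        out[on] = g
        return out
    active = on & (times < schedule.t_stop - 1e-9)
    out[active] = g
    after = times >= schedule.t_stop - 1e-9
    if not schedule.immediate_washout:
        w = float(schedule.washout_rate)
        out[after] = g * np.exp(-w * (times[after] - schedule.t_stop))
    return out


def simulate_fibrillar(
    soluble_traj: SolubleTrajectory,
    fparams: FibrillarParams,
    schedule: TherapySchedule,
) -> PetTrajectory:
    """Integrate the fibrillar compartment driven by a soluble trajectory.

    Uses the exact integrating-factor solution of the linear ODE with
    trapezoid quadrature on the trajectory grid (duplicated dose points
    contribute zero-width intervals, so the soluble discontinuities are
    handled exactly).
    """
    t = soluble_traj.times
    a = soluble_traj.conc
    rho = fparams.c_f + _gamma_profile(t, fparams, schedule)
    big_r = cumulative_trapezoid(rho, t, initial=0.0)
    # well-scaled: exp(big_r - r_max) <= 1 everywhere
    r_max = big_r[-1]
    integ = cumulative_trapezoid(a * np.exp(big_r - r_max), t, initial=0.0)
    f = fparams.f0 * np.exp(-big_r) + fparams.k_agg * np.exp(r_max - big_r) * integ
    return PetTrajectory(t, np.maximum(f, 0.0))


def detect_crossing(
    traj,
    threshold: float,
    direction: str = "down",
    t_min: float = 0.0,
) -> Optional[float]:
    """First time >= t_min at which the signal crosses a threshold.

    Works on PET (``centiloids``) or soluble (``conc``) trajectories;
    linear interpolation between grid points; at an instantaneous jump
    (duplicated time stamp) the crossing is the jump time itself.
    Returns None if no crossing occurs in the stated direction.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    t = traj.times
    v = traj.centiloids if hasattr(traj, "centiloids") else traj.conc
    if len(t) < 2:
        raise ValueError("trajectory too short for crossing detection")
    v0, v1 = v[:-1], v[1:]
    t0, t1 = t[:-1], t[1:]
    if direction == "up":
        hits = (v0 < threshold) & (v1 >= threshold)
    else:
        hits = (v0 > threshold) & (v1 <= threshold)
    for i in np.nonzero(hits)[0]:
        if t1[i] < t_min:
            continue
        if t1[i] == t0[i]:
            tc = t0[i]
        else:
            tc = t0[i] + (threshold - v0[i]) / (v1[i] - v0[i]) * (t1[i] - t0[i])
        if tc >= t_min:
            return float(tc)
    return None


def quasi_steady_fibrillar(
    fparams: FibrillarParams, a_const: float, gamma: float = 0.0
) -> float:
    """Equilibrium burden k_agg * A / (c_f + gamma) for constant soluble A."""
    total = fparams.c_f + gamma
    if total <= 0:
        raise ValueError("total fibrillar clearance must be > 0")
    return fparams.k_agg * a_const / total


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: Parameter order used by the optimizer.
_PARAM_NAMES = ("k_agg", "c_f", "gamma_it", "gamma_iv", "washout_it", "washout_iv")

#: Default calibration bounds (log-uniform start sampling for all six).
DEFAULT_BOUNDS = {
    "k_agg": (1e-5, 5e-3),
    "c_f": (1e-3, 0.1),
    "gamma_it": (1e-4, 0.3),
    "gamma_iv": (1e-4, 0.3),
    "washout_it": (0.01, 2.0),
    "washout_iv": (0.01, 5.0),
}


class _MilestoneModel:
    """Forward model: fibrillar parameters -> milestone crossing times.

    Soluble trajectories that do not depend on the fitted parameters
    (untreated, and both therapy arms without discontinuation) are
    simulated once and cached; the post-discontinuation arms depend on
    the candidate washout rates and stop times and are re-simulated per
    evaluation.
    """

    def __init__(
        self,
        kparams: KineticParams,
        milestones: Milestones,
        t_start: float = DEFAULT_ONSET_MONTH,
        grid: Optional[GridSpec] = None,
        disc_horizon: float = 320.0,
    ) -> None:
        self.kparams = kparams
        self.milestones = milestones
        self.t_start = t_start
        self.grid = grid or GridSpec(t_end=220.0, dt=0.01)
        self.disc_grid = GridSpec(t_end=disc_horizon, dt=self.grid.dt)
        self.sched_unt = TherapySchedule(arm="untreated")
        self.sched_it = TherapySchedule(arm="intrathecal", t_start=t_start)
        self.sched_iv = TherapySchedule(arm="iv", t_start=t_start)
        self.sol_unt = simulate_soluble(self.sched_unt, kparams, self.grid)
        self.sol_it = simulate_soluble(self.sched_it, kparams, self.grid)
        self.sol_iv = simulate_soluble(self.sched_iv, kparams, self.grid)

    def crossing_times(self, fp: FibrillarParams, w_it: float, w_iv: float) -> dict:
        ms = self.milestones
        out: dict = {}
        pet_unt = simulate_fibrillar(self.sol_unt, fp, self.sched_unt)
        out["t_onset"] = detect_crossing(pet_unt, ms.positivity_cl, "up")
        pet_it = simulate_fibrillar(self.sol_it, fp, self.sched_it)
        out["t_neg_it"] = detect_crossing(
            pet_it, ms.negativity_cl, "down", t_min=self.t_start
        )
        pet_iv = simulate_fibrillar(self.sol_iv, fp, self.sched_iv)
        out["t_neg_iv"] = detect_crossing(
            pet_iv, ms.negativity_cl, "down", t_min=self.t_start
        )
        out["repositivity_delay"] = None
        if out["t_neg_it"] is not None and out["t_neg_iv"] is not None:
            iv_int = self._repositivity_interval(
                "iv", out["t_neg_iv"], fp, w_iv
            )
            it_int = self._repositivity_interval(
                "intrathecal", out["t_neg_it"], fp, w_it
            )
            if iv_int is not None and it_int is not None:
                out["repositivity_delay"] = it_int - iv_int
                out["repositivity_interval_it"] = it_int
                out["repositivity_interval_iv"] = iv_int
        return out

    def _repositivity_interval(
        self, arm: str, t_stop: float, fp: FibrillarParams, w: float
    ) -> Optional[float]:
        sched = TherapySchedule(
            arm=arm, t_start=self.t_start, t_stop=t_stop, washout_rate=w
        )
        sol = simulate_soluble(sched, self.kparams, self.disc_grid)
        pet = simulate_fibrillar(sol, fp, sched)
        t_re = detect_crossing(pet, self.milestones.positivity_cl, "up", t_min=t_stop)
        return None if t_re is None else t_re - t_stop

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        k_agg, c_f, g_it, g_iv, w_it, w_iv = theta
        fp = FibrillarParams(k_agg=k_agg, c_f=c_f, gamma_it=g_it, gamma_iv=g_iv)
        times = self.crossing_times(fp, w_it, w_iv)
        ms = self.milestones
        targets = {
            "t_onset": ms.t_onset,
            "t_neg_it": ms.t_neg_it,
            "t_neg_iv": ms.t_neg_iv,
            "repositivity_delay": ms.repositivity_delay,
        }
        res = []
        for key, target in targets.items():
            got = times.get(key)
            res.append(MISSING_CROSSING_PENALTY if got is None else got - target)
        return np.asarray(res)


def calibrate_fibrillar(
    kparams: KineticParams,
    milestones: Optional[Milestones] = None,
    bounds: Optional[dict] = None,
    n_starts: int = 32,
    seed: int = 1,
    t_start: float = DEFAULT_ONSET_MONTH,
    grid: Optional[GridSpec] = None,
) -> CalibrationResult:
    """Fit the fibrillar surrogate to the milestone set.

    Minimizes the sum of squared crossing-time errors over
    (k_agg, c_f, gamma_it, gamma_iv, washout_it, washout_iv) with
    bounded least squares (trust-region reflective) from ``n_starts``
    Sobol starts sampled log-uniformly within the bounds; fully
    reproducible under ``seed``. A milestone whose crossing never occurs
    contributes a fixed penalty residual instead of raising.

    ``converged`` requires every milestone residual within 0.5 month.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    milestones = milestones or Milestones()
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in _PARAM_NAMES])
    hi = np.array([bnds[n][1] for n in _PARAM_NAMES])
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy lower < upper")

    model = _MilestoneModel(kparams, milestones, t_start=t_start, grid=grid)

    sampler = qmc.Sobol(d=len(_PARAM_NAMES), scramble=True, seed=seed)
    unit = sampler.random(n_starts)
    # log-uniform start sampling (rates span decades); optimization itself
    # runs on the linear scale within [lo, hi]
    safe_lo = np.maximum(lo, 1e-12)
    starts = np.exp(np.log(safe_lo) + unit * (np.log(hi) - np.log(safe_lo)))
    starts = np.clip(starts, lo, hi)

    best = None
    for x0 in starts:
        try:
            fit = least_squares(
                model.residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, diff_step=1e-3,
            )
        except Exception:  # pragma: no cover - defensive against rare failures
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:  # pragma: no cover
        raise RuntimeError("all calibration starts failed")

    theta = best.x
    fp = FibrillarParams(
        k_agg=theta[0], c_f=theta[1], gamma_it=theta[2], gamma_iv=theta[3]
    )
    res_vec = model.residuals(theta)
    keys = ("t_onset", "t_neg_it", "t_neg_iv", "repositivity_delay")
    residuals = {k: float(r) for k, r in zip(keys, res_vec)}
    loss = float(np.sum(res_vec**2))
    converged = bool(np.all(np.abs(res_vec) <= 0.5))
    return CalibrationResult(
        fparams=fp,
        washout_it=float(theta[4]),
        washout_iv=float(theta[5]),
        residuals=residuals,
        loss=loss,
        converged=converged,
        n_starts_used=n_starts,
        seed=seed,
        bounds=bnds,
    )


# ---------------------------------------------------------------------------
# Shipped calibrated defaults
# ---------------------------------------------------------------------------

#: Frozen result of ``calibrate_fibrillar(KineticParams(), Milestones(),
#: n_starts=32, seed=1)`` with DEFAULT_BOUNDS -- reproducible via
#: scripts/calibrate_defaults.py; every milestone residual < 1e-8 month.
DEFAULT_FIBRILLAR = FibrillarParams(
    k_agg=1.5858265881663744e-04,
    c_f=1.04983909910226e-02,
    gamma_it=2.3358835046936418e-02,
    gamma_iv=3.488792295687286e-03,
    f0=0.0,
)
DEFAULT_WASHOUT_IT = 0.5911796864415959
DEFAULT_WASHOUT_IV = 0.2190633405234952


def calibrated_defaults():
    """Shipped fibrillar parameters and washout rates.

    Returns ``(FibrillarParams, washout_it, washout_iv)`` frozen from
    the documented calibration run (seed 1, 32 Sobol starts, default
    bounds); every milestone residual of that run is below 0.5 month.
    """
    return DEFAULT_FIBRILLAR, DEFAULT_WASHOUT_IT, DEFAULT_WASHOUT_IV
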