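"""Virtual-subject cohorts and noisy observations.

Between-subject variability is lognormal on the positive kinetic
parameters (rates cannot go negative, and skewed variability is the
norm for clearance/production rates), truncated at the 1%/99% quantiles
to avoid pathological draws. The measurement model is multiplicative
lognormal noise for CSF concentrations (assay error scales with level)
and additive zero-mean Gaussian noise for PET centiloids, clipped at
zero with a logged count. Neither the variability magnitudes nor the
noise model are empirical constants; they are package defaults chosen
to be plausible for lumbar-puncture and amyloid-PET measurement and are
fully configurable.

All randomness flows through explicit integer seeds; no global state.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import KineticParams
from .trajectories import SolubleTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "VirtualSubject",
    "ObservationSet",
    "ParamFit",
    "generate_virtual_cohort",
    "sample_observations",
    "recover_params",
]

#: Kinetic fields that vary between subjects.
_VARIED = ("p_prod", "c_nat", "c_it", "e_dose")


@dataclass(frozen=True)
class VirtualSubject:
    subject_id: str
    params: KineticParams
    arm: str = "untreated"


@dataclass
class ObservationSet:
    """Noisy CSF and PET observations of one simulated subject."""

    csf_times: np.ndarray
    csf_values: np.ndarray          # pg/mL
    pet_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pet_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    csf_sigma_log: float = 0.0
    pet_sigma_cl: float = 0.0
    seed: Optional[int] = None

    def to_frame(self, subject_id: str = "s0", arm: str = "untreated") -> pd.DataFrame:
        rows = [
            {"subject_id": subject_id, "arm": arm, "time_month": t,
             "measure": "csf_pg_ml", "value": v}
            for t, v in zip(self.csf_times, self.csf_values)
        ] + [
            {"subject_id": subject_id, "arm": arm, "time_month": t,
             "measure": "pet_cl", "value": v}
            for t, v in zip(self.pet_times, self.pet_values)
        ]
        return pd.DataFrame(rows)


@dataclass
class ParamFit:
    """Least-squares recovery of (a_init, P, k) from CSF observations."""

    a_init: float
    p_prod: float
    k: float
    residual_norm: float
    converged: bool


def generate_virtual_cohort(
    n: int,
    cv: float = 0.2,
    seed: int = 0,
    base: Optional[KineticParams] = None,
    arms: Sequence[str] = ("intrathecal", "iv"),
) -> list:
    """Draw ``n`` virtual subjects around the default kinetic parameters.

    Each varied parameter (P, C, CIT, E) is lognormal with mean equal
    to the base value and coefficient of variation ``cv``, truncated at
    its own [1%, 99%] quantiles; ``cv = 0`` reproduces the base
    parameters exactly. Arms are assigned round-robin. Deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= cv < 1.0):
        raise ValueError("cv must be in [0, 1)")
    base = base or KineticParams()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))  # lognormal sigma giving the stated CV
    subjects = []
    for i in range(n):
        draws = {}
        for name in _VARIED:
            mu = getattr(base, name)
            if cv == 0.0 or mu == 0.0:
                draws[name] = mu
                continue
            z = rng.standard_normal()
            z = float(np.clip(z, -2.3263478740408408, 2.3263478740408408))  # 1%/99%
            # mean-parameterized lognormal: E[mu * exp(sigma z - sigma^2/2)] = mu
            draws[name] = mu * np.exp(sigma * z - 0.5 * sigma**2)
        if draws["e_dose"] >= 1.0:
            draws["e_dose"] = 0.99
        params = base.replace(**draws)
        subjects.append(
            VirtualSubject(
                subject_id=f"s{i:04d}",
                params=params,
                arm=arms[i % len(arms)],
            )
        )
    return subjects


def sample_observations(
    traj: SolubleTrajectory,
    csf_times: Sequence[float],
    pet_traj=None,
    pet_times: Sequence[float] = (),
    csf_sigma_log: float = 0.1,
    pet_sigma_cl: float = 3.0,
    seed: int = 0,
) -> ObservationSet:
    """Sample noisy observations from simulated trajectories.

    CSF: value * exp(sigma_log * z); PET: value + sigma_cl * z, clipped
    at 0 (clip count logged). Zero noise returns exact trajectory
    values. Observation times must lie within the trajectory span.
    """
    csf_times = np.asarray(csf_times, dtype=float)
    pet_times = np.asarray(pet_times, dtype=float)
    lo, hi = traj.t_span
    if len(csf_times) and (csf_times.min() < lo - 1e-9 or csf_times.max() > hi + 1e-9):
        raise ValueError("CSF observation times outside trajectory span")
    rng = np.random.default_rng(seed)
    csf = np.array([traj.value_at(t, convention="pre_dose") for t in csf_times])
    if csf_sigma_log > 0:
        csf = csf * np.exp(csf_sigma_log * rng.standard_normal(len(csf)))
    pet = np.empty(0)
    if pet_traj is not None and len(pet_times):
        p_lo, p_hi = pet_traj.t_span
        if pet_times.min() < p_lo - 1e-9 or pet_times.max() > p_hi + 1e-9:
            raise ValueError("PET observation times outside trajectory span")
        pet = np.array([pet_traj.value_at(t) for t in pet_times])
        if pet_sigma_cl > 0:
            pet = pet + pet_sigma_cl * rng.standard_normal(len(pet))
            n_clip = int(np.sum(pet < 0))
            if n_clip:
                logger.info("clipped %d negative PET observations to 0", n_clip)
            pet = np.maximum(pet, 0.0)
    return ObservationSet(
        csf_times=csf_times, csf_values=csf,
        pet_times=pet_times, pet_values=pet,
        csf_sigma_log=csf_sigma_log, pet_sigma_cl=pet_sigma_cl, seed=seed,
    )


def recover_params(
    obs: ObservationSet,
    init: Optional[KineticParams] = None,
    bounds: Optional[dict] = None,
    therapy_on: bool = True,
) -> ParamFit:
    """Fit the closed-form soluble solution to CSF observations.

    Estimates (a_init, P, k) in A(t) = (a_init - P/k) e^{-k t} + P/k by
    nonlinear least squares on the observed (time, concentration)
    pairs. Times are taken relative to the first observation. Requires
    at least three distinct observation times for identifiability.
    """
    t = np.asarray(obs.csf_times, dtype=float)
    y = np.asarray(obs.csf_values, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct CSF observation times to identify "
                         "(a_init, P, k)")
    t_rel = t - t.min()
    init = init or KineticParams()
    k0 = init.c_nat + (init.c_it if therapy_on else 0.0)
    x0 = np.array([max(y[0], 1e-6), init.p_prod, k0])
    bnds = {"a_init": (1e-9, 1e6), "p_prod": (1e-9, 1e5), "k": (1e-6, 1e2)}
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds["a_init"][0], bnds["p_prod"][0], bnds["k"][0]])
    hi = np.array([bnds["a_init"][1], bnds["p_prod"][1], bnds["k"][1]])

    def model(x):
        a0, p, k = x
        return (a0 - p / k) * np.exp(-k * t_rel) + p / k

    fit = least_squares(
        lambda x: model(x) - y, np.clip(x0, lo, hi), bounds=(lo, hi),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return ParamFit(
        a_init=float(fit.x[0]),
        p_prod=float(fit.x[1]),
        k=float(fit.x[2]),
        residual_norm=float(np.linalg.norm(fit.fun)),
        converged=bool(fit.success),
    )
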