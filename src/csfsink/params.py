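"""Domain parameter types for the soluble-amyloid kinetic model.

Units convention throughout the package: time in months, soluble
amyloid-beta concentration in pg/mL, fibrillar amyloid burden in
centiloids (CL). All rate constants are per month.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

__all__ = [
    "KineticParams",
    "TherapySchedule",
    "IMMEDIATE",
    "DEFAULT_ONSET_MONTH",
    "PET_POSITIVITY_CL",
    "PET_NEGATIVITY_CL",
]

#: Month of symptomatic disease onset on the model clock; therapy arms
#: start treatment here by default.
DEFAULT_ONSET_MONTH = 120.0
#: Amyloid-PET positivity threshold (centiloids).
PET_POSITIVITY_CL = 35.0
#: Amyloid-PET negativity threshold (centiloids).
PET_NEGATIVITY_CL = 24.0

#: Sentinel for an instantaneous post-discontinuation washout.
IMMEDIATE = "immediate"


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the one-compartment soluble CSF amyloid-beta model.

    The soluble pool obeys dA/dt = P - k(t) A where k = c_nat untreated,
    k = c_nat + c_it under continuous intrathecal pseudodelivery, and
    discrete IV doses multiply A instantaneously by (1 - e_dose).

    Attributes
    ----------
    a0 : float
        Initial soluble concentration at model time 0 (pg/mL).
    p_prod : float
        Constant production rate of soluble amyloid-beta (pg/mL/month).
    c_nat : float
        Natural (physiological) clearance rate (1/month).
    c_it : float
        Added clearance induced by intrathecal pseudodelivery (1/month).
    e_dose : float
        Fractional reduction of the soluble pool per IV dose, in [0, 1).
    tau_dose : float
        IV dosing interval (months).
    """

    a0: float = 100.0
    p_prod: float = 180.0
    c_nat: float = 0.05
    c_it: float = 0.90
    e_dose: float = 0.60
    tau_dose: float = 1.0

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ValueError(f"a0 must be >= 0, got {self.a0}")
        if self.p_prod < 0:
            raise ValueError(f"p_prod must be >= 0, got {self.p_prod}")
        if self.c_nat <= 0:
            raise ValueError(f"c_nat must be > 0, got {self.c_nat}")
        if self.c_it < 0:
            raise ValueError(f"c_it must be >= 0, got {self.c_it}")
        if not (0.0 <= self.e_dose < 1.0):
            raise ValueError(f"e_dose must be in [0, 1), got {self.e_dose}")
        if self.tau_dose <= 0:
            raise ValueError(f"tau_dose must be > 0, got {self.tau_dose}")

    def replace(self, **kwargs) -> "KineticParams":
        d = asdict(self)
        d.update(kwargs)
        return KineticParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class TherapySchedule:
    """Therapy arm, start/stop times and post-stop washout.

    Attributes
    ----------
    arm : str
        One of ``"untreated"``, ``"intrathecal"``, ``"iv"``.
    t_start : float
        Month at which therapy begins (first IV dose is given at
        ``t_start``, then every ``tau_dose`` while therapy is on).
    t_stop : float or None
        Month of discontinuation; ``None`` means therapy never stops.
    washout_rate : float or "immediate"
        Exponential decay rate (1/month) of the residual therapy effect
        after ``t_stop``. The intrathecal added clearance decays as
        ``c_it * exp(-washout_rate * (t - t_stop))``; IV dosing simply
        ceases at ``t_stop``. ``"immediate"`` removes the effect at once.
    """

    arm: str = "untreated"
    t_start: float = DEFAULT_ONSET_MONTH
    t_stop: Union[float, None] = None
    washout_rate: Union[float, str] = IMMEDIATE

    def __post_init__(self) -> None:
        if self.arm not in ("untreated", "intrathecal", "iv"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.t_stop is not None and self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")
        if self.washout_rate != IMMEDIATE:
            if not isinstance(self.washout_rate, (int, float)) or self.washout_rate <= 0:
                raise ValueError("washout_rate must be > 0 or 'immediate'")

    @property
    def immediate_washout(self) -> bool:
        return self.washout_rate == IMMEDIATE

    def dose_times(self, params: KineticParams, t_end: float) -> list:
        """IV dose instants t_start + n*tau_dose in [t_start, min(t_stop, t_end))."""
        if self.arm != "iv":
            return []
        stop = t_end if self.t_stop is None else min(self.t_stop, t_end)
        times, t, n = [], self.t_start, 0
        while t < stop - 1e-12:
            times.append(t)
            n += 1
            t = self.t_start + n * params.tau_dose
        return times


def load_json_config(path: Union[str, Path]) -> dict:
    """Read a JSON configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
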