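"""Time-stamped trajectory containers for the soluble and PET compartments.

Dose instants appear twice in a soluble trajectory grid (pre-dose then
post-dose value at the same time stamp), so ``times`` is non-decreasing
and strictly increasing everywhere except at dose instants.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["SolubleTrajectory", "PetTrajectory"]


def _check_grid(times: np.ndarray, values: np.ndarray, allow_ties: bool) -> None:
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(times) == 0:
        raise ValueError("empty trajectory")
    d = np.diff(times)
    if allow_ties:
        if np.any(d < 0):
            raise ValueError("times must be non-decreasing")
    else:
        if np.any(d <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SolubleTrajectory:
    """Soluble CSF amyloid-beta concentration curve (pg/mL vs months).

    Attributes
    ----------
    times : ndarray
        Non-decreasing time grid; dose instants are duplicated so both
        the pre-dose and post-dose concentration are recorded.
    conc : ndarray
        Concentration at each grid point (pg/mL), nonnegative.
    dose_times : ndarray
        IV dose instants (months), empty for non-IV arms.
    events : list of str
        Per-point annotation: "", "start", "stop", "dose_pre", "dose_post".
    """

    times: np.ndarray
    conc: np.ndarray
    dose_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    events: Optional[list] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.dose_times = np.asarray(self.dose_times, dtype=float)
        _check_grid(self.times, self.conc, allow_ties=True)
        if np.any(self.conc < -1e-9):
            raise ValueError("negative concentration in trajectory")
        if self.events is None:
            self.events = [""] * len(self.times)

    @property
    def t_span(self) -> tuple:
        return float(self.times[0]), float(self.times[-1])

    def value_at(self, t: float, convention: str = "instant") -> float:
        """Concentration at time ``t``.

        At a dose instant the pre-dose value is returned under the
        ``"pre_dose"`` convention and the post-dose value under
        ``"instant"`` (the right-continuous reading).
        """
        lo, hi = self.t_span
        if not (lo - 1e-9 <= t <= hi + 1e-9):
            raise ValueError(f"t={t} outside trajectory span [{lo}, {hi}]")
        i_left = int(np.searchsorted(self.times, t, side="left"))
        i_right = int(np.searchsorted(self.times, t, side="right"))
        if i_right > i_left:  # t lands exactly on (possibly duplicated) grid point
            return float(self.conc[i_left if convention == "pre_dose" else i_right - 1])
        return float(np.interp(t, self.times, self.conc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_month": self.times, "conc_pg_ml": self.conc, "event": self.events}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the trajectory as UTF-8 CSV (time_month, conc_pg_ml, event)."""
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SolubleTrajectory":
        df = pd.read_csv(path, keep_default_na=False)
        ev = list(df["event"].astype(str)) if "event" in df else None
        dose = df.loc[df.get("event", "") == "dose_pre", "time_month"].to_numpy() if ev else np.empty(0)
        return cls(df["time_month"].to_numpy(), df["conc_pg_ml"].to_numpy(), dose, ev)


@dataclass
class PetTrajectory:
    """Fibrillar amyloid burden curve (centiloids vs months)."""

    times: np.ndarray
    centiloids: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centiloids = np.asarray(self.centiloids, dtype=float)
        _check_grid(self.times, self.centiloids, allow_ties=True)
        if np.any(self.centiloids < -1e-9):
            raise ValueError("negative centiloid value in trajectory")

    @property
    def t_span(self) -> tuple:
        return float(self.times[0]), float(self.times[-1])

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.centiloids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_month": self.times, "centiloid": self.centiloids})

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PetTrajectory":
        df = pd.read_csv(path)
        return cls(df["time_month"].to_numpy(), df["centiloid"].to_numpy())
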