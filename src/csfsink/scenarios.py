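"""Scenario pipeline: two-arm cohort comparison, discontinuation study
and sensitivity sweeps, with JSON config and report writers.

The three arms share one model clock: amyloid accumulates untreated
from model time 0; the treated arms start therapy at symptomatic onset
(month 120 by default, when the untreated PET trajectory reaches the
35-CL positivity threshold under the shipped calibration).
"""
from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .kinetics import (
    GridSpec,
    percent_reduction,
    reaccumulation_time,
    simulate_soluble,
    steady_state_soluble,
)
from .params import (
    DEFAULT_ONSET_MONTH,
    IMMEDIATE,
    KineticParams,
    PET_NEGATIVITY_CL,
    PET_POSITIVITY_CL,
    TherapySchedule,
)
from .pet import (
    FibrillarParams,
    calibrated_defaults,
    detect_crossing,
    simulate_fibrillar,
)
from .trajectories import PetTrajectory, SolubleTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ScenarioReport",
    "run_cohort_comparison",
    "run_discontinuation",
    "sensitivity_sweep",
]

ARMS = ("untreated", "intrathecal", "iv")


@dataclass
class ScenarioConfig:
    """Full scenario configuration; defaults reproduce the reference setting.

    ``fibrillar`` may be None, in which case the shipped calibrated
    surrogate (and its arm-specific washout rates) is used. Reduction
    metrics are evaluated ``reduction_eval_months`` after therapy start
    relative to the untreated level at start (pre-dose convention for
    the IV arm).
    """

    kinetic: KineticParams = field(default_factory=KineticParams)
    fibrillar: Optional[FibrillarParams] = None
    washout_it: Optional[float] = None
    washout_iv: Optional[float] = None
    t_start: float = DEFAULT_ONSET_MONTH
    positivity_cl: float = PET_POSITIVITY_CL
    negativity_cl: float = PET_NEGATIVITY_CL
    grid: GridSpec = field(default_factory=GridSpec)
    t_end_discontinuation: float = 320.0
    reduction_eval_months: float = 12.0
    stop_rule: str = "negativity"  # each arm stops at its own negativity time
    immediate_washout: bool = False
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.negativity_cl >= self.positivity_cl:
            raise ValueError("negativity threshold must lie below positivity")
        if min(self.negativity_cl, self.positivity_cl) <= 0:
            raise ValueError("thresholds must be positive")

    def resolved_fibrillar(self):
        """(FibrillarParams, washout_it, washout_iv) with defaults filled in."""
        if self.fibrillar is None:
            fp, w_it, w_iv = calibrated_defaults()
        else:
            fp, w_it, w_iv = self.fibrillar, self.washout_it, self.washout_iv
            if w_it is None or w_iv is None:
                _, d_it, d_iv = calibrated_defaults()
                w_it = d_it if w_it is None else w_it
                w_iv = d_iv if w_iv is None else w_iv
        return fp, w_it, w_iv

    def to_dict(self) -> dict:
        d = {
            "kinetic": self.kinetic.to_dict(),
            "fibrillar": None if self.fibrillar is None else self.fibrillar.to_dict(),
            "washout_it": self.washout_it,
            "washout_iv": self.washout_iv,
            "t_start": self.t_start,
            "positivity_cl": self.positivity_cl,
            "negativity_cl": self.negativity_cl,
            "grid": {"t_end": self.grid.t_end, "dt": self.grid.dt},
            "t_end_discontinuation": self.t_end_discontinuation,
            "reduction_eval_months": self.reduction_eval_months,
            "stop_rule": self.stop_rule,
            "immediate_washout": self.immediate_washout,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        kw = dict(d)
        if "kinetic" in kw and isinstance(kw["kinetic"], dict):
            kw["kinetic"] = KineticParams.from_dict(kw["kinetic"])
        fib = kw.get("fibrillar")
        if isinstance(fib, dict):
            kw["fibrillar"] = FibrillarParams(**fib)
        if "grid" in kw and isinstance(kw["grid"], dict):
            kw["grid"] = GridSpec(**kw["grid"])
        known = set(cls.__dataclass_fields__)
        unknown = set(kw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ScenarioReport:
    """Per-arm milestone metrics plus provenance."""

    arms: dict
    comparison: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"arms": self.arms, "comparison": self.comparison,
                "provenance": self.provenance}

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _schedule_for(arm: str, config: ScenarioConfig, t_stop: Optional[float],
                  w_it, w_iv) -> TherapySchedule:
    if arm == "untreated":
        return TherapySchedule(arm="untreated")
    rate: Union[float, str]
    if config.immediate_washout:
        rate = IMMEDIATE
    else:
        rate = w_it if arm == "intrathecal" else w_iv
    return TherapySchedule(arm=arm, t_start=config.t_start, t_stop=t_stop,
                           washout_rate=rate)


def _simulate_arm(arm: str, config: ScenarioConfig, grid: GridSpec,
                  t_stop: Optional[float] = None):
    import dataclasses

    fp, w_it, w_iv = config.resolved_fibrillar()
    # a null-delivery arm (no added clearance / zero-effect doses) carries no
    # antibody at all, so it induces no fibrillar clearance either
    if arm == "intrathecal" and config.kinetic.c_it == 0.0:
        fp = dataclasses.replace(fp, gamma_it=0.0)
    if arm == "iv" and config.kinetic.e_dose == 0.0:
        fp = dataclasses.replace(fp, gamma_iv=0.0)
    sched = _schedule_for(arm, config, t_stop, w_it, w_iv)
    sol = simulate_soluble(sched, config.kinetic, grid)
    pet = simulate_fibrillar(sol, fp, sched)
    return sched, sol, pet


def _write_trajectories(tag: str, arm: str, sol, pet, config: ScenarioConfig) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sol.to_csv(out / f"{tag}_{arm}_soluble.csv")
    pet.to_csv(out / f"{tag}_{arm}_pet.csv")


def run_cohort_comparison(config: Optional[ScenarioConfig] = None) -> ScenarioReport:
    """Simulate all three arms on a shared clock and report milestones.

    Per arm: PET positivity/negativity crossing times, CSF percent
    reduction at the evaluation horizon after therapy start, and
    trough/peak summaries for the IV arm. Trajectories are written as
    CSV when ``config.output_dir`` is set.
    """
    config = config or ScenarioConfig()
    kp = config.kinetic
    grid = config.grid
    arms: dict = {}
    baseline = None
    for arm in ARMS:
        sched, sol, pet = _simulate_arm(arm, config, grid)
        _write_trajectories("compare", arm, sol, pet, config)
        entry: dict = {
            "pet_positivity_month": detect_crossing(pet, config.positivity_cl, "up"),
            "pet_negativity_month": None,
            "csf_reduction_12mo_pct": None,
        }
        if arm == "untreated":
            baseline = sol.value_at(config.t_start, convention="pre_dose")
            entry["soluble_at_onset_pg_ml"] = baseline
        else:
            entry["pet_negativity_month"] = detect_crossing(
                pet, config.negativity_cl, "down", t_min=config.t_start
            )
            t_eval = config.t_start + config.reduction_eval_months
            conv = "pre_dose" if arm == "iv" else "instant"
            entry["csf_reduction_12mo_pct"] = 100.0 * percent_reduction(
                sol, baseline, t_eval, convention=conv
            )
        if arm == "iv":
            entry["iv_trough_pg_ml"] = steady_state_soluble(kp, "iv_trough")
            entry["iv_peak_pg_ml"] = steady_state_soluble(kp, "iv_peak")
        arms[arm] = entry
    t_it = arms["intrathecal"]["pet_negativity_month"]
    t_iv = arms["iv"]["pet_negativity_month"]
    comparison = {
        "negativity_difference_months": None
        if t_it is None or t_iv is None
        else t_iv - t_it
    }
    report = ScenarioReport(
        arms=arms,
        comparison=comparison,
        provenance={
            "config_hash": config.config_hash(),
            "version": _pkg_version,
            "seed": config.seed,
        },
    )
    if config.output_dir is not None:
        report.to_json(Path(config.output_dir) / "compare_report.json")
    return report


def run_discontinuation(config: Optional[ScenarioConfig] = None) -> ScenarioReport:
    """Discontinuation study with the stop-at-negativity rule.

    Each treated arm stops at its own PET-negativity time, the
    simulation continues through washout, and the report carries the
    interval from discontinuation to re-crossing the positivity
    threshold per arm (intrathecal minus IV difference in
    ``comparison``) plus the soluble reaccumulation half-time.
    """
    config = config or ScenarioConfig()
    base = run_cohort_comparison(
        ScenarioConfig(**{**_cfg_kwargs(config), "output_dir": None})
    )
    disc_grid = GridSpec(t_end=config.t_end_discontinuation, dt=config.grid.dt)
    arms: dict = dict(untreated=base.arms["untreated"])
    intervals: dict = {}
    for arm in ("intrathecal", "iv"):
        entry = dict(base.arms[arm])
        t_neg = entry["pet_negativity_month"]
        if t_neg is None:
            logger.info("%s arm never reached PET negativity; no discontinuation", arm)
            entry.update(
                discontinuation_month=None,
                repositivity_month=None,
                repositivity_interval_months=None,
                soluble_half_recovery_months=None,
            )
            arms[arm] = entry
            continue
        sched, sol, pet = _simulate_arm(arm, config, disc_grid, t_stop=t_neg)
        _write_trajectories("discontinue", arm, sol, pet, config)
        t_re = detect_crossing(pet, config.positivity_cl, "up", t_min=t_neg)
        interval = None if t_re is None else t_re - t_neg
        intervals[arm] = interval
        washout = sched.washout_rate if arm == "intrathecal" else IMMEDIATE
        half = reaccumulation_time(
            config.kinetic,
            sol.value_at(t_neg, convention="pre_dose"),
            0.5,
            washout=washout,
        )
        entry.update(
            discontinuation_month=t_neg,
            repositivity_month=t_re,
            repositivity_interval_months=interval,
            soluble_half_recovery_months=half,
        )
        arms[arm] = entry
    comparison = dict(base.comparison)
    it_i, iv_i = intervals.get("intrathecal"), intervals.get("iv")
    comparison["repositivity_delay_months"] = (
        None if it_i is None or iv_i is None else it_i - iv_i
    )
    report = ScenarioReport(
        arms=arms,
        comparison=comparison,
        provenance={
            "config_hash": config.config_hash(),
            "version": _pkg_version,
            "seed": config.seed,
        },
    )
    if config.output_dir is not None:
        report.to_json(Path(config.output_dir) / "discontinue_report.json")
    return report


def _cfg_kwargs(config: ScenarioConfig) -> dict:
    d = {f: getattr(config, f) for f in ScenarioConfig.__dataclass_fields__}
    return d


def sensitivity_sweep(
    config: Optional[ScenarioConfig] = None,
    param_grid: Optional[dict] = None,
) -> pd.DataFrame:
    """Cross-product sweep of kinetic parameters.

    ``param_grid`` maps KineticParams field names to value lists. Each
    row reports time-to-negativity per treated arm, the 12-month CSF
    reduction, the analytic IV trough, and the immediate-washout
    soluble half-recovery time. Invalid combinations are skipped with a
    logged warning.
    """
    config = config or ScenarioConfig()
    if not param_grid:
        raise ValueError("param_grid must be a nonempty mapping")
    names = sorted(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        overrides = dict(zip(names, combo))
        try:
            kp = config.kinetic.replace(**overrides)
        except (ValueError, TypeError) as exc:
            logger.warning("skipping invalid combination %s: %s", overrides, exc)
            continue
        cfg = ScenarioConfig(**{**_cfg_kwargs(config), "kinetic": kp,
                                "output_dir": None})
        rep = run_cohort_comparison(cfg)
        row = dict(overrides)
        row["t_negativity_it"] = rep.arms["intrathecal"]["pet_negativity_month"]
        row["t_negativity_iv"] = rep.arms["iv"]["pet_negativity_month"]
        row["csf_reduction_12mo_it_pct"] = rep.arms["intrathecal"][
            "csf_reduction_12mo_pct"
        ]
        row["csf_reduction_12mo_iv_pct"] = rep.arms["iv"]["csf_reduction_12mo_pct"]
        row["iv_trough_pg_ml"] = steady_state_soluble(kp, "iv_trough")
        half = reaccumulation_time(
            kp, steady_state_soluble(kp, "intrathecal"), 0.5, washout=IMMEDIATE
        )
        row["soluble_half_recovery_months"] = half
        rows.append(row)
    return pd.DataFrame(rows)
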