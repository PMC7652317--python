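"""Synthetic two-arm trial generator with known ground truth.

Emulates the published inputs of the analysis: per-arm survival IPD with
right censoring, recurrent heart-failure hospitalisations with a plateauing
cohort cumulative count, Kaplan-Meier step curves, numbers-at-risk tables,
and "digitized" coordinate exports (noisy point samples of the KM curve,
as a plot digitizer would produce).  Time is in months from randomization.

Censoring combines an exponential censoring hazard with an administrative
cut-off at the follow-up horizon.  Each patient's lifetime hospitalisation
target is Poisson with mean equal to the per-patient plateau; event times
are i.i.d. loglogistic, truncated at the patient's observed time, so the
cohort cumulative count plateaus as the model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .reconstruct import DigitizedCurve, RiskTable

__all__ = [
    "OSTruth",
    "HFHTruth",
    "TrialSpec",
    "SyntheticTrial",
    "simulate_ipd",
    "simulate_hospitalisations",
    "km_estimate",
    "digitize_km",
    "simulate_trial",
]

_OS_FAMILIES = ("exponential", "weibull", "loglogistic")


@dataclass(frozen=True)
class OSTruth:
    """True death-time distribution for one arm (monthly scale)."""

    family: str = "exponential"
    rate: float | None = 0.02  # exponential monthly hazard
    scale: float | None = None  # weibull / loglogistic scale (months)
    shape: float | None = None

    def __post_init__(self):
        if self.family not in _OS_FAMILIES:
            raise ValueError(f"unknown OS family {self.family!r}")
        if self.family == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ValueError("exponential needs rate > 0")
        else:
            if self.scale is None or self.scale <= 0 or self.shape is None or self.shape <= 0:
                raise ValueError(f"{self.family} needs scale > 0 and shape > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(size=n)
        if self.family == "exponential":
            return -np.log(u) / self.rate
        if self.family == "weibull":
            return self.scale * (-np.log(u)) ** (1.0 / self.shape)
        # loglogistic inverse CDF: S(t) = 1/(1+(t/a)^b)
        return self.scale * ((1.0 - u) / u) ** (1.0 / self.shape)


@dataclass(frozen=True)
class HFHTruth:
    """True per-patient hospitalisation process for one arm.

    ``plateau`` is the expected lifetime hospitalisation count per patient;
    event times are loglogistic(scale, shape) in months.
    """

    scale: float = 12.0
    shape: float = 1.5
    plateau: float = 1.0

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("scale and shape must be > 0")
        if self.plateau < 0:
            raise ValueError("plateau must be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """Ground-truth description of a synthetic two-arm trial."""

    arm_sizes: dict = field(default_factory=lambda: {"intervention": 150, "control": 150})
    os_truth: dict = field(
        default_factory=lambda: {
            "intervention": OSTruth(),
            "control": OSTruth(),
        }
    )
    hfh_truth: dict = field(
        default_factory=lambda: {
            "intervention": HFHTruth(),
            "control": HFHTruth(),
        }
    )
    censor_rate: float = 0.005  # exponential monthly censoring hazard
    follow_up_months: float = 24.0
    seed: int = 0

    def __post_init__(self):
        for arm, n in self.arm_sizes.items():
            if int(n) < 1:
                raise ValueError(f"arm {arm!r} must have >= 1 patient")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not 0 < self.follow_up_months <= 360:
            raise ValueError("follow_up_months must lie in (0, 360]")
        missing = set(self.arm_sizes) - set(self.os_truth)
        if missing or set(self.arm_sizes) - set(self.hfh_truth):
            raise ValueError("os_truth and hfh_truth must cover every arm")

    @property
    def arms(self) -> tuple:
        return tuple(self.arm_sizes)

    def _arm_rng(self, arm: str, stream: int) -> np.random.Generator:
        idx = list(self.arm_sizes).index(arm)
        return np.random.default_rng([self.seed, idx, stream])


def simulate_ipd(spec: TrialSpec, arm: str) -> pd.DataFrame:
    """Simulate one arm's survival IPD: columns time_months, event.

    time = min(death draw, censor draw, follow-up); event flags death only.
    Deterministic given the spec's seed and the arm label.
    """
    if arm not in spec.arm_sizes:
        raise ValueError(f"unknown arm {arm!r}")
    rng = spec._arm_rng(arm, 0)
    n = int(spec.arm_sizes[arm])
    death = spec.os_truth[arm].draw(rng, n)
    if spec.censor_rate > 0:
        censor = -np.log(rng.uniform(size=n)) / spec.censor_rate
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, spec.follow_up_months)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return pd.DataFrame({"time_months": time, "event": event})


def simulate_hospitalisations(ipd: pd.DataFrame, hfh_truth: HFHTruth, seed: int):
    """Simulate per-patient hospitalisation event times for one arm.

    Each patient draws a lifetime target count Poisson(plateau); event times
    are i.i.d. loglogistic(scale, shape), of which only those at or before
    the patient's observed (death/censor) time are kept.  Returns the list
    of per-patient event-time arrays and the cohort cumulative count curve
    as (sorted event times, cumulative counts).
    """
    if hfh_truth.plateau < 0:
        raise ValueError("plateau must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.asarray(ipd["time_months"], dtype=float)
    per_patient = []
    for t_obs in times:
        k = rng.poisson(hfh_truth.plateau) if hfh_truth.plateau > 0 else 0
        if k == 0:
            per_patient.append(np.empty(0))
            continue
        u = rng.uniform(size=k)
        ev = hfh_truth.scale * ((1.0 - u) / u) ** (1.0 / hfh_truth.shape)
        per_patient.append(np.sort(ev[ev <= t_obs]))
    all_events = np.sort(np.concatenate(per_patient)) if per_patient else np.empty(0)
    cum_counts = np.arange(1, all_events.size + 1, dtype=float)
    return per_patient, (all_events, cum_counts)


def km_estimate(ipd: pd.DataFrame):
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns (times, survival) step-function points including t = 0, S = 1.
    """
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], ipd["event"])
    sf = kmf.survival_function_
    times = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.iloc[:, 0], dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return times, surv


def _step_value(times: np.ndarray, values: np.ndarray, t) -> np.ndarray:
    """Right-continuous step-function evaluation."""
    idx = np.searchsorted(times, np.asarray(t, dtype=float), side="right") - 1
    return values[np.clip(idx, 0, len(values) - 1)]


def number_at_risk(ipd: pd.DataFrame, at_times) -> np.ndarray:
    """True number of patients still at risk at each requested time."""
    t_obs = np.asarray(ipd["time_months"], dtype=float)
    at = np.asarray(at_times, dtype=float)
    return np.array([(t_obs >= t).sum() for t in at], dtype=int)


def digitize_km(
    km,
    ipd: pd.DataFrame,
    n_points: int = 100,
    jitter_sd: float = 0.0,
    interval_months: float = 6.0,
    seed: int = 0,
    arm: str = "",
):
    """Emulate plot-digitizer output for a KM curve.

    Samples ``n_points`` coordinates on a uniform time grid over the curve's
    span, reads the step-function value, adds Gaussian noise with standard
    deviation ``jitter_sd`` and clips to [0, 1].  The risk table reports the
    true numbers at risk at multiples of ``interval_months``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    times, surv = km
    rng = np.random.default_rng(seed)
    t_max = float(times[-1])
    grid = np.linspace(0.0, t_max, n_points)
    vals = _step_value(np.asarray(times, float), np.asarray(surv, float), grid)
    if jitter_sd > 0:
        vals = vals + rng.normal(0.0, jitter_sd, size=vals.shape)
    vals = np.clip(vals, 0.0, 1.0)
    curve = DigitizedCurve(times=grid, values=vals, kind="survival", arm=arm)

    risk_times = np.arange(0.0, t_max + 1e-9, interval_months)
    risk = number_at_risk(ipd, risk_times)
    table = RiskTable(times=risk_times, n_risk=risk)
    return curve, table


@dataclass
class SyntheticTrial:
    """All generated artifacts of one synthetic trial."""

    spec: TrialSpec
    ipd: dict  # arm -> DataFrame(time_months, event)
    hosp_events: dict  # arm -> list of per-patient event-time arrays
    hosp_curve: dict  # arm -> (event times, cumulative counts)
    km: dict  # arm -> (times, survival)


def simulate_trial(spec: TrialSpec) -> SyntheticTrial:
    """Generate IPD, hospitalisations and KM curves for every arm."""
    ipd, hosp_events, hosp_curve, km = {}, {}, {}, {}
    for i, arm in enumerate(spec.arms):
        df = simulate_ipd(spec, arm)
        ipd[arm] = df
        ev, curve = simulate_hospitalisations(
            df, spec.hfh_truth[arm], seed=int(spec._arm_rng(arm, 1).integers(2**31))
        )
        hosp_events[arm] = ev
        hosp_curve[arm] = curve
        km[arm] = km_estimate(df)
    return SyntheticTrial(spec=spec, ipd=ipd, hosp_events=hosp_events,
                          hosp_curve=hosp_curve, km=km)


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False)


def write_curve_csv(times, values, path) -> None:
    pd.DataFrame({"time_months": times, "value": values}).to_csv(path, index=False)


def write_risk_table_csv(table: RiskTable, path) -> None:
    pd.DataFrame({"time_months": table.times, "n_risk": table.n_risk}).to_csv(
        path, index=False
    )
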