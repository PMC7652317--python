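"""Plateauing cumulative heart-failure-hospitalisation (HFH) model.

The cohort's cumulative hospitalisation count is modelled as

    cum(t) = max * (1 - exp(-Lambda(t)))

where ``Lambda`` is a parametric cumulative hazard and ``max`` the plateau
(asymptote) the cohort count approaches as survivors run out.  Two hazard
families are supported:

* ``loglogistic``: Lambda(t) = log(1 + (t/alpha)**beta), giving the closed
  form cum(t) = max * (t/alpha)**beta / (1 + (t/alpha)**beta);
* ``exponential``: Lambda(t) = k*t, giving cum(t) = max * (1 - exp(-k*t)) —
  this special case has a closed-form two-point calibration from a
  within-trial count and a lifetime plateau.

The model is fitted to digitized cumulative count curves by least squares,
and converted to per-cycle per-patient new-hospitalisation increments for
the cohort engine by monthly differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "HFHModel",
    "FixedIncrements",
    "cumulative_events",
    "fit_cumulative",
    "per_cycle_increments",
    "calibrate_two_point",
]


@dataclass(frozen=True)
class HFHModel:
    """Parametric cohort cumulative-hospitalisation curve.

    ``params`` is (alpha, beta) for loglogistic, (k,) for exponential.
    ``max_events`` is the cohort plateau; ``arm_size`` the randomized arm
    size used to convert cohort counts to per-patient increments.
    """

    family: str  # "loglogistic" | "exponential"
    params: tuple
    max_events: float
    arm_size: int

    def __post_init__(self):
        if self.family not in ("loglogistic", "exponential"):
            raise ValueError(f"unknown HFH family {self.family!r}")
        want = 2 if self.family == "loglogistic" else 1
        if len(self.params) != want:
            raise ValueError(f"{self.family} needs {want} parameter(s)")
        if any(p <= 0 for p in self.params):
            raise ValueError("scale/shape/rate parameters must be > 0")
        if self.max_events < 0:
            raise ValueError("max_events (plateau) must be >= 0")
        if self.arm_size < 1:
            raise ValueError("arm_size must be >= 1")

    def cumulative(self, t):
        return cumulative_events(self, t)

    def cumulative_events(self, t):
        return cumulative_events(self, t)

    def per_cycle_increments(self, horizon_months: int):
        return per_cycle_increments(self, horizon_months)


def cumulative_events(model: HFHModel, t) -> float | np.ndarray:
    """Cohort cumulative hospitalisation count at time ``t`` months."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if model.family == "loglogistic":
        alpha, beta = model.params
        z = (t / alpha) ** beta
        out = model.max_events * z / (1.0 + z)
    else:
        (k,) = model.params
        out = model.max_events * -np.expm1(-k * t)
    return out if out.ndim else float(out)


def per_cycle_increments(model: HFHModel, horizon_months: int) -> np.ndarray:
    """Per-patient new hospitalisations per monthly cycle, t = 0..horizon-1.

    increment(t) = [cum(t+1) - cum(t)] / arm_size; the increments telescope,
    so their sum times arm_size equals cum(horizon) exactly.
    """
    if horizon_months > 360:
        raise ValueError("horizon must be <= 360 months")
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    grid = np.arange(horizon_months + 1, dtype=float)
    cum = np.asarray(cumulative_events(model, grid), dtype=float)
    return np.diff(cum) / model.arm_size


class FixedIncrements:
    """Hospitalisation schedule given directly as per-cycle increments.

    Used by treatment-effect curtailment/waning scenarios, where the
    intervention arm's monthly increments are spliced or blended with the
    control arm's and no single parametric curve applies.
    """

    def __init__(self, increments, arm_size: int):
        self.increments = np.asarray(increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValueError("increments must be >= 0")
        if arm_size < 1:
            raise ValueError("arm_size must be >= 1")
        self.arm_size = int(arm_size)

    def per_cycle_increments(self, horizon_months: int) -> np.ndarray:
        if horizon_months > len(self.increments):
            raise ValueError("horizon exceeds stored increment schedule")
        return self.increments[:horizon_months]


def fit_cumulative(times, values, family: str, arm_size: int) -> HFHModel:
    """Least-squares fit of the plateauing curve to a cumulative-count curve.

    ``times``/``values`` are a preprocessed digitized cumulative-count curve
    (>= 3 points, non-decreasing).  The plateau is constrained to be at
    least the final observed count.  A flat all-zero curve yields
    ``max_events = 0`` with an arbitrary scale (flagged by a warning).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 points to fit")
    if np.any(y < 0):
        raise ValueError("cumulative counts must be >= 0")
    y_final = float(y[-1])
    if y_final == 0.0:
        warnings.warn("flat zero curve: plateau 0, scale arbitrary", stacklevel=2)
        params = (1.0, 1.0) if family == "loglogistic" else (1.0,)
        return HFHModel(family, params, 0.0, arm_size)

    t_med = float(np.interp(y_final / 2.0, y, t))  # time at half the final count
    if family == "loglogistic":
        def resid(x):
            alpha, beta, mx = np.exp(x[0]), np.exp(x[1]), y_final + np.exp(x[2])
            m = HFHModel("loglogistic", (alpha, beta), mx, arm_size)
            return cumulative_events(m, t) - y

        starts = [
            (np.log(max(t_med, 1e-3)), np.log(s), np.log(max(0.3 * y_final, 1e-6)))
            for s in (1.0, 0.5, 2.0)
        ]
        n_par = 3
        build = lambda x: HFHModel(
            "loglogistic", (np.exp(x[0]), np.exp(x[1])), y_final + np.exp(x[2]), arm_size
        )
    elif family == "exponential":
        def resid(x):
            k, mx = np.exp(x[0]), y_final + np.exp(x[1])
            m = HFHModel("exponential", (k,), mx, arm_size)
            return cumulative_events(m, t) - y

        k0 = np.log(2.0) / max(t_med, 1e-3)
        starts = [
            (np.log(k0 * s), np.log(max(0.3 * y_final, 1e-6))) for s in (1.0, 0.5, 2.0)
        ]
        n_par = 2
        build = lambda x: HFHModel(
            "exponential", (np.exp(x[0]),), y_final + np.exp(x[1]), arm_size
        )
    else:
        raise ValueError(f"unknown HFH family {family!r}")

    best = None
    for x0 in starts:
        # log-parameter bounds keep the search finite when the optimum sits on
        # a boundary (plateau at the final count, or a barely-curving series)
        res = optimize.least_squares(
            resid, np.clip(np.asarray(x0, dtype=float), -25.0, 25.0),
            bounds=(-30.0, 30.0), xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if np.all(np.isfinite(res.x)) and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"least-squares fit failed to converge for {family}")
    _ = n_par
    return build(best.x)


def calibrate_two_point(
    count_at_24m: float,
    plateau: float,
    arm_size: int,
    family: str = "exponential",
    beta: float | None = None,
) -> HFHModel:
    """Calibrate the curve through a 24-month count and a lifetime plateau.

    For the exponential family the rate has the closed form
    ``k = -ln(1 - count/plateau) / 24``.  For the loglogistic family the
    shape ``beta`` must be supplied and the scale alpha is solved so that
    cum(24) equals the observed count.
    """
    if not 0 < count_at_24m < plateau:
        raise ValueError("need 0 < count_at_24m < plateau")
    frac = count_at_24m / plateau
    if family == "exponential":
        k = -np.log1p(-frac) / 24.0
        return HFHModel("exponential", (k,), float(plateau), arm_size)
    if family == "loglogistic":
        if beta is None or beta <= 0:
            raise ValueError("loglogistic calibration needs a positive beta")
        # cum(24)/max = z/(1+z) with z = (24/alpha)**beta  =>  z = frac/(1-frac)
        z = frac / (1.0 - frac)
        alpha = 24.0 / z ** (1.0 / beta)
        return HFHModel("loglogistic", (alpha, beta), float(plateau), arm_size)
    raise ValueError(f"unknown HFH family {family!r}")
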