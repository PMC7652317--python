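"""Parametric survival models on the monthly time scale.

Five standard families are supported, each parameterised with strictly
positive parameters on the monthly time scale:

========== ======================== =======================================
family      params                   survival function S(t)
========== ======================== =======================================
exponential rate (lambda)           exp(-lambda * t)
weibull     scale, shape            exp(-(t/scale)**shape)
gompertz    rate (a), shape (b)     exp(-(a/b) * (exp(b*t) - 1))
loglogistic scale (alpha), shape    1 / (1 + (t/alpha)**shape)
lognormal   scale (exp(mu)), sigma  1 - Phi((ln t - ln scale)/sigma)
========== ======================== =======================================

A hazard ratio ``hr`` acts multiplicatively on the hazard, i.e.
``S_hr(t) = S(t) ** hr`` (proportional hazards imposed on the survival
function for the non-PH families, since hazard ratios are applied
generically between arms).

Fitting maximises the right-censored log-likelihood by quasi-Newton search
on log-transformed parameters with three starts; the exponential MLE is
closed form (events / total follow-up time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import life_expectancy

__all__ = [
    "FAMILIES",
    "SurvModel",
    "fit_parametric",
    "survival_at",
    "apply_hazard_ratio",
    "rank_models",
    "calibrate_exponential_to_life_expectancy",
    "CurtailedSurvival",
    "WanedSurvival",
]

FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "gompertz": ("rate", "shape"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("scale", "sigma"),
}


def _log_sf(family: str, t: np.ndarray, p: tuple) -> np.ndarray:
    """log S(t) for the base model (hr = 1)."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = p
        return -lam * t
    if family == "weibull":
        scale, shape = p
        return -((t / scale) ** shape)
    if family == "gompertz":
        a, b = p
        return -(a / b) * np.expm1(b * t)
    if family == "loglogistic":
        scale, shape = p
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (t / scale) ** shape, 0.0)
        return -np.log1p(z)
    if family == "lognormal":
        scale, sigma = p
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - np.log(scale)) / sigma, -np.inf)
        return stats.norm.logsf(z)
    raise ValueError(f"unknown family {family!r}")


def _log_pdf(family: str, t: np.ndarray, p: tuple) -> np.ndarray:
    """log f(t) for the base model; t must be > 0."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = p
        return np.log(lam) - lam * t
    if family == "weibull":
        scale, shape = p
        z = t / scale
        return np.log(shape / scale) + (shape - 1.0) * np.log(z) - z**shape
    if family == "gompertz":
        a, b = p
        return np.log(a) + b * t - (a / b) * np.expm1(b * t)
    if family == "loglogistic":
        scale, shape = p
        z = (t / scale) ** shape
        return np.log(shape / scale) + (shape - 1.0) * np.log(t / scale) - 2.0 * np.log1p(z)
    if family == "lognormal":
        scale, sigma = p
        z = (np.log(t) - np.log(scale)) / sigma
        return stats.norm.logpdf(z) - np.log(sigma * t)
    raise ValueError(f"unknown family {family!r}")


def _hazard(family: str, t: np.ndarray, p: tuple) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = p
        return np.full_like(t, lam)
    if family == "gompertz":
        a, b = p
        return a * np.exp(b * t)
    return np.exp(_log_pdf(family, np.maximum(t, 1e-12), p) - _log_sf(family, t, p))


@dataclass(frozen=True)
class SurvModel:
    """A fitted or calibrated parametric survival model.

    ``hr`` multiplies the hazard: survival is ``S_base(t) ** hr``.
    ``loglik``/``aic`` are present only for maximum-likelihood fits.
    """

    family: str
    params: tuple
    hr: float = 1.0
    loglik: float | None = None
    aic: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.params) != len(_PARAM_NAMES[self.family]):
            raise ValueError(
                f"{self.family} needs params {_PARAM_NAMES[self.family]}"
            )
        if any(p <= 0 for p in self.params):
            raise ValueError("all parameters must be strictly positive")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")

    @property
    def param_names(self) -> tuple:
        return _PARAM_NAMES[self.family]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        out = np.exp(self.hr * _log_sf(self.family, t, self.params))
        return out if out.ndim else float(out)

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        out = -self.hr * _log_sf(self.family, t, self.params)
        return out if out.ndim else float(out)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        out = self.hr * _hazard(self.family, t, self.params)
        return out if out.ndim else float(out)


def survival_at(model: SurvModel, t) -> float | np.ndarray:
    """Survival probability at time ``t`` months (hazard ratio applied)."""
    return model.survival(t)


def apply_hazard_ratio(model: SurvModel, hr: float) -> SurvModel:
    """Return the model with an extra multiplicative hazard ratio applied."""
    if hr <= 0:
        raise ValueError("hr must be > 0")
    return replace(model, hr=model.hr * hr)


def _neg_loglik(family: str, log_p: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    p = tuple(np.exp(log_p))
    with np.errstate(over="ignore", invalid="ignore"):
        ll = np.where(
            event.astype(bool),
            _log_pdf(family, time, p),
            _log_sf(family, time, p),
        )
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def fit_parametric(ipd: pd.DataFrame, family: str) -> SurvModel:
    """Fit one family to right-censored IPD by maximum likelihood.

    ``ipd`` needs columns ``time_months`` (> 0) and ``event`` (0/1).
    Returns the model with its log-likelihood and AIC = 2k - 2*loglik.
    Raises if the family is unknown, fewer than 2 events are present, or
    the optimiser fails to converge from any start.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    time = np.asarray(ipd["time_months"], dtype=float)
    event = np.asarray(ipd["event"], dtype=int)
    if np.any(time <= 0):
        raise ValueError("all times must be > 0")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit, got {n_events}")

    total_time = float(time.sum())
    lam_hat = n_events / total_time  # closed-form exponential MLE
    if family == "exponential":
        ll = n_events * np.log(lam_hat) - lam_hat * total_time
        return SurvModel("exponential", (lam_hat,), loglik=float(ll), aic=float(2 - 2 * ll))

    med = float(np.median(time))
    starts = {
        "weibull": [(med, 1.0), (med, 0.7), (med, 1.5)],
        "gompertz": [(lam_hat, 0.01), (lam_hat / 2, 0.05), (lam_hat, 0.001)],
        "loglogistic": [(med, 1.0), (med, 0.7), (med, 2.0)],
        "lognormal": [(med, 1.0), (med, 0.5), (med, 2.0)],
    }[family]

    best = None
    for p0 in starts:
        res = optimize.minimize(
            lambda lp: _neg_loglik(family, lp, time, event),
            np.log(np.asarray(p0, dtype=float)),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"maximum-likelihood fit failed to converge for {family}")
    params = tuple(np.exp(best.x))
    ll = -float(best.fun)
    k = len(params)
    return SurvModel(family, params, loglik=ll, aic=float(2 * k - 2 * ll))


def rank_models(fits: list[SurvModel]) -> pd.DataFrame:
    """Rank fitted models by ascending AIC (ties: fewer parameters first)."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for m in fits:
        if m.aic is None:
            raise ValueError(f"model {m.family} has no AIC (not a fitted model)")
        rows.append(
            {
                "family": m.family,
                "params": m.params,
                "n_params": m.n_params,
                "loglik": m.loglik,
                "aic": m.aic,
            }
        )
    df = pd.DataFrame(rows).sort_values(["aic", "n_params"], kind="stable")
    return df.reset_index(drop=True)


def calibrate_exponential_to_life_expectancy(
    target_ly: float,
    horizon_months: int = 360,
    annual_discount: float = 0.0,
) -> SurvModel:
    """Solve for the exponential monthly hazard reproducing a life expectancy.

    Finds lambda by bracketing root search so that the cohort engine's
    (dis)counted life expectancy over ``horizon_months`` monthly cycles with
    midpoint accrual equals ``target_ly`` years (to 1e-8).  This lets the
    model be parameterised directly from a published life expectancy.
    """
    if not 0 < target_ly < horizon_months / 12.0:
        raise ValueError("target_ly must lie in (0, horizon/12) years")

    def gap(lam: float) -> float:
        m = SurvModel("exponential", (lam,))
        return life_expectancy(m, horizon_months, annual_discount) - target_ly

    lo, hi = 1e-10, 10.0
    max_le = gap(lo) + target_ly
    if target_ly >= max_le:
        raise ValueError(
            f"target {target_ly} LY unattainable: at most {max_le:.6f} LY "
            f"over this horizon/discount"
        )
    lam = optimize.brentq(gap, lo, hi, xtol=1e-14, rtol=1e-14)
    return SurvModel("exponential", (lam,))


class CurtailedSurvival:
    """Intervention survival whose hazard reverts to the control's after a cut-off.

    Before ``switch_month`` the hazard is the intervention model's; from
    ``switch_month`` on it is the control model's.  Survival is continuous:
    ``S(t) = S_i(t)`` for t <= T and ``S_i(T) * S_c(t)/S_c(T)`` beyond.
    """

    def __init__(self, intervention, control, switch_month: float):
        if switch_month <= 0:
            raise ValueError("switch_month must be > 0")
        self.intervention = intervention
        self.control = control
        self.switch_month = float(switch_month)

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        T = self.switch_month
        h_pre = self.intervention.cumulative_hazard(np.minimum(t, T))
        h_post = np.where(
            t > T,
            self.control.cumulative_hazard(np.maximum(t, T))
            - self.control.cumulative_hazard(T),
            0.0,
        )
        out = h_pre + h_post
        return out if out.ndim else float(out)

    def survival(self, t):
        out = np.exp(-np.asarray(self.cumulative_hazard(t), dtype=float))
        return out if out.ndim else float(out)


class WanedSurvival:
    """Intervention survival whose hazard wanes linearly towards the control's.

    Up to ``start_month`` the hazard is the intervention's own; between
    ``start_month`` and ``end_month`` it interpolates linearly (on the hazard
    scale) to the control hazard; beyond ``end_month`` it equals the
    control's.  The blended cumulative hazard is integrated on a fine grid
    (exact for constant hazards, where the blend is linear in t).
    """

    _GRID_STEP = 0.01  # months

    def __init__(self, intervention, control, start_month: float, end_month: float):
        if end_month <= start_month:
            raise ValueError("end_month must exceed start_month")
        self.intervention = intervention
        self.control = control
        self.start_month = float(start_month)
        self.end_month = float(end_month)
        # cache blended cumulative hazard over [start, end]
        n = max(2, int(np.ceil((end_month - start_month) / self._GRID_STEP)) + 1)
        grid = np.linspace(start_month, end_month, n)
        w = (grid - start_month) / (end_month - start_month)
        h = (1.0 - w) * self.intervention.hazard(grid) + w * self.control.hazard(grid)
        ch = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (h[:-1] + h[1:]) / 2.0)])
        self._grid = grid
        self._blend_cumhaz = ch

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        T0, T1 = self.start_month, self.end_month
        base = self.intervention.cumulative_hazard(np.minimum(t, T0))
        blend = np.interp(np.clip(t, T0, T1), self._grid, self._blend_cumhaz)
        tail = np.where(
            t > T1,
            self.control.cumulative_hazard(np.maximum(t, T1))
            - self.control.cumulative_hazard(T1),
            0.0,
        )
        out = base + blend + tail
        return out if out.ndim else float(out)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        w = np.clip((t - self.start_month) / (self.end_month - self.start_month), 0.0, 1.0)
        out = (1.0 - w) * self.intervention.hazard(t) + w * self.control.hazard(t)
        return out if out.ndim else float(out)

    def survival(self, t):
        out = np.exp(-np.asarray(self.cumulative_hazard(t), dtype=float))
        return out if out.ndim else float(out)
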