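"""Three-state monthly Markov cohort engine.

States: alive free of heart-failure hospitalisation (HFH), alive with HFH
(a one-cycle state: a hospitalised patient returns to the stable state the
next cycle), and dead.  The engine takes an overall-survival model (any
object with a ``survival(t)`` method on the monthly time scale) and a
sequence of per-patient new-hospitalisation increments, builds a per-cycle
trace, and accrues discounted and undiscounted life-years, QALYs and costs.

Accrual convention: state occupancy and discounting are evaluated at cycle
midpoints (t + 0.5 months); upfront items (device + index stay) fall at
t = 0 undiscounted.  There is no additional half-cycle correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "EconParams",
    "CohortTrace",
    "ArmOutcome",
    "CEResult",
    "discount_factor",
    "build_trace",
    "accrue_outcomes",
    "run_arm",
    "compare",
    "life_expectancy",
]


@dataclass(frozen=True)
class EconParams:
    """Cost, utility and run-length settings (EUR, French health-system view).

    Defaults are the base-case inputs: device and index-stay reimbursement,
    per-event hospitalisation tariff, monthly medical therapy and GP visit,
    twice-yearly cardiologist visit (spread as 50/12 EUR per month), utility
    0.6575 for stable disease with a 0.1063 annual disutility while
    hospitalised, 2.5 % annual discounting, 360 monthly cycles (30 years).
    """

    cost_device: float = 21_100.00
    cost_index_stay: float = 5_398.00
    cost_hfh: float = 3_462.80
    cost_med_monthly: float = 23.89
    cost_gp_monthly: float = 25.00
    cost_cardio_per_visit: float = 25.00  # twice yearly
    u_stable: float = 0.6575
    disutility_hfh: float = 0.1063  # per year hospitalised, subtracted
    discount_annual: float = 0.025
    horizon_months: int = 360
    cycle_months: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "cost_device",
            "cost_index_stay",
            "cost_hfh",
            "cost_med_monthly",
            "cost_gp_monthly",
            "cost_cardio_per_visit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.u_stable <= 1.0:
            raise ValueError("u_stable must lie in [0, 1]")
        if not 0.0 <= self.u_stable - self.disutility_hfh <= 1.0:
            raise ValueError("u_stable - disutility_hfh must lie in [0, 1]")
        if self.discount_annual < 0:
            raise ValueError("discount_annual must be >= 0")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")

    @property
    def routine_monthly_cost(self) -> float:
        """Routine care per alive patient-month: therapy + GP + cardiologist."""
        return (
            self.cost_med_monthly
            + self.cost_gp_monthly
            + 2.0 * self.cost_cardio_per_visit / 12.0
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kw) -> "EconParams":
        return replace(self, **kw)


def discount_factor(annual_rate: float, t_months) -> np.ndarray | float:
    """Discount factor ``(1 + rate) ** (-t / 12)`` at time ``t`` in months."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    out = (1.0 + annual_rate) ** (-t / 12.0)
    return out if out.ndim else float(out)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy at cycle midpoints.

    ``new_hosp`` is the expected number of new hospitalisations per patient
    in each cycle; ``hospitalised`` is the fraction of the cohort occupying
    the (one-cycle) hospitalised state.
    """

    midpoints: np.ndarray  # t + 0.5, months
    survival: np.ndarray
    new_hosp: np.ndarray
    stable: np.ndarray
    hospitalised: np.ndarray
    dead: np.ndarray
    discount: np.ndarray

    def occupancy_sums(self) -> np.ndarray:
        return self.stable + self.hospitalised + self.dead


def build_trace(os_model, increments, econ: EconParams) -> CohortTrace:
    """Build a cohort trace from a survival model and hospitalisation increments.

    ``increments`` must have one per-patient new-hospitalisation count per
    cycle (length = horizon).  Increments exceeding the surviving fraction
    are clamped to it (with a warning): a cohort cannot hospitalise more
    patients than are alive.
    """
    increments = np.asarray(increments, dtype=float)
    horizon = econ.horizon_months
    if increments.shape != (horizon,):
        raise ValueError(
            f"increments must have length {horizon}, got {increments.shape}"
        )
    mid = np.arange(horizon, dtype=float) + 0.5
    surv = np.asarray(os_model.survival(mid), dtype=float)
    if np.any(increments > surv + 1e-12):
        warnings.warn(
            "hospitalisation increments exceed survival in some cycles; clamped",
            stacklevel=2,
        )
    hosp = np.minimum(increments, surv)
    stable = surv - hosp
    dead = 1.0 - surv
    disc = discount_factor(econ.discount_annual, mid)
    return CohortTrace(
        midpoints=mid,
        survival=surv,
        new_hosp=increments,
        stable=stable,
        hospitalised=hosp,
        dead=dead,
        discount=np.asarray(disc, dtype=float),
    )


@dataclass
class ArmOutcome:
    """Per-arm accrued outcomes, discounted and undiscounted."""

    ly: float
    qaly: float
    cost: float
    ly_undisc: float
    qaly_undisc: float
    cost_undisc: float
    cost_upfront: float = 0.0
    cost_routine: float = 0.0
    cost_hosp: float = 0.0
    hosp_lifetime_cohort: float = float("nan")  # cohort count over the horizon
    hosp_24m_cohort: float = float("nan")  # cohort count within 24 months


def accrue_outcomes(trace: CohortTrace, econ: EconParams, upfront: bool) -> ArmOutcome:
    """Accrue (un)discounted life-years, QALYs and costs over a trace.

    Per cycle: LY += S/12 * D; QALY += (S*u_stable - new_hosp*disutility)/12 * D;
    cost += (S*routine_monthly + new_hosp*cost_hfh) * D.  With ``upfront``,
    device + index-stay costs are added at t=0 undiscounted.
    """
    S = trace.survival
    h = trace.new_hosp
    D = trace.discount
    ly_cycles = S / 12.0
    qaly_cycles = (S * econ.u_stable - h * econ.disutility_hfh) / 12.0
    routine_cycles = S * econ.routine_monthly_cost
    hosp_cycles = h * econ.cost_hfh

    up = econ.cost_device + econ.cost_index_stay if upfront else 0.0
    return ArmOutcome(
        ly=float(np.sum(ly_cycles * D)),
        qaly=float(np.sum(qaly_cycles * D)),
        cost=float(np.sum((routine_cycles + hosp_cycles) * D) + up),
        ly_undisc=float(np.sum(ly_cycles)),
        qaly_undisc=float(np.sum(qaly_cycles)),
        cost_undisc=float(np.sum(routine_cycles + hosp_cycles) + up),
        cost_upfront=up,
        cost_routine=float(np.sum(routine_cycles * D)),
        cost_hosp=float(np.sum(hosp_cycles * D)),
    )


def run_arm(os_model, hfh_model, econ: EconParams, upfront: bool) -> ArmOutcome:
    """Build the trace for one arm and accrue its outcomes.

    ``hfh_model`` is any object exposing ``per_cycle_increments(horizon)``
    (per-patient) and, optionally, ``arm_size`` and ``cumulative_events(t)``
    for cohort hospitalisation totals.
    """
    horizon = econ.horizon_months
    increments = np.asarray(hfh_model.per_cycle_increments(horizon), dtype=float)
    trace = build_trace(os_model, increments, econ)
    out = accrue_outcomes(trace, econ, upfront)
    arm_size = getattr(hfh_model, "arm_size", None)
    if arm_size:
        out.hosp_lifetime_cohort = float(np.sum(increments) * arm_size)
        n24 = min(24, horizon)
        out.hosp_24m_cohort = float(np.sum(increments[:n24]) * arm_size)
    return out


@dataclass
class CEResult:
    """Incremental comparison (intervention minus control)."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    status: str  # "icer" | "dominant" | "dominated" | "indifferent" | "infinite"
    delta_cost_undisc: float = float("nan")
    delta_qaly_undisc: float = float("nan")
    delta_ly_undisc: float = float("nan")
    icer_undisc: float | None = None


def _icer_status(delta_cost: float, delta_qaly: float, tol: float = 1e-12):
    if abs(delta_cost) < tol and abs(delta_qaly) < tol:
        return None, "indifferent"
    if delta_cost < 0 and delta_qaly >= 0:
        return None, "dominant"
    if delta_qaly < 0 and delta_cost >= 0:
        return None, "dominated"
    if abs(delta_qaly) < tol:
        return None, "infinite" if delta_cost > 0 else "dominant"
    return delta_cost / delta_qaly, "icer"


def compare(intervention: ArmOutcome, control: ArmOutcome) -> CEResult:
    """Incremental cost, QALY, LY and the ICER (EUR per QALY gained)."""
    dc = intervention.cost - control.cost
    dq = intervention.qaly - control.qaly
    dly = intervention.ly - control.ly
    icer, status = _icer_status(dc, dq)
    dc_u = intervention.cost_undisc - control.cost_undisc
    dq_u = intervention.qaly_undisc - control.qaly_undisc
    icer_u, _ = _icer_status(dc_u, dq_u)
    return CEResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        icer=icer,
        status=status,
        delta_cost_undisc=dc_u,
        delta_qaly_undisc=dq_u,
        delta_ly_undisc=intervention.ly_undisc - control.ly_undisc,
        icer_undisc=icer_u,
    )


def life_expectancy(
    os_model,
    horizon_months: int = 360,
    annual_discount: float = 0.0,
) -> float:
    """(Dis)counted life expectancy (years) over the horizon, midpoint accrual."""
    mid = np.arange(horizon_months, dtype=float) + 0.5
    surv = np.asarray(os_model.survival(mid), dtype=float)
    disc = discount_factor(annual_discount, mid)
    return float(np.sum(surv * disc) / 12.0)
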