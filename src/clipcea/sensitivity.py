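"""Deterministic and probabilistic sensitivity analyses.

One-way deterministic analysis (tornado), the multivariate scenario grid
("up to 64 pairs" of cost/QALY per arm), a scenario-level bootstrap over
those pairs (one pair per arm drawn uniformly with replacement per
iteration), the cost-effectiveness plane with its 95 % confidence ellipse,
the cost-effectiveness acceptability curve (CEAC), quadrant shares, and the
treatment-effect curtailment and waning scenario transforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EconParams, run_arm, compare
from .hfh import FixedIncrements
from .survival import apply_hazard_ratio, CurtailedSurvival, WanedSurvival

__all__ = [
    "ArmModels",
    "ModelInputs",
    "Variation",
    "run_comparison",
    "one_way_dsa",
    "scenario_grid",
    "bootstrap_ce",
    "ceac",
    "confidence_ellipse",
    "quadrant_shares",
    "curtail_effect",
    "wane_effect",
    "standard_grid_factors",
    "run_psa",
    "Factor",
    "BootstrapReplicates",
]


@dataclass(frozen=True)
class ArmModels:
    """One arm's model inputs: survival, hospitalisation, upfront costs."""

    os: object  # anything with .survival(t)
    hfh: object  # anything with .per_cycle_increments(horizon)
    upfront: bool = False
    label: str = ""


@dataclass(frozen=True)
class ModelInputs:
    """A full two-arm comparison specification."""

    intervention: ArmModels
    control: ArmModels
    econ: EconParams = field(default_factory=EconParams)
    label: str = ""


def run_comparison(inputs: ModelInputs):
    """Run both arms through the engine; returns (CEResult, out_i, out_c)."""
    out_i = run_arm(inputs.intervention.os, inputs.intervention.hfh,
                    inputs.econ, inputs.intervention.upfront)
    out_c = run_arm(inputs.control.os, inputs.control.hfh,
                    inputs.econ, inputs.control.upfront)
    return compare(out_i, out_c), out_i, out_c


@dataclass(frozen=True)
class Variation:
    """A single input variation.

    ``target``: "econ" (field of EconParams), "os_hr" (hazard ratio on the
    arm's survival), or "hfh_scale" (multiplier on the arm's monthly
    hospitalisation increments, i.e. on the plateau).
    ``arm``: "intervention", "control" or "both" (ignored for econ).
    ``kind``: "multiplier" or "override" (econ only).
    """

    target: str
    value: float
    field: str = ""
    arm: str = "both"
    kind: str = "multiplier"
    label: str = ""

    def describe(self) -> str:
        if self.label:
            return self.label
        if self.target == "econ":
            return f"{self.field} {self.kind} {self.value}"
        return f"{self.target}[{self.arm}] x{self.value}"


def _scale_hfh(hfh, factor: float):
    """Multiply an arm's hospitalisation increments by a factor."""
    if hasattr(hfh, "max_events"):
        return replace(hfh, max_events=hfh.max_events * factor)
    if isinstance(hfh, FixedIncrements):
        return FixedIncrements(hfh.increments * factor, hfh.arm_size)
    raise TypeError(f"cannot scale hospitalisations on {type(hfh).__name__}")


def _apply_to_arm(arm: ArmModels, var: Variation) -> ArmModels:
    if var.target == "os_hr":
        return replace(arm, os=apply_hazard_ratio(arm.os, var.value))
    if var.target == "hfh_scale":
        return replace(arm, hfh=_scale_hfh(arm.hfh, var.value))
    raise ValueError(f"unknown arm-level target {var.target!r}")


def apply_variations(inputs: ModelInputs, variations) -> ModelInputs:
    """Return a copy of the inputs with each variation applied in order."""
    out = inputs
    for var in variations:
        if var.target == "econ":
            base = getattr(out.econ, var.field)
            new = var.value if var.kind == "override" else base * var.value
            out = replace(out, econ=out.econ.with_(**{var.field: new}))
        else:
            if var.arm in ("intervention", "both"):
                out = replace(out, intervention=_apply_to_arm(out.intervention, var))
            if var.arm in ("control", "both"):
                out = replace(out, control=_apply_to_arm(out.control, var))
    return out


def one_way_dsa(inputs: ModelInputs, scenarios) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    ``scenarios`` is a list of (name, low_variations, high_variations); each
    side re-runs the full model with exactly that input varied.  Rows are
    sorted by the width of the ICER range; undefined ICERs (dominance)
    appear as NaN with the status recorded in the flags column.
    """
    base, _, _ = run_comparison(inputs)
    rows = []
    for name, low, high in scenarios:
        res_lo, _, _ = run_comparison(apply_variations(inputs, low))
        res_hi, _, _ = run_comparison(apply_variations(inputs, high))
        icer_lo = res_lo.icer if res_lo.icer is not None else np.nan
        icer_hi = res_hi.icer if res_hi.icer is not None else np.nan
        width = (
            abs(icer_hi - icer_lo)
            if np.isfinite(icer_lo) and np.isfinite(icer_hi)
            else np.inf
        )
        rows.append(
            {
                "scenario": name,
                "low_icer": icer_lo,
                "high_icer": icer_hi,
                "range": width,
                "flags": f"{res_lo.status}/{res_hi.status}",
            }
        )
    df = pd.DataFrame(rows).sort_values("range", ascending=False, kind="stable")
    df.attrs["base_icer"] = base.icer
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class Factor:
    """One grid factor: a named list of variation levels.

    ``shared`` marks model-level parameters (utility weights, tariffs, the
    direction of the survival-CI variation) whose drawn level must be common
    to both arms in the stratified bootstrap; arm-specific factors (device
    cost, an arm's own hospitalisation increments) are not shared.
    Each level is a tuple of Variations applied together.
    """

    name: str
    levels: tuple
    shared: bool = False


def scenario_grid(arm: ArmModels, econ: EconParams, factors) -> pd.DataFrame:
    """Run one arm under the Cartesian product of variation factors.

    ``factors`` is a list of :class:`Factor`; every combination of levels is
    run through the engine and its (cost, QALY) pair recorded, along with
    one ``level_<name>`` column per factor.  With k binary factors this
    yields 2**k pairs for the arm.
    """
    factors = [
        f if isinstance(f, Factor) else Factor(name=f"f{i}", levels=tuple(f))
        for i, f in enumerate(factors)
    ]
    if any(len(f.levels) == 0 for f in factors):
        raise ValueError("every factor needs at least one level")
    rows = []
    for combo in itertools.product(*(range(len(f.levels)) for f in factors)):
        variations = []
        for f, li in zip(factors, combo):
            level = f.levels[li]
            variations.extend(level if isinstance(level, (tuple, list)) else [level])
        inputs = ModelInputs(intervention=arm, control=arm, econ=econ)
        varied = apply_variations(inputs, variations)
        out = run_arm(varied.intervention.os, varied.intervention.hfh,
                      varied.econ, varied.intervention.upfront)
        row = {
            "cost": out.cost,
            "qaly": out.qaly,
            "ly": out.ly,
            "settings": " | ".join(v.describe() for v in variations) or "base",
        }
        for f, li in zip(factors, combo):
            row[f"level_{f.name}"] = li
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["shared_factors"] = [f.name for f in factors if f.shared]
    return df


@dataclass
class BootstrapReplicates:
    """Joint replicates of (incremental cost, incremental QALY)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly})


def bootstrap_ce(pairs_intervention: pd.DataFrame, pairs_control: pd.DataFrame,
                 n_iter: int = 500, seed: int = 0,
                 shared_factors=None) -> BootstrapReplicates:
    """Scenario-level bootstrap of incremental cost and QALY.

    Each iteration draws one (cost, QALY) pair per arm uniformly with
    replacement and records the differences.  Without ``shared_factors`` the
    two arms are drawn independently.  With ``shared_factors`` (a list of
    factor names common to both grids) the draw is stratified: the
    intervention pair is drawn uniformly, then the control pair uniformly
    among the control rows whose shared-factor levels match — model-level
    parameters (utility weights, tariffs, the survival-CI direction) then
    take the same value in both arms of a replicate, as a single cohort
    model requires, while arm-specific factors stay independent.
    """
    if len(pairs_intervention) == 0 or len(pairs_control) == 0:
        raise ValueError("pair lists must be non-empty")
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, len(pairs_intervention), size=n_iter)
    if shared_factors:
        cols = [f"level_{name}" for name in shared_factors]
        for col in cols:
            if col not in pairs_intervention or col not in pairs_control:
                raise ValueError(f"both grids must carry column {col!r}")
        groups = {
            key: idx.to_numpy()
            for key, idx in pairs_control.groupby(cols, sort=False).groups.items()
        }
        keys_i = list(pairs_intervention[cols].itertuples(index=False, name=None))
        keys_i = [k if len(cols) > 1 else k[0] for k in keys_i]
        ic = np.empty(n_iter, dtype=int)
        for j, i_row in enumerate(ii):
            pool = groups[keys_i[i_row]]
            ic[j] = pool[rng.integers(0, len(pool))]
    else:
        ic = rng.integers(0, len(pairs_control), size=n_iter)
    ci = pairs_intervention["cost"].to_numpy()[ii]
    qi = pairs_intervention["qaly"].to_numpy()[ii]
    cc = pairs_control["cost"].to_numpy()[ic]
    qc = pairs_control["qaly"].to_numpy()[ic]
    return BootstrapReplicates(
        delta_cost=ci - cc, delta_qaly=qi - qc, seed=seed, n_iter=n_iter
    )


def ceac(replicates: BootstrapReplicates, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay w, the probability is the fraction of
    replicates with positive net monetary benefit w * dQALY - dCost.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(wtp) < 0):
        raise ValueError("wtp_grid must be ascending")
    nmb = wtp[:, None] * replicates.delta_qaly[None, :] - replicates.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "probability": prob})


@dataclass
class Ellipse:
    center: np.ndarray
    radii: np.ndarray  # semi-axes
    axes: np.ndarray  # columns are the axis directions
    level: float
    degenerate: bool = False


def confidence_ellipse(replicates: BootstrapReplicates, level: float = 0.95) -> Ellipse:
    """Normal-theory confidence ellipse of the replicate cloud.

    Built from the sample mean and covariance at the chi-square(2) quantile
    of the requested level; identical replicates yield a degenerate flag.
    """
    x = np.column_stack([replicates.delta_cost, replicates.delta_qaly])
    if len(x) < 3:
        raise ValueError("need at least 3 replicates")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    degenerate = bool(np.min(evals) <= 1e-300)
    radii = np.sqrt(np.maximum(evals, 0.0) * q)
    return Ellipse(center=mean, radii=radii, axes=evecs, level=level,
                   degenerate=degenerate)


def quadrant_shares(replicates: BootstrapReplicates) -> dict:
    """Fractions of replicates in each cost-effectiveness-plane quadrant.

    NE: dCost > 0, dQALY > 0; NW: dCost > 0, dQALY < 0; SW: both < 0;
    SE: dCost < 0, dQALY > 0.  Exact zeros count to the positive side.
    """
    dc = replicates.delta_cost >= 0
    dq = replicates.delta_qaly >= 0
    n = len(replicates.delta_cost)
    return {
        "NE": float(np.sum(dc & dq)) / n,
        "NW": float(np.sum(dc & ~dq)) / n,
        "SW": float(np.sum(~dc & ~dq)) / n,
        "SE": float(np.sum(~dc & dq)) / n,
    }


def standard_grid_factors(arm: str, cost_variation: float = 0.20,
                          hosp_variation: float = 0.20,
                          utility_variation: float = 0.10,
                          os_hazard_variation: float = 0.20,
                          os_mode: str = "per_arm_ci",
                          os_hazard_multipliers: tuple | None = None):
    """Binary variation factors for one arm of the multivariate grid.

    Per arm: the device cost (intervention arm only) and the
    hospitalisation tariff +/- ``cost_variation``; the arm's monthly
    hospitalisation increments +/- ``hosp_variation``; the stable-state
    utility +/- ``utility_variation``; and a survival factor whose form
    depends on ``os_mode``:

    * ``"per_arm_ci"`` — each arm's own monthly hazard multiplied by the
      two ``os_hazard_multipliers`` (default ``1 -/+ os_hazard_variation``,
      a stand-in for the arms' fitted 95 % CIs; pass published
      equivalent-hazard-ratio bounds such as ``(0.76, 1.31)`` where they
      exist).  The *direction* of this variation is a shared factor, so a
      stratified bootstrap moves both arms to their lower or upper CI
      together — survival uncertainty shifts the cohort, it does not
      manufacture a treatment effect;
    * ``"hr_on_intervention"`` — the intervention arm's hazard multiplied
      by each of ``os_hazard_multipliers`` with the control arm's survival
      left at base (a one-sided effect-uncertainty factor).

    The hospitalisation tariff and the utility are model-level (shared)
    factors; device cost and each arm's hospitalisation increments are
    arm-specific.
    """
    if arm not in ("intervention", "control"):
        raise ValueError("arm must be 'intervention' or 'control'")
    lo, hi = 1.0 - cost_variation, 1.0 + cost_variation
    factors = []
    if arm == "intervention":
        factors.append(Factor("device_cost", (
            Variation("econ", lo, field="cost_device", label=f"device x{lo}"),
            Variation("econ", hi, field="cost_device", label=f"device x{hi}"),
        )))
    factors.append(Factor("hfh_cost", (
        Variation("econ", lo, field="cost_hfh", label=f"hfh cost x{lo}"),
        Variation("econ", hi, field="cost_hfh", label=f"hfh cost x{hi}"),
    ), shared=True))
    factors.append(Factor("hosp", (
        Variation("hfh_scale", 1.0 - hosp_variation, arm="both",
                  label=f"hosp x{1.0 - hosp_variation}"),
        Variation("hfh_scale", 1.0 + hosp_variation, arm="both",
                  label=f"hosp x{1.0 + hosp_variation}"),
    )))
    factors.append(Factor("utility", (
        Variation("econ", 1.0 - utility_variation, field="u_stable",
                  label=f"utility x{1.0 - utility_variation}"),
        Variation("econ", 1.0 + utility_variation, field="u_stable",
                  label=f"utility x{1.0 + utility_variation}"),
    ), shared=True))
    if os_hazard_multipliers is None:
        os_hazard_multipliers = (1.0 - os_hazard_variation, 1.0 + os_hazard_variation)
    if os_mode == "per_arm_ci":
        factors.append(Factor("os_ci", tuple(
            Variation("os_hr", m, arm="both", label=f"os hazard x{m}")
            for m in os_hazard_multipliers
        ), shared=True))
    elif os_mode == "hr_on_intervention":
        if arm == "intervention":
            factors.append(Factor("os_hr", tuple(
                Variation("os_hr", m, arm="both", label=f"os HR {m}")
                for m in os_hazard_multipliers
            )))
    else:
        raise ValueError(f"unknown os_mode {os_mode!r}")
    return factors


def run_psa(inputs: ModelInputs, n_iter: int = 500, seed: int = 0,
            wtp_grid=None, stratify_shared: bool = True, **variation_kw):
    """Scenario-grid bootstrap PSA: grids, replicates, CEAC.

    Builds the per-arm standard grids, runs every scenario through the
    engine, bootstraps ``n_iter`` (cost, QALY) pair draws (stratified so
    model-level factors take a common level in both arms, unless
    ``stratify_shared`` is False), and evaluates the CEAC on ``wtp_grid``
    (default 0..100,000 EUR/QALY in 1,000 steps).
    Returns (replicates, ceac table, grid_intervention, grid_control).

    For the comparison anchored on the published equivalent hazard-ratio
    bounds pass ``os_mode="hr_on_intervention"``: the survival factor then
    lives in the intervention grid only and the control arm's survival is
    not varied.
    """
    factors_i = standard_grid_factors("intervention", **variation_kw)
    factors_c = standard_grid_factors("control", **variation_kw)
    grid_i = scenario_grid(inputs.intervention, inputs.econ, factors_i)
    grid_c = scenario_grid(inputs.control, inputs.econ, factors_c)
    shared = None
    if stratify_shared:
        shared = [n for n in grid_i.attrs["shared_factors"]
                  if n in grid_c.attrs["shared_factors"]]
    reps = bootstrap_ce(grid_i, grid_c, n_iter=n_iter, seed=seed,
                        shared_factors=shared or None)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100_001.0, 1_000.0)
    curve = ceac(reps, wtp_grid)
    return reps, curve, grid_i, grid_c


def _blend_increments(inc_i: np.ndarray, inc_c: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return (1.0 - weights) * inc_i + weights * inc_c


def curtail_effect(inputs: ModelInputs, stop_year: float) -> ModelInputs:
    """Curtail the treatment effect after ``stop_year`` years.

    From month 12 * stop_year on, the intervention arm's death hazard and
    monthly hospitalisation increments revert to the control arm's values;
    before that they are unchanged.  ``stop_year`` must be at least 2 (the
    within-trial window).
    """
    if stop_year < 2:
        raise ValueError("stop_year must be >= 2 (the observed trial window)")
    T = 12.0 * stop_year
    horizon = inputs.econ.horizon_months
    os_mod = CurtailedSurvival(inputs.intervention.os, inputs.control.os, T)
    inc_i = np.asarray(inputs.intervention.hfh.per_cycle_increments(horizon), float)
    inc_c = np.asarray(inputs.control.hfh.per_cycle_increments(horizon), float)
    w = (np.arange(horizon) >= T).astype(float)  # cycle t covers [t, t+1)
    arm_size = getattr(inputs.intervention.hfh, "arm_size", 1)
    hfh = FixedIncrements(_blend_increments(inc_i, inc_c, w), arm_size)
    return replace(inputs, intervention=replace(inputs.intervention, os=os_mod, hfh=hfh))


def wane_effect(inputs: ModelInputs, end_year: float, start_year: float = 2.0) -> ModelInputs:
    """Wane the treatment effect linearly between two time points.

    The intervention arm's hazard (and monthly hospitalisation increments)
    interpolate linearly from their own values at month 12 * start_year to
    the control arm's values at month 12 * end_year, and equal the
    control's thereafter.
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    T0, T1 = 12.0 * start_year, 12.0 * end_year
    horizon = inputs.econ.horizon_months
    os_mod = WanedSurvival(inputs.intervention.os, inputs.control.os, T0, T1)
    inc_i = np.asarray(inputs.intervention.hfh.per_cycle_increments(horizon), float)
    inc_c = np.asarray(inputs.control.hfh.per_cycle_increments(horizon), float)
    mid = np.arange(horizon) + 0.5
    w = np.clip((mid - T0) / (T1 - T0), 0.0, 1.0)
    arm_size = getattr(inputs.intervention.hfh, "arm_size", 1)
    hfh = FixedIncrements(_blend_increments(inc_i, inc_c, w), arm_size)
    return replace(inputs, intervention=replace(inputs.intervention, os=os_mod, hfh=hfh))
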