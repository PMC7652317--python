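"""Parametric survival fitting, hazard ratios and life-expectancy calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from clipcea.engine import life_expectancy
from clipcea.survival import (
    FAMILIES,
    SurvModel,
    apply_hazard_ratio,
    calibrate_exponential_to_life_expectancy,
    fit_parametric,
    rank_models,
    survival_at,
)
from clipcea.synthetic import OSTruth, TrialSpec, simulate_ipd


def _sim(family="exponential", n=1000, seed=0, censor=0.005, follow_up=120, **truth_kw):
    truth = OSTruth(family=family, **truth_kw) if truth_kw else OSTruth()
    spec = TrialSpec(
        arm_sizes={"intervention": n, "control": 10},
        os_truth={"intervention": truth, "control": OSTruth()},
        censor_rate=censor,
        follow_up_months=follow_up,
        seed=seed,
    )
    return simulate_ipd(spec, "intervention")


class TestFit:
    def test_exponential_mle_is_events_over_time(self):
        ipd = pd.DataFrame({"time_months": [2.0, 4.0, 6.0, 8.0], "event": [1, 1, 1, 0]})
        m = fit_parametric(ipd, "exponential")
        assert m.params[0] == pytest.approx(3 / 20.0)
        assert m.aic == pytest.approx(2 - 2 * m.loglik)

    def test_exponential_parameter_recovery_within_2_se(self):
        lam = 0.019
        ipd = _sim(rate=lam, n=1000, seed=7)
        m = fit_parametric(ipd, "exponential")
        se = m.params[0] / np.sqrt(ipd.event.sum())
        assert abs(m.params[0] - lam) < 2 * se

    def test_weibull_with_unit_shape_matches_exponential_loglik(self):
        ipd = _sim(n=400, seed=1)
        exp_fit = fit_parametric(ipd, "exponential")
        # Weibull at (scale = 1/lambda, shape = 1) nests the exponential
        wei = SurvModel("weibull", (1 / exp_fit.params[0], 1.0))
        t = np.asarray(ipd.time_months)
        e = np.asarray(ipd.event)
        from clipcea.survival import _log_pdf, _log_sf

        ll = np.where(
            e == 1,
            _log_pdf("weibull", t, wei.params),
            _log_sf("weibull", t, wei.params),
        ).sum()
        assert ll == pytest.approx(exp_fit.loglik, abs=1e-6)

    @pytest.mark.parametrize(
        "family", ["exponential", "weibull", "loglogistic", "lognormal"]
    )
    def test_fitted_loglik_matches_lifelines(self, family):
        """Cross-check the MLE against the independent lifelines fit
        (every family lifelines implements; it has no Gompertz fitter)."""
        import lifelines

        fitters = {
            "exponential": lifelines.ExponentialFitter,
            "weibull": lifelines.WeibullFitter,
            "loglogistic": lifelines.LogLogisticFitter,
            "lognormal": lifelines.LogNormalFitter,
        }
        ipd = _sim(n=500, seed=3)
        mine = fit_parametric(ipd, family)
        theirs = fitters[family]().fit(ipd.time_months, ipd.event)
        assert mine.loglik == pytest.approx(theirs.log_likelihood_, rel=1e-5)

    def test_zero_events_rejected(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            fit_parametric(ipd, "exponential")

    def test_unknown_family_rejected(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            fit_parametric(ipd, "gamma")


class TestSurvivalAt:
    def test_survival_at_zero_is_one(self):
        for family, params in [
            ("exponential", (0.02,)),
            ("weibull", (30.0, 1.3)),
            ("gompertz", (0.01, 0.02)),
            ("loglogistic", (30.0, 1.5)),
            ("lognormal", (30.0, 1.0)),
        ]:
            m = SurvModel(family, params, hr=1.7)
            assert survival_at(m, 0.0) == pytest.approx(1.0)

    def test_exponential_median_closed_form(self):
        m = SurvModel("exponential", (0.02,))
        assert survival_at(m, np.log(2) / 0.02) == pytest.approx(0.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(SurvModel("exponential", (0.02,)), -1.0)

    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.02,)),
        ("weibull", (30.0, 1.3)),
        ("gompertz", (0.01, 0.02)),
        ("loglogistic", (30.0, 1.5)),
        ("lognormal", (30.0, 1.0)),
    ])
    def test_survival_monotone_non_increasing(self, family, params):
        m = SurvModel(family, params)
        t = np.linspace(0, 360, 500)
        s = m.survival(t)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))


class TestHazardRatio:
    def test_hr_one_is_identity(self):
        m = SurvModel("loglogistic", (30.0, 1.5))
        t = np.linspace(0, 120, 50)
        assert np.allclose(apply_hazard_ratio(m, 1.0).survival(t), m.survival(t))

    def test_exponential_hr_rescales_rate(self):
        m = SurvModel("exponential", (0.02,))
        scaled = SurvModel("exponential", (0.76 * 0.02,))
        t = np.linspace(0, 240, 100)
        assert np.allclose(apply_hazard_ratio(m, 0.76).survival(t), scaled.survival(t))

    @pytest.mark.parametrize("family,params", [
        ("weibull", (30.0, 1.3)),
        ("loglogistic", (30.0, 1.5)),
        ("lognormal", (30.0, 1.0)),
    ])
    def test_power_rule_pointwise(self, family, params):
        m = SurvModel(family, params)
        t = np.linspace(0, 120, 60)
        assert np.allclose(
            apply_hazard_ratio(m, 0.62).survival(t), m.survival(t) ** 0.62
        )

    def test_composition_is_multiplicative(self):
        m = SurvModel("weibull", (30.0, 1.3))
        a = apply_hazard_ratio(apply_hazard_ratio(m, 0.8), 1.5)
        b = apply_hazard_ratio(m, 0.8 * 1.5)
        t = np.linspace(0, 120, 60)
        assert np.allclose(a.survival(t), b.survival(t))

    def test_non_positive_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(SurvModel("exponential", (0.02,)), 0.0)


class TestRanking:
    def test_single_fit_ranks_itself(self):
        m = SurvModel("exponential", (0.02,), loglik=-10.0, aic=22.0)
        table = rank_models([m])
        assert list(table.family) == ["exponential"]

    def test_true_family_competitive_on_large_sample(self):
        ipd = _sim(n=2000, seed=11, censor=0.0, follow_up=360)
        fits = [fit_parametric(ipd, f) for f in FAMILIES]
        table = rank_models(fits)
        exp_aic = table.loc[table.family == "exponential", "aic"].iloc[0]
        assert exp_aic - table.aic.min() <= 2.0

    def test_true_family_wins_by_aic_across_replicates(self):
        """On large samples (n = 5000) the generating family is within 2 AIC
        of the best fit in at least 80% of 20 seeded replicates."""
        wins = 0
        for seed in range(20):
            spec = TrialSpec(
                arm_sizes={"intervention": 5000, "control": 10},
                os_truth={"intervention": OSTruth(rate=0.02), "control": OSTruth()},
                censor_rate=0.005,
                follow_up_months=60,
                seed=seed,
            )
            ipd = simulate_ipd(spec, "intervention")
            fits = [fit_parametric(ipd, f) for f in FAMILIES]
            table = rank_models(fits)
            exp_aic = table.loc[table.family == "exponential", "aic"].iloc[0]
            wins += exp_aic <= table.aic.min() + 2.0
        assert wins >= 16

    def test_ordering_is_permutation_sorted_by_aic(self):
        ipd = _sim(n=300, seed=2)
        fits = [fit_parametric(ipd, f) for f in ("exponential", "weibull", "lognormal")]
        table = rank_models(fits)
        assert sorted(table.family) == sorted(["exponential", "weibull", "lognormal"])
        assert np.all(np.diff(table.aic) >= 0)


class TestCalibration:
    def test_hazard_matches_closed_form_restricted_mean(self):
        # independent oracle: solve (1 - exp(-360 lam)) / (12 lam) = 4.38
        target = 4.38
        f = lambda lam: (1 - np.exp(-360 * lam)) / (12 * lam) - target
        lam_oracle = optimize.brentq(f, 1e-6, 1.0, xtol=1e-14)
        m = calibrate_exponential_to_life_expectancy(target, 360, 0.0)
        # engine uses the midpoint rule, so agreement is to discretisation error
        assert m.params[0] == pytest.approx(lam_oracle, abs=1e-4)
        assert m.params[0] == pytest.approx(0.019, abs=5e-4)

    def test_calibrated_model_is_a_fixed_point_of_the_engine(self):
        m = calibrate_exponential_to_life_expectancy(3.38, 360, 0.0)
        assert life_expectancy(m, 360, 0.0) == pytest.approx(3.38, abs=1e-6)
        md = calibrate_exponential_to_life_expectancy(4.93, 360, 0.025)
        assert life_expectancy(md, 360, 0.025) == pytest.approx(4.93, abs=1e-6)

    def test_small_hazard_approaches_horizon_limit(self):
        # as lambda -> 0 the attainable LE tends to horizon/12; just inside works
        m = calibrate_exponential_to_life_expectancy(29.0, 360, 0.0)
        assert m.params[0] < 0.001

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_exponential_to_life_expectancy(30.0, 360, 0.0)
        with pytest.raises(ValueError):
            calibrate_exponential_to_life_expectancy(-1.0, 360, 0.0)
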