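"""Tornado, scenario grid, bootstrap, CEAC, ellipse, effect curtailment/waning."""

import numpy as np
import pandas as pd
import pytest

from clipcea.engine import EconParams
from clipcea.sensitivity import (
    BootstrapReplicates,
    Factor,
    Variation,
    apply_variations,
    bootstrap_ce,
    ceac,
    confidence_ellipse,
    curtail_effect,
    one_way_dsa,
    quadrant_shares,
    run_comparison,
    scenario_grid,
    standard_grid_factors,
    wane_effect,
)


class TestOneWayDSA:
    def test_device_cost_up_20pc_raises_cost_by_4220(self, mitra_inputs):
        base, base_i, base_c = run_comparison(mitra_inputs)
        varied = apply_variations(
            mitra_inputs, [Variation("econ", 1.2, field="cost_device")]
        )
        res, out_i, out_c = run_comparison(varied)
        assert res.delta_cost - base.delta_cost == pytest.approx(0.2 * 21_100.0)

    def test_null_variation_reproduces_base_icer(self, mitra_inputs):
        base, _, _ = run_comparison(mitra_inputs)
        table = one_way_dsa(
            mitra_inputs,
            [("null",
              [Variation("econ", 1.0, field="cost_device")],
              [Variation("econ", 1.0, field="cost_device")])],
        )
        assert table.low_icer.iloc[0] == pytest.approx(base.icer)
        assert table.high_icer.iloc[0] == pytest.approx(base.icer)

    def test_tornado_rows_bracket_base_case(self, coapt_inputs):
        base, _, _ = run_comparison(coapt_inputs)
        table = one_way_dsa(
            coapt_inputs,
            [
                ("device",
                 [Variation("econ", 0.8, field="cost_device")],
                 [Variation("econ", 1.2, field="cost_device")]),
                ("utility",
                 [Variation("econ", 0.9, field="u_stable")],
                 [Variation("econ", 1.1, field="u_stable")]),
            ],
        )
        for _, row in table.iterrows():
            lo, hi = sorted([row.low_icer, row.high_icer])
            assert lo <= base.icer + 1e-9 and hi >= base.icer - 1e-9

    def test_hr_076_scenario_matches_published_icer(self, mitra_inputs):
        varied = apply_variations(
            mitra_inputs, [Variation("os_hr", 0.76, arm="intervention")]
        )
        res, _, _ = run_comparison(varied)
        assert res.icer == pytest.approx(35_523.0, rel=0.03)


class TestScenarioGrid:
    def _factor(self, name, field, levels, shared=False):
        return Factor(name, tuple(
            Variation("econ", v, field=field) for v in levels
        ), shared=shared)

    def test_three_binary_factors_give_eight_pairs(self, coapt_inputs):
        factors = [
            self._factor("device", "cost_device", (0.8, 1.2)),
            self._factor("hfh", "cost_hfh", (0.8, 1.2)),
            self._factor("util", "u_stable", (0.9, 1.1)),
        ]
        grid = scenario_grid(coapt_inputs.intervention, coapt_inputs.econ, factors)
        assert len(grid) == 8

    def test_six_binary_factors_give_64_pairs(self, coapt_inputs):
        factors = [
            self._factor(f"f{i}", "cost_hfh", (0.9, 1.1)) for i in range(6)
        ]
        grid = scenario_grid(coapt_inputs.intervention, coapt_inputs.econ, factors)
        assert len(grid) == 64

    def test_all_baseline_levels_reproduce_base_outcome(self, coapt_inputs):
        from clipcea.engine import run_arm

        factors = [self._factor("f", "cost_hfh", (1.0,))]
        grid = scenario_grid(coapt_inputs.intervention, coapt_inputs.econ, factors)
        base = run_arm(coapt_inputs.intervention.os, coapt_inputs.intervention.hfh,
                       coapt_inputs.econ, True)
        assert grid.cost.iloc[0] == pytest.approx(base.cost)
        assert grid.qaly.iloc[0] == pytest.approx(base.qaly)

    def test_standard_factors_counts(self):
        fi = standard_grid_factors("intervention")
        fc = standard_grid_factors("control")
        assert len(fi) == 5 and len(fc) == 4  # device cost on intervention only
        assert {f.name for f in fi if f.shared} == {"hfh_cost", "utility", "os_ci"}


class TestBootstrap:
    def _pairs(self, rows):
        return pd.DataFrame(rows)

    def test_single_pair_per_arm_gives_constant_replicates(self):
        a = self._pairs([{"cost": 10.0, "qaly": 2.0}])
        b = self._pairs([{"cost": 4.0, "qaly": 1.0}])
        reps = bootstrap_ce(a, b, n_iter=500, seed=0)
        assert np.all(reps.delta_cost == 6.0)
        assert np.all(reps.delta_qaly == 1.0)

    def test_fixed_seed_reproducible(self):
        a = self._pairs([{"cost": c, "qaly": q} for c, q in [(1, 1), (2, 3), (5, 2)]])
        r1 = bootstrap_ce(a, a, n_iter=200, seed=11)
        r2 = bootstrap_ce(a, a, n_iter=200, seed=11)
        assert np.array_equal(r1.delta_cost, r2.delta_cost)
        assert np.array_equal(r1.delta_qaly, r2.delta_qaly)

    def test_replicate_means_converge_to_grid_means(self):
        rng = np.random.default_rng(1)
        a = self._pairs([{"cost": c, "qaly": q}
                         for c, q in zip(rng.normal(100, 10, 16), rng.normal(2, .2, 16))])
        b = self._pairs([{"cost": c, "qaly": q}
                         for c, q in zip(rng.normal(50, 10, 16), rng.normal(1, .2, 16))])
        reps = bootstrap_ce(a, b, n_iter=500, seed=2)
        exp_dc = a.cost.mean() - b.cost.mean()
        se = np.sqrt(a.cost.var() / 1 + b.cost.var()) / np.sqrt(500)
        assert abs(reps.delta_cost.mean() - exp_dc) < 3 * se * 2

    def test_stratified_draw_matches_shared_levels(self):
        a = self._pairs([
            {"cost": 10.0, "qaly": 1.0, "level_util": 0},
            {"cost": 20.0, "qaly": 2.0, "level_util": 1},
        ])
        b = self._pairs([
            {"cost": 1.0, "qaly": 0.5, "level_util": 0},
            {"cost": 2.0, "qaly": 1.5, "level_util": 1},
        ])
        reps = bootstrap_ce(a, b, n_iter=300, seed=3, shared_factors=["util"])
        # matched levels only: (10-1, 1-0.5) or (20-2, 2-1.5)
        combos = set(zip(reps.delta_cost.tolist(), reps.delta_qaly.tolist()))
        assert combos <= {(9.0, 0.5), (18.0, 0.5)}


class TestCEAC:
    def _reps(self, dc, dq):
        return BootstrapReplicates(np.asarray(dc, float), np.asarray(dq, float),
                                   seed=0, n_iter=len(dc))

    def test_probability_definition_via_nmb(self):
        reps = self._reps([100.0, 100.0], [1.0, 0.001])
        curve = ceac(reps, [0.0, 200.0, 1e6])
        assert list(curve.probability) == [0.0, 0.5, 1.0]

    def test_wtp_zero_all_costly_gives_zero(self):
        reps = self._reps([10.0, 20.0], [1.0, 2.0])
        assert ceac(reps, [0.0]).probability.iloc[0] == 0.0

    def test_bounded_and_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(4)
        reps = self._reps(rng.normal(100, 50, 400), rng.uniform(0.1, 2.0, 400))
        curve = ceac(reps, np.linspace(0, 200, 50))
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()
        assert np.all(np.diff(curve.probability) >= 0)

    def test_descending_wtp_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(self._reps([1.0], [1.0]), [10.0, 5.0])


class TestEllipse:
    def test_circular_cloud_gives_circular_ellipse(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        reps = BootstrapReplicates(3 + 2 * np.cos(theta), -1 + 2 * np.sin(theta),
                                   seed=0, n_iter=theta.size)
        ell = confidence_ellipse(reps, level=0.95)
        assert ell.center == pytest.approx([3.0, -1.0], abs=1e-9)
        assert ell.radii[0] == pytest.approx(ell.radii[1], rel=1e-9)
        assert not ell.degenerate

    def test_identical_replicates_flag_degenerate(self):
        reps = BootstrapReplicates(np.full(10, 5.0), np.full(10, 1.0), 0, 10)
        assert confidence_ellipse(reps).degenerate

    def test_level_zero_collapses_to_center(self):
        rng = np.random.default_rng(0)
        reps = BootstrapReplicates(rng.normal(size=50), rng.normal(size=50), 0, 50)
        ell = confidence_ellipse(reps, level=0.0)
        assert np.allclose(ell.radii, 0.0)


class TestQuadrants:
    def test_all_northeast(self):
        reps = BootstrapReplicates(np.ones(10), np.ones(10), 0, 10)
        assert quadrant_shares(reps)["NE"] == 1.0

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(9)
        reps = BootstrapReplicates(rng.normal(size=999), rng.normal(size=999), 0, 999)
        assert sum(quadrant_shares(reps).values()) == pytest.approx(1.0)

    def test_symmetric_cloud_splits_evenly(self):
        rng = np.random.default_rng(10)
        n = 4000
        reps = BootstrapReplicates(rng.normal(size=n), rng.normal(size=n), 0, n)
        shares = quadrant_shares(reps)
        se = 3 * np.sqrt(0.25 * 0.75 / n)
        for q in ("NE", "NW", "SW", "SE"):
            assert abs(shares[q] - 0.25) < se

    def test_exact_zero_counts_to_positive_side(self):
        reps = BootstrapReplicates(np.array([0.0]), np.array([0.0]), 0, 1)
        assert quadrant_shares(reps)["NE"] == 1.0


class TestEffectDuration:
    def test_curtail_at_horizon_recovers_base_case(self, coapt_inputs):
        base, _, _ = run_comparison(coapt_inputs)
        res, _, _ = run_comparison(curtail_effect(coapt_inputs, 30.0))
        assert res.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-9)
        assert res.delta_cost == pytest.approx(base.delta_cost, rel=1e-9)

    def test_curtail_at_two_years_with_equal_arms_leaves_little_effect(self, mitra_inputs):
        # arms share the same survival model, so only the within-window
        # hospitalisation difference survives the curtailment
        base, _, _ = run_comparison(mitra_inputs)
        res, _, _ = run_comparison(curtail_effect(mitra_inputs, 2.0))
        assert res.delta_ly == pytest.approx(0.0, abs=1e-12)
        assert 0 < res.delta_qaly < base.delta_qaly

    def test_curtailment_effect_grows_with_duration(self, coapt_inputs):
        base, _, _ = run_comparison(coapt_inputs)
        dly = [run_comparison(curtail_effect(coapt_inputs, y))[0].delta_ly
               for y in (2.0, 6.0, 18.0)]
        assert dly[0] < dly[1] < dly[2] < base.delta_ly

    def test_curtailed_coapt_icer_below_wtp_at_six_years(self, coapt_inputs):
        res, _, _ = run_comparison(curtail_effect(coapt_inputs, 6.0))
        assert res.icer <= 50_000.0

    def test_curtail_below_trial_window_rejected(self, coapt_inputs):
        with pytest.raises(ValueError):
            curtail_effect(coapt_inputs, 1.0)

    def test_waning_matches_base_within_trial_window(self, coapt_inputs):
        waned = wane_effect(coapt_inputs, end_year=10.0)
        t = np.linspace(0.0, 24.0, 49)
        assert np.allclose(
            waned.intervention.os.survival(t),
            coapt_inputs.intervention.os.survival(t),
            rtol=0, atol=1e-12,
        )

    def test_waned_hazard_midpoint_is_mean_of_both(self, coapt_inputs):
        waned = wane_effect(coapt_inputs, end_year=10.0)
        mid = (24.0 + 120.0) / 2
        h_i = coapt_inputs.intervention.os.hazard(mid)
        h_c = coapt_inputs.control.os.hazard(mid)
        assert waned.intervention.os.hazard(mid) == pytest.approx((h_i + h_c) / 2)

    def test_waning_far_horizon_approaches_base(self, coapt_inputs):
        base, _, _ = run_comparison(coapt_inputs)
        res, _, _ = run_comparison(wane_effect(coapt_inputs, end_year=300.0))
        assert res.delta_qaly == pytest.approx(base.delta_qaly, rel=0.05)

    def test_waning_end_before_start_rejected(self, coapt_inputs):
        with pytest.raises(ValueError):
            wane_effect(coapt_inputs, end_year=2.0)


def test_bootstrap_quadrants_converge_to_enumeration():
    """Large-sample bootstrap quadrant shares match exact grid-product fractions."""
    a = pd.DataFrame({"cost": [10.0, -10.0], "qaly": [1.0, 1.0]})
    b = pd.DataFrame({"cost": [0.0, 0.0], "qaly": [0.5, 1.5]})
    reps = bootstrap_ce(a, b, n_iter=50_000, seed=6)
    shares = quadrant_shares(reps)
    # enumeration: dc in {+10,-10} x dq in {+0.5,-0.5}, each combo 1/4
    for q in ("NE", "NW", "SW", "SE"):
        assert abs(shares[q] - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 50_000)
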