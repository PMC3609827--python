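"""Moment fitting, world sampling and simulation summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt import (
    FoodDatabase,
    FoodItem,
    NutrientRequirement,
    Scenario,
    UncertaintySpec,
    builtin_scenario,
    fit_beta_moments,
    fit_gamma_moments,
    optimize_diet,
    run_simulation,
    sample_world,
)


class TestMomentFitting:
    def test_gamma_closed_form(self):
        assert fit_gamma_moments(4.0, 2.0) == pytest.approx((4.0, 1.0))
        assert fit_gamma_moments(1.0, 1.0) == pytest.approx((1.0, 1.0))  # exponential

    def test_beta_closed_form_for_potato_wastage(self):
        alpha, beta = fit_beta_moments(0.45, 0.0142)
        nu = 0.45 * 0.55 / 0.0142**2 - 1
        assert alpha == pytest.approx(0.45 * nu)
        assert beta == pytest.approx(0.55 * nu)

    def test_beta_variance_bound_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            fit_beta_moments(0.5, 0.51)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_gamma_moments(0.0, 1.0)

    @settings(deadline=None, max_examples=30)
    @given(mean=st.floats(0.05, 10.0), cv=st.floats(0.01, 1.0))
    def test_gamma_moments_reproduced(self, mean, cv):
        shape, scale = fit_gamma_moments(mean, cv * mean)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert shape * scale**2 == pytest.approx((cv * mean) ** 2, rel=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(mean=st.floats(0.05, 0.95), frac=st.floats(0.05, 0.8))
    def test_beta_moments_reproduced(self, mean, frac):
        sd = frac * (mean * (1 - mean)) ** 0.5
        alpha, beta = fit_beta_moments(mean, sd)
        assert alpha / (alpha + beta) == pytest.approx(mean, rel=1e-9)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert var == pytest.approx(sd**2, rel=1e-9)


def _degenerate_spec(**kw):
    return UncertaintySpec(nutrient_cv=0.0, energy_target_sd=0.0, **kw)


def _one_food_db(price_sd=0.0, wastage_sd=0.0, req_sd=0.0):
    items = [
        FoodItem(
            "f", "f", "other", 1.00, 0.3, 1.0, {"protein": 20.0},
            price_sd=price_sd, wastage_sd=wastage_sd,
        )
    ]
    reqs = [NutrientRequirement("protein", "g", min_mean=50.0, heterogeneity_sd=req_sd)]
    return FoodDatabase(items=items, requirements=reqs).validate()


class TestSampleWorld:
    def test_all_zero_sds_reproduce_the_database(self):
        db = _one_food_db()
        world = sample_world(db, _degenerate_spec(), draw_index=3)
        assert world.food("f").price_mean == db.food("f").price_mean
        assert world.food("f").wastage_mean == db.food("f").wastage_mean
        assert world.food("f").nutrient_content == db.food("f").nutrient_content
        assert world.requirement("protein").min_mean == 50.0

    def test_same_seed_and_draw_identical(self, default_db):
        spec = UncertaintySpec(seed=5)
        a = sample_world(default_db, spec, 17)
        b = sample_world(default_db, spec, 17)
        for fa, fb in zip(a.items, b.items):
            assert fa.price_mean == fb.price_mean
            assert fa.wastage_mean == fb.wastage_mean
            assert fa.nutrient_content == fb.nutrient_content
        c = sample_world(default_db, spec, 18)
        assert any(fa.price_mean != fc.price_mean for fa, fc in zip(a.items, c.items))

    def test_original_database_untouched(self, default_db):
        before = default_db.food("carrots").price_mean
        sample_world(default_db, UncertaintySpec(seed=1), 0)
        assert default_db.food("carrots").price_mean == before

    def test_price_draws_recover_the_mean(self):
        db = _one_food_db(price_sd=0.10)
        spec = _degenerate_spec(seed=2)
        draws = [sample_world(db, spec, k).food("f").price_mean for k in range(2000)]
        assert np.mean(draws) == pytest.approx(1.00, abs=0.01)

    def test_category_cv_fallback_for_foods_without_price_sd(self, default_db):
        # taro has no price SD; it borrows variability from its category
        spec = _degenerate_spec(seed=3)
        draws = [sample_world(default_db, spec, k).food("taro").price_mean for k in range(60)]
        assert np.std(draws) > 0

    def test_sampled_wastage_stays_in_unit_interval(self, default_db):
        spec = UncertaintySpec(seed=4)
        for k in range(50):
            world = sample_world(default_db, spec, k)
            for f in world.items:
                assert 0.0 <= f.wastage_mean < 1.0
                assert f.price_mean > 0


class TestRunSimulation:
    def test_degenerate_simulation_collapses_to_the_optimum(self, micro_db):
        scenario = builtin_scenario("C1").restricted_to(micro_db)
        spec = _degenerate_spec(n_iterations=5, seed=0)
        # zero out the database's own sds too
        db = micro_db.copy()
        for f in db.items:
            f.price_sd = 0.0
            f.wastage_sd = 0.0
        for r in db.requirements:
            r.heterogeneity_sd = 0.0
        det = optimize_diet(db, scenario)
        sim = run_simulation(db, scenario, spec)
        out = sim.outputs["objective"]
        assert out.lower95 == out.median == out.upper95 == pytest.approx(det.objective_value)
        assert sim.n_feasible == 5 and sim.n_infeasible == 0

    def test_interval_ordering_and_accounting(self, micro_db):
        scenario = builtin_scenario("C1").restricted_to(micro_db)
        sim = run_simulation(micro_db, scenario, UncertaintySpec(n_iterations=60, seed=1))
        assert sim.n_feasible + sim.n_infeasible == 60
        for key, s in sim.outputs.items():
            if key.startswith("ratio:"):
                # statistic-wise ratios (ratio of medians, of SI bounds)
                # need not be ordered like a quantile interval
                continue
            if not np.isnan(s.mean):
                assert s.lower95 <= s.median <= s.upper95

    def test_two_seeds_agree_within_monte_carlo_error(self, micro_db):
        scenario = builtin_scenario("C1").restricted_to(micro_db)
        sims = [
            run_simulation(micro_db, scenario, UncertaintySpec(n_iterations=200, seed=s))
            for s in (11, 12)
        ]
        costs = [sim.outputs["cost"] for sim in sims]
        spread = (costs[0].upper95 - costs[0].lower95) / 3.92  # ~ per-draw sd
        se = 1.25 * spread / np.sqrt(200)  # median standard error
        assert abs(costs[0].median - costs[1].median) < 3 * 2**0.5 * se * 3

    def test_constructed_half_infeasible_fixture(self):
        # requirement sd makes the floor jump above what the single food can
        # supply (capped at 100 g) in about half the draws
        items = [FoodItem("f", "f", "other", 1.0, 0.0, 1.0, {"protein": 50.0})]
        reqs = [NutrientRequirement("protein", "g", min_mean=50.0, heterogeneity_sd=8.0)]
        db = FoodDatabase(items=items, requirements=reqs).validate()
        scenario = Scenario(id="half", per_food_max={"f": 100.0})
        spec = _degenerate_spec(n_iterations=400, seed=9)
        sim = run_simulation(db, scenario, spec)
        assert 0.35 < sim.n_infeasible / 400 < 0.65
        assert sim.outputs["cost"].median <= 1.0

    def test_ratio_outputs_are_ratios_of_statistics(self, micro_db):
        scenario = builtin_scenario("C1").restricted_to(micro_db)
        sim = run_simulation(micro_db, scenario, UncertaintySpec(n_iterations=50, seed=2))
        r = sim.outputs["ratio:potassium_sodium"]
        k = sim.outputs["nutrient:potassium"]
        na = sim.outputs["nutrient:sodium"]
        assert r.median == pytest.approx(k.median / na.median)
        assert r.mean == pytest.approx(k.mean / na.mean)
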