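"""LP/MILP solving, diet evaluation and energy scaling."""

import numpy as np
import pytest

from dietopt import (
    FoodDatabase,
    FoodItem,
    NutrientRequirement,
    Scenario,
    builtin_scenario,
    compile_constraints,
    evaluate_diet,
    generate_known_optimum_instance,
    optimize_diet,
    scale_to_energy,
    solve_lp,
)

from oracles import semicontinuous_brute_force


def _protein_db(exclude_tag=None):
    tags = frozenset() if exclude_tag is None else frozenset({exclude_tag})
    items = [
        FoodItem("a", "a", "other", 1.00, 0.0, 1.0, {"protein": 20.0}, tags=tags),
        FoodItem("b", "b", "other", 0.60, 0.0, 1.0, {"protein": 10.0}, tags=tags),
    ]
    reqs = [NutrientRequirement("protein", "g", min_mean=50.0)]
    return FoodDatabase(items=items, requirements=reqs).validate()


class TestSolveLp:
    def test_two_food_protein_floor(self):
        db = _protein_db()
        system = compile_constraints(Scenario(id="t"), db)
        sol = solve_lp(system)
        assert sol.status == "optimal"
        assert sol.quantities["a"] == pytest.approx(250.0, rel=1e-9)
        assert sol.quantities["b"] == pytest.approx(0.0, abs=1e-9)
        assert sol.cost == pytest.approx(2.50, rel=1e-9)

    def test_vacuous_constraint_gives_empty_diet(self):
        db = _protein_db()
        db.requirements[0].min_mean = 0.0
        sol = solve_lp(compile_constraints(Scenario(id="t"), db))
        assert sol.status == "optimal"
        assert sol.cost == pytest.approx(0.0, abs=1e-12)

    def test_unreachable_floor_is_infeasible(self):
        db = _protein_db()
        s = Scenario(id="t", per_food_max={"a": 0.0, "b": 0.0})
        sol = solve_lp(compile_constraints(s, db))
        assert sol.status == "infeasible"

    def test_binding_constraints_reported(self):
        db = _protein_db()
        sol = solve_lp(compile_constraints(Scenario(id="t"), db))
        assert "nutrient:protein" in sol.binding_constraints


class TestSemicontinuity:
    def test_small_optimal_amount_pushed_to_ten_grams(self):
        # only food "rare" supplies the trace nutrient, optimally at < 10 g
        items = [
            FoodItem("bulk", "bulk", "other", 0.50, 0.0, 1.0, {"energy": 1500.0, "trace": 0.0}),
            FoodItem("rare", "rare", "other", 2.00, 0.0, 1.0, {"energy": 1500.0, "trace": 10.0}),
        ]
        reqs = [
            NutrientRequirement("energy", "kJ", min_mean=3000.0),
            NutrientRequirement("trace", "g", min_mean=0.5),  # 5 g of "rare" suffices
        ]
        db = FoodDatabase(items=items, requirements=reqs).validate()
        for strategy in ("milp", "iterative"):
            sol = optimize_diet(db, Scenario(id="t"), strategy=strategy)
            assert sol.status == "optimal"
            assert sol.quantities["rare"] == pytest.approx(10.0, rel=1e-6)

    @pytest.mark.parametrize("strategy", ["milp", "iterative"])
    def test_no_food_lands_in_forbidden_interval(self, default_db, strategy):
        for sid in ("C1", "G1", "NZ_T"):
            sol = optimize_diet(default_db, builtin_scenario(sid), strategy=strategy)
            assert sol.status == "optimal"
            scenario = builtin_scenario(sid)
            for fid, q in sol.quantities.items():
                food = default_db.food(fid)
                if food.is_condiment or fid in scenario.per_food_min:
                    continue
                assert not (1e-6 < q < 10.0 - 1e-6), f"{sid}:{fid} at {q} g"

    def test_milp_matches_subset_brute_force(self):
        rng = np.random.default_rng(7)
        from oracles import random_instance

        for _ in range(10):
            db, scenario, c, a_ge, b_ge = random_instance(rng)
            expected = semicontinuous_brute_force(c, a_ge, b_ge, scenario.min_if_included)
            sol = optimize_diet(db, scenario, strategy="milp")
            assert expected is not None and sol.status == "optimal"
            assert sol.objective_value == pytest.approx(expected[0], rel=1e-6, abs=1e-9)

    def test_iterative_never_beats_exact(self):
        rng = np.random.default_rng(11)
        from oracles import random_instance

        for _ in range(10):
            db, scenario, *_ = random_instance(rng)
            exact = optimize_diet(db, scenario, strategy="milp")
            heuristic = optimize_diet(db, scenario, strategy="iterative")
            if heuristic.status == "optimal":
                assert heuristic.objective_value >= exact.objective_value - 1e-9


class TestOptimizeDiet:
    def test_budget_below_min_cost_is_infeasible(self, micro_db):
        c1 = builtin_scenario("C1").restricted_to(micro_db)
        base = optimize_diet(micro_db, c1)
        assert base.status == "optimal"
        import dataclasses

        squeezed = dataclasses.replace(
            c1, id="squeezed", objective="min_ghg", budget_cap=0.5 * base.cost
        )
        tight = optimize_diet(micro_db, squeezed)
        # half the min-cost budget cannot buy a feasible diet
        assert tight.status == "infeasible"

    def test_optimum_bounds_any_feasible_diet(self, micro_db):
        c1 = builtin_scenario("C1").restricted_to(micro_db)
        opt = optimize_diet(micro_db, c1)
        # perturb the optimum into another feasible diet: add food mass
        bulky = {fid: q * 1.15 + (20.0 if q > 0 else 0.0) for fid, q in opt.quantities.items()}
        hand = evaluate_diet(micro_db, bulky)
        assert opt.objective_value <= hand.cost + 1e-9

    def test_salt_minimum_yields_to_sodium_cap(self, default_db):
        sol = optimize_diet(default_db, builtin_scenario("NZ_M"))
        assert sol.status == "optimal"
        assert sol.nutrient_intakes["sodium"] <= 2300.0 * (1 + 1e-6)
        # salt present but below the stated 3.5 g because sodium binds
        assert 0.0 < sol.quantities["salt"] < 3.5

    def test_known_optimum_instances(self):
        for kind in ("single_binding_nutrient", "two_constraint_vertex", "budget_capped"):
            db, scenario, expected = generate_known_optimum_instance(kind)
            sol = optimize_diet(db, scenario)
            assert sol.status == "optimal"
            assert sol.objective_value == pytest.approx(expected["objective_value"], rel=1e-6)
            for fid, q in expected["quantities"].items():
                assert sol.quantities[fid] == pytest.approx(q, rel=1e-6, abs=1e-6)


class TestEvaluateDiet:
    def test_direct_arithmetic(self):
        items = [FoodItem("x", "x", "other", 0.50, 0.0, 2.0, {"energy": 100.0})]
        db = FoodDatabase(items=items, requirements=[NutrientRequirement("energy", "kJ", min_mean=1.0)]).validate()
        sol = evaluate_diet(db, {"x": 100.0})
        assert sol.cost == pytest.approx(0.50)
        assert sol.ghg == pytest.approx(0.20)
        assert sol.status == "evaluated"

    def test_wastage_inflates_cost(self):
        items = [FoodItem("x", "x", "other", 1.00, 0.5, 1.0, {"energy": 100.0})]
        db = FoodDatabase(items=items, requirements=[NutrientRequirement("energy", "kJ", min_mean=1.0)]).validate()
        assert evaluate_diet(db, {"x": 100.0}).cost == pytest.approx(2.00)

    def test_empty_diet_is_all_zero(self, micro_db):
        sol = evaluate_diet(micro_db, {})
        assert sol.cost == 0.0 and sol.ghg == 0.0
        assert all(v == 0.0 for v in sol.nutrient_intakes.values())

    def test_unknown_food_raises(self, micro_db):
        with pytest.raises(KeyError, match="unicorn"):
            evaluate_diet(micro_db, {"unicorn": 10.0})


class TestScaleToEnergy:
    def test_documented_scaling_factor(self, micro_db):
        diet = {fid: 100.0 for fid in micro_db.food_ids}
        scaled = scale_to_energy(diet, micro_db, 11450.0)
        current = evaluate_diet(micro_db, diet).nutrient_intakes["energy"]
        for fid in diet:
            assert scaled[fid] == pytest.approx(100.0 * 11450.0 / current, rel=1e-12)
        assert evaluate_diet(micro_db, scaled).nutrient_intakes["energy"] == pytest.approx(
            11450.0, rel=1e-9
        )

    def test_identity_when_already_on_target(self, micro_db):
        diet = {micro_db.food_ids[0]: 123.0}
        energy = evaluate_diet(micro_db, diet).nutrient_intakes["energy"]
        scaled = scale_to_energy(diet, micro_db, energy)
        assert scaled == pytest.approx(diet)

    def test_zero_energy_diet_rejected(self, micro_db):
        with pytest.raises(ValueError, match="zero-energy"):
            scale_to_energy({}, micro_db, 11450.0)
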