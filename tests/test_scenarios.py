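"""Built-in scenarios and constraint compilation."""

import dataclasses

import numpy as np
import pytest

from dietopt import (
    BUILTIN_SCENARIO_IDS,
    CategoryConstraint,
    CompilationError,
    FoodDatabase,
    FoodItem,
    LinkedRatio,
    NutrientRequirement,
    Scenario,
    builtin_scenario,
    compile_constraints,
)


class TestBuiltins:
    def test_all_sixteen_load(self):
        for sid in BUILTIN_SCENARIO_IDS:
            s = builtin_scenario(sid)
            assert s.id == sid

    def test_unknown_id_lists_valid_ids(self):
        with pytest.raises(KeyError, match="C1"):
            builtin_scenario("C99")

    def test_g1_minimizes_ghg_under_five_dollars(self):
        s = builtin_scenario("G1")
        assert s.objective == "min_ghg"
        assert s.budget_cap == 5.00
        assert builtin_scenario("G1", match_paper=True).budget_cap == 4.99

    def test_budget_caps_nine_dollars_for_looser_scenarios(self):
        for sid in ("G2", "G3", "G4", "MED_G", "ASIAN_G"):
            assert builtin_scenario(sid).budget_cap == 9.00

    def test_c1_caps_added_sugar_at_sixty_grams(self):
        assert builtin_scenario("C1").added_sugar_max == 60

    def test_vegan_scenario_excludes_all_animal_foods(self):
        s = builtin_scenario("G4")
        assert {"animal_product", "dairy_product", "fish", "meat", "egg"} <= s.excluded_tags

    def test_default_variety_caps(self):
        s = builtin_scenario("C1")
        for fid in ("flour_wholemeal", "flour_white", "pasta", "oats"):
            assert s.per_food_max[fid] == 240
        caps = [c for c in s.category_constraints if c.per_member_max == 200]
        assert caps and "vegetable" in caps[0].any_of

    def test_flour_oil_ratio_in_c2(self):
        s = builtin_scenario("C2")
        assert any(
            r.food_a == "flour_wholemeal" and r.food_b == "vegetable_oil" and r.ratio_a_to_b == 7
            for r in s.linked_ratios
        )

    def test_min_cost_scenarios_reject_budget_cap(self):
        with pytest.raises(ValueError, match="budget_cap"):
            Scenario(id="bad", objective="min_cost", budget_cap=5.0)
        with pytest.raises(ValueError, match="budget_cap"):
            Scenario(id="bad", objective="min_ghg")


def _toy_db(n_veg=6):
    items = [
        FoodItem(f"veg{i}", f"veg{i}", "fruit_veg", 0.5, 0.0, 0.5,
                 {"energy": 150.0}, tags=frozenset({"vegetable"}))
        for i in range(n_veg)
    ]
    items.append(
        FoodItem("spud", "spud", "fruit_veg", 0.2, 0.0, 0.6, {"energy": 320.0},
                 tags=frozenset({"vegetable", "starchy_root"}))
    )
    items.append(FoodItem("flour", "flour", "cereal_grain", 0.15, 0.05, 1.1, {"energy": 1430.0}))
    items.append(FoodItem("oil", "oil", "fat_oil", 0.55, 0.0, 3.0, {"energy": 3700.0}))
    reqs = [NutrientRequirement("energy", "kJ", min_mean=5000.0)]
    return FoodDatabase(items=items, requirements=reqs).validate()


class TestCompilation:
    def test_aggregate_row_covers_non_starchy_vegetables(self):
        db = _toy_db()
        s = Scenario(
            id="c4ish",
            category_constraints=[
                CategoryConstraint(
                    name="veg", any_of={"vegetable"}, none_of={"starchy_root"}, total_min=412.0
                )
            ],
        )
        system = compile_constraints(s, db)
        row = next(r for r in system.rows if r.name == "category:veg")
        assert row.lower == 412.0
        assert set(row.coeffs) == {f"veg{i}" for i in range(6)}
        assert all(v == 1.0 for v in row.coeffs.values())

    def test_empty_scenario_compiles_to_nutrient_rows_only(self):
        db = _toy_db(n_veg=1)
        system = compile_constraints(Scenario(id="plain"), db)
        assert [r.name for r in system.rows] == ["nutrient:energy"]

    def test_linked_ratio_becomes_equality_row(self):
        db = _toy_db()
        s = Scenario(id="c2ish", linked_ratios=[LinkedRatio("flour", "oil", 7.0)])
        system = compile_constraints(s, db)
        row = next(r for r in system.rows if r.name.startswith("ratio:"))
        assert row.coeffs == {"flour": 1.0, "oil": -7.0}
        assert row.lower == row.upper == 0.0

    def test_budget_row_uses_purchased_weight_cost(self):
        db = _toy_db()
        s = Scenario(id="g1ish", objective="min_ghg", budget_cap=5.0)
        system = compile_constraints(s, db)
        row = next(r for r in system.rows if r.name == "budget")
        assert row.upper == 5.0
        assert row.coeffs["flour"] == pytest.approx(0.15 / (100 * (1 - 0.05)))

    def test_missing_food_reference_is_a_compile_error(self):
        db = _toy_db()
        s = Scenario(id="bad", per_food_min={"unicorn_steak": 100.0})
        with pytest.raises(CompilationError, match="unicorn_steak"):
            compile_constraints(s, db)

    def test_inconsistent_bounds_are_a_compile_error(self):
        db = _toy_db()
        s = Scenario(id="bad", per_food_min={"flour": 300.0}, per_food_max={"flour": 240.0})
        with pytest.raises(CompilationError, match="flour"):
            compile_constraints(s, db)

    def test_excluded_foods_get_no_variable(self):
        db = _toy_db()
        s = Scenario(id="novaeg", excluded_tags=frozenset({"starchy_root"}))
        system = compile_constraints(s, db)
        assert "spud" not in system.food_ids

    def test_forced_recipe_amount_overrides_per_member_cap(self):
        db = _toy_db()
        s = Scenario(
            id="nzsish",
            per_food_min={"spud": 426.0},
            category_constraints=[
                CategoryConstraint(name="cap", any_of={"vegetable"}, per_member_max=200.0)
            ],
        )
        system = compile_constraints(s, db)
        i = system.index("spud")
        assert system.lower[i] == 426.0 and system.upper[i] > 426.0
        j = system.index("veg0")
        assert system.upper[j] == 200.0

    def test_compilation_is_deterministic(self, default_db):
        s = builtin_scenario("MED")
        a = compile_constraints(s, default_db)
        b = compile_constraints(s, default_db)
        assert a.food_ids == b.food_ids
        assert [r.name for r in a.rows] == [r.name for r in b.rows]
        assert np.array_equal(a.cost_per_g, b.cost_per_g)
        for ra, rb in zip(a.rows, b.rows):
            assert ra.coeffs == rb.coeffs and ra.lower == rb.lower and ra.upper == rb.upper

    def test_added_constraint_never_enlarges_feasible_region(self, default_db):
        # any solution of the augmented system satisfies the original rows
        from dietopt import optimize_diet

        base = builtin_scenario("C1")
        augmented = dataclasses.replace(
            base,
            category_constraints=base.category_constraints
            + [CategoryConstraint(name="extra_veg", any_of={"vegetable"}, total_min=300.0)],
        )
        sol = optimize_diet(default_db, augmented)
        assert sol.status == "optimal"
        system = compile_constraints(base, default_db)
        x = np.array([sol.quantities.get(fid, 0.0) for fid in system.food_ids])
        a, lb, ub = system.row_matrix()
        vals = a @ x
        assert (vals >= lb - 1e-6 * np.maximum(1, np.abs(lb))).all()
        assert (vals <= ub + 1e-6 * np.maximum(1, np.abs(ub))).all()

    def test_scenario_price_override_changes_cost_vector(self, default_db):
        s = builtin_scenario("ASIAN")
        system = compile_constraints(s, default_db)
        i = system.index("rice")
        w = default_db.food("rice").wastage_mean
        assert system.cost_per_g[i] == pytest.approx(0.18 / (100 * (1 - w)))
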