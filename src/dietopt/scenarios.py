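"""Declarative diet scenarios and compilation into linear constraint systems.

A :class:`Scenario` bundles an objective (minimize daily cost or daily GHG
emissions) with the constraints that shape the diet: tag-based food
exclusions, per-food gram bounds (recipe components, variety caps),
aggregate category constraints (e.g. total non-starchy vegetables),
linked-ratio equalities (e.g. flour mixed with oil 7:1 for flatbreads),
an added-sugar cap, and — for emission-minimizing scenarios — a daily
budget cap.

Sixteen built-in scenarios ship as editable YAML files:

================  ==========================================================
C1–C4             least-cost diets (plain; with porridge + flour/oil dishes;
                  minimal cooking skills; high vegetable)
G1–G4             least-GHG diets under budget caps ($5; $9; $9 + porridge;
                  $9 vegan)
MED, MED_G        Mediterranean-style pattern (min cost / min GHG)
ASIAN, ASIAN_G    Asian-style pattern (min cost / min GHG)
NZ_M/S/T/P        familiar-meal diets (mince, sausages, tuna pasta, Pacific
                  theme) with a standard breakfast and lunch
================  ==========================================================
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .food_data import ENERGY_ID, FoodDatabase, FoodItem, purchased_weight

__all__ = [
    "BUILTIN_SCENARIO_IDS",
    "Scenario",
    "CategoryConstraint",
    "LinkedRatio",
    "LinearRow",
    "ConstraintSystem",
    "CompilationError",
    "builtin_scenario",
    "load_scenario",
    "compile_constraints",
]

BUILTIN_SCENARIO_IDS = (
    "C1",
    "C2",
    "C3",
    "C4",
    "G1",
    "G2",
    "G3",
    "G4",
    "MED",
    "MED_G",
    "ASIAN",
    "ASIAN_G",
    "NZ_M",
    "NZ_S",
    "NZ_T",
    "NZ_P",
)

#: Default minimum daily amount for any selected non-condiment food (grams).
DEFAULT_MIN_IF_INCLUDED = 10.0


class CompilationError(ValueError):
    """A scenario cannot be realized over the given database."""


@dataclass
class CategoryConstraint:
    """Aggregate bound over foods selected by tags.

    A food is a member when it carries at least one tag in ``any_of``
    (empty = all foods), none in ``none_of``, and its id is not in
    ``exclude_ids``.  ``per_member_max`` caps each member individually
    (tightening its upper bound) unless the scenario forces a larger
    per-food minimum on it, as recipes sometimes do.
    """

    name: str
    any_of: frozenset[str] = field(default_factory=frozenset)
    none_of: frozenset[str] = field(default_factory=frozenset)
    exclude_ids: frozenset[str] = field(default_factory=frozenset)
    total_min: float | None = None
    total_max: float | None = None
    per_member_max: float | None = None

    def __post_init__(self) -> None:
        self.any_of = frozenset(self.any_of)
        self.none_of = frozenset(self.none_of)
        self.exclude_ids = frozenset(self.exclude_ids)

    def matches(self, food: FoodItem) -> bool:
        if food.id in self.exclude_ids:
            return False
        if self.any_of and not (food.tags & self.any_of):
            return False
        if food.tags & self.none_of:
            return False
        return True


@dataclass
class LinkedRatio:
    """Equality link between two foods: ``x_a = ratio_a_to_b * x_b``."""

    food_a: str
    food_b: str
    ratio_a_to_b: float

    def __post_init__(self) -> None:
        if self.ratio_a_to_b <= 0:
            raise ValueError("ratio_a_to_b must be positive")


@dataclass
class Scenario:
    """Declarative constraint bundle for one optimization run."""

    id: str
    objective: str = "min_cost"  # or "min_ghg"
    budget_cap: float | None = None  # NZ$/day, required for min_ghg
    excluded_tags: frozenset[str] = field(default_factory=frozenset)
    per_food_min: dict[str, float] = field(default_factory=dict)
    per_food_max: dict[str, float] = field(default_factory=dict)
    category_constraints: list[CategoryConstraint] = field(default_factory=list)
    linked_ratios: list[LinkedRatio] = field(default_factory=list)
    added_sugar_max: float | None = None
    min_if_included: float = DEFAULT_MIN_IF_INCLUDED
    price_overrides: dict[str, float] = field(default_factory=dict)
    #: Foods whose per_food_min may be lowered when it makes the scenario
    #: infeasible.  Cooking salt is adjustable by default: the sodium cap
    #: always stays active, and added salt yields to it.
    adjustable_min_ids: tuple[str, ...] = ("salt",)
    description: str = ""

    def __post_init__(self) -> None:
        self.excluded_tags = frozenset(self.excluded_tags)
        if self.objective not in ("min_cost", "min_ghg"):
            raise ValueError(f"unknown objective '{self.objective}'")
        if self.objective == "min_cost" and self.budget_cap is not None:
            raise ValueError(f"scenario '{self.id}': min_cost scenarios take no budget_cap")
        if self.objective == "min_ghg" and self.budget_cap is None:
            raise ValueError(f"scenario '{self.id}': min_ghg scenarios require a budget_cap")

    def restricted_to(self, db: FoodDatabase) -> "Scenario":
        """Drop references to foods absent from ``db``.

        Convenience for running a scenario over a reduced database (e.g. a
        micro test fixture); forced recipe components that the database
        cannot supply are silently omitted rather than raising at compile
        time.
        """
        present = set(db.food_ids)
        return replace(
            self,
            per_food_min={k: v for k, v in self.per_food_min.items() if k in present},
            per_food_max={k: v for k, v in self.per_food_max.items() if k in present},
            linked_ratios=[
                r for r in self.linked_ratios if r.food_a in present and r.food_b in present
            ],
            price_overrides={k: v for k, v in self.price_overrides.items() if k in present},
            category_constraints=[replace(c) for c in self.category_constraints],
        )


# ---------------------------------------------------------------------------
# Built-in scenario files
# ---------------------------------------------------------------------------


def _scenario_from_dict(doc: dict) -> Scenario:
    cats = [
        CategoryConstraint(
            name=c["name"],
            any_of=frozenset(c.get("any_of", [])),
            none_of=frozenset(c.get("none_of", [])),
            exclude_ids=frozenset(c.get("exclude_ids", [])),
            total_min=c.get("total_min"),
            total_max=c.get("total_max"),
            per_member_max=c.get("per_member_max"),
        )
        for c in doc.get("category_constraints", [])
    ]
    ratios = [
        LinkedRatio(r["food_a"], r["food_b"], float(r["ratio_a_to_b"]))
        for r in doc.get("linked_ratios", [])
    ]
    return Scenario(
        id=doc["id"],
        objective=doc.get("objective", "min_cost"),
        budget_cap=doc.get("budget_cap"),
        excluded_tags=frozenset(doc.get("excluded_tags", [])),
        per_food_min={k: float(v) for k, v in (doc.get("per_food_min") or {}).items()},
        per_food_max={k: float(v) for k, v in (doc.get("per_food_max") or {}).items()},
        category_constraints=cats,
        linked_ratios=ratios,
        added_sugar_max=doc.get("added_sugar_max"),
        min_if_included=float(doc.get("min_if_included", DEFAULT_MIN_IF_INCLUDED)),
        price_overrides={k: float(v) for k, v in (doc.get("price_overrides") or {}).items()},
        description=doc.get("description", ""),
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML file (same schema as the builtins)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _scenario_from_dict(doc)


def _builtin_dir():
    return importlib.resources.files("dietopt") / "scenarios_builtin"


def _merge_defaults(doc: dict, defaults: dict) -> dict:
    merged = dict(doc)
    merged["min_if_included"] = doc.get("min_if_included", defaults.get("min_if_included", 10))
    pfm = dict(defaults.get("per_food_max", {}))
    pfm.update(doc.get("per_food_max", {}))
    merged["per_food_max"] = pfm
    merged["category_constraints"] = list(defaults.get("category_constraints", [])) + list(
        doc.get("category_constraints", [])
    )
    if "added_sugar_max" not in doc and "added_sugar_max" in defaults:
        merged["added_sugar_max"] = defaults["added_sugar_max"]
    return merged


def builtin_scenario(scenario_id: str, match_paper: bool = False) -> Scenario:
    """Return one of the 16 built-in scenarios, fully populated.

    ``match_paper`` switches the G1 budget cap from the nominal $5.00 to the
    just-below value $4.99 at which the published run reports the cap
    binding (a linear program cannot express a strict "< $5" inequality).
    """
    if scenario_id not in BUILTIN_SCENARIO_IDS:
        raise KeyError(
            f"unknown scenario id '{scenario_id}'; valid ids: {', '.join(BUILTIN_SCENARIO_IDS)}"
        )
    base = _builtin_dir()
    defaults = yaml.safe_load((base / "_defaults.yaml").read_text(encoding="utf-8"))
    doc = yaml.safe_load((base / f"{scenario_id}.yaml").read_text(encoding="utf-8"))
    scenario = _scenario_from_dict(_merge_defaults(doc, defaults))
    if match_paper and scenario_id == "G1":
        scenario = replace(scenario, budget_cap=4.99)
    return scenario


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


@dataclass
class LinearRow:
    """One linear constraint row: lower <= coeffs . x <= upper."""

    name: str
    coeffs: dict[str, float]
    lower: float | None = None
    upper: float | None = None


@dataclass
class ConstraintSystem:
    """A scenario realized over a database as a concrete linear system.

    Decision variables are grams edible per day, one per non-excluded
    food, ordered by sorted food id.  ``cost_per_g`` and ``ghg_per_g``
    already include the wastage correction (cost and emissions attach to
    purchased weight).
    """

    scenario_id: str
    objective: str
    food_ids: list[str]
    cost_per_g: np.ndarray  # NZ$/day per gram edible: p/(100(1-w))
    ghg_per_g: np.ndarray  # kg CO2e/day per gram edible: g/(1000(1-w))
    lower: np.ndarray  # per-food gram bounds
    upper: np.ndarray
    rows: list[LinearRow]
    nutrient_coeffs: dict[str, np.ndarray]  # nutrient/day per gram edible: c/100
    semicontinuous: np.ndarray  # bool mask: subject to the min-if-included rule
    min_if_included: float

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    def index(self, food_id: str) -> int:
        return self.food_ids.index(food_id)

    def objective_vector(self) -> np.ndarray:
        return self.cost_per_g if self.objective == "min_cost" else self.ghg_per_g

    def row_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (A, lb, ub) for the constraint rows (infinite where absent)."""
        n = self.n_foods
        a = np.zeros((len(self.rows), n))
        lb = np.full(len(self.rows), -np.inf)
        ub = np.full(len(self.rows), np.inf)
        pos = {fid: i for i, fid in enumerate(self.food_ids)}
        for r, row in enumerate(self.rows):
            for fid, c in row.coeffs.items():
                a[r, pos[fid]] = c
            if row.lower is not None:
                lb[r] = row.lower
            if row.upper is not None:
                ub[r] = row.upper
        return a, lb, ub


def compile_constraints(scenario: Scenario, db: FoodDatabase) -> ConstraintSystem:
    """Realize a scenario over a database as a linear constraint system.

    Row order is deterministic: nutrient rows sorted by nutrient id, then
    category-aggregate rows in scenario order, then the added-sugar row,
    then linked-ratio equalities, then the budget row.
    """
    # referenced food ids must exist
    referenced = (
        set(scenario.per_food_min)
        | set(scenario.per_food_max)
        | set(scenario.price_overrides)
        | {r.food_a for r in scenario.linked_ratios}
        | {r.food_b for r in scenario.linked_ratios}
    )
    missing = sorted(fid for fid in referenced if fid not in db)
    if missing:
        raise CompilationError(
            f"scenario '{scenario.id}' references food id(s) absent from the database: "
            + ", ".join(missing)
        )

    included = sorted(
        f.id for f in db.items if not (f.tags & scenario.excluded_tags)
    )
    if not included:
        raise CompilationError(f"scenario '{scenario.id}': all foods excluded")
    for fid in scenario.per_food_min:
        if fid not in included:
            raise CompilationError(
                f"scenario '{scenario.id}': food '{fid}' has a minimum but is excluded by tags"
            )

    foods = [db.food(fid) for fid in included]
    n = len(foods)
    pos = {fid: i for i, fid in enumerate(included)}

    price = np.array(
        [scenario.price_overrides.get(f.id, f.price_mean) for f in foods]
    )
    wast = np.array([f.wastage_mean for f in foods])
    ghg = np.array([f.ghg_factor for f in foods])
    cost_per_g = price / (100.0 * (1.0 - wast))
    ghg_per_g = ghg / (1000.0 * (1.0 - wast))

    lower = np.zeros(n)
    upper = np.full(n, np.inf)
    forced = np.zeros(n, dtype=bool)  # explicit recipe minimum present
    for fid, v in scenario.per_food_min.items():
        lower[pos[fid]] = v
        forced[pos[fid]] = v > 0
    for fid, v in scenario.per_food_max.items():
        if fid in pos:
            upper[pos[fid]] = min(upper[pos[fid]], v)

    rows: list[LinearRow] = []

    # nutrient rows (sorted by nutrient id for deterministic output)
    nutrient_coeffs: dict[str, np.ndarray] = {}
    for req in sorted(db.requirements, key=lambda r: r.nutrient_id):
        coeffs = np.array([f.nutrient_content.get(req.nutrient_id, 0.0) / 100.0 for f in foods])
        nutrient_coeffs[req.nutrient_id] = coeffs
        rows.append(
            LinearRow(
                name=f"nutrient:{req.nutrient_id}",
                coeffs={fid: c for fid, c in zip(included, coeffs) if c != 0.0},
                lower=req.min_mean,
                upper=req.max_mean,
            )
        )

    # category aggregates; per-member caps tighten variable bounds except
    # where a recipe forces a larger amount of a specific food
    for cc in scenario.category_constraints:
        members = [f.id for f in foods if cc.matches(f)]
        if cc.per_member_max is not None:
            for fid in members:
                i = pos[fid]
                if forced[i] and lower[i] > cc.per_member_max:
                    continue
                upper[i] = min(upper[i], cc.per_member_max)
        if cc.total_min is not None or cc.total_max is not None:
            if not members and cc.total_min is not None and cc.total_min > 0:
                raise CompilationError(
                    f"scenario '{scenario.id}': category constraint '{cc.name}' requires "
                    f">= {cc.total_min} g but matches no food in the database"
                )
            rows.append(
                LinearRow(
                    name=f"category:{cc.name}",
                    coeffs={fid: 1.0 for fid in members},
                    lower=cc.total_min,
                    upper=cc.total_max,
                )
            )

    if scenario.added_sugar_max is not None:
        sugar_ids = [f.id for f in foods if "added_sugar" in f.tags]
        if sugar_ids:
            rows.append(
                LinearRow(
                    name="added_sugar",
                    coeffs={fid: 1.0 for fid in sugar_ids},
                    upper=scenario.added_sugar_max,
                )
            )

    for lr in scenario.linked_ratios:
        rows.append(
            LinearRow(
                name=f"ratio:{lr.food_a}:{lr.food_b}",
                coeffs={lr.food_a: 1.0, lr.food_b: -lr.ratio_a_to_b},
                lower=0.0,
                upper=0.0,
            )
        )

    if scenario.objective == "min_ghg" and scenario.budget_cap is not None:
        rows.append(
            LinearRow(
                name="budget",
                coeffs={fid: c for fid, c in zip(included, cost_per_g)},
                upper=scenario.budget_cap,
            )
        )

    bad = [fid for i, fid in enumerate(included) if lower[i] > upper[i] + 1e-12]
    if bad:
        raise CompilationError(
            f"scenario '{scenario.id}': infeasible per-food bounds (min > max) for: "
            + ", ".join(bad)
        )

    semicont = np.array(
        [not f.is_condiment and not forced[i] for i, f in enumerate(foods)], dtype=bool
    )

    return ConstraintSystem(
        scenario_id=scenario.id,
        objective=scenario.objective,
        food_ids=included,
        cost_per_g=cost_per_g,
        ghg_per_g=ghg_per_g,
        lower=lower,
        upper=upper,
        rows=rows,
        nutrient_coeffs=nutrient_coeffs,
        semicontinuous=semicont,
        min_if_included=scenario.min_if_included,
    )
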