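"""Linear-programming diet solver with a minimum-quantity-if-included rule.

The core problem is the classical least-cost diet linear program: choose
grams per day of each food, minimizing daily cost (or daily GHG
emissions), subject to nutrient lower/upper bounds and scenario
constraints.  On top of the LP sits a semicontinuity rule — every
selected non-condiment food must reach a minimum daily amount (10 g by
default) or be left out entirely — which makes the exact problem a small
mixed-integer program.

Two strategies are provided:

* ``"milp"`` (default): exact semicontinuous solve via binary inclusion
  indicators (HiGHS branch-and-bound through :func:`scipy.optimize.milp`).
* ``"iterative"``: heuristic that solves the plain LP, fixes to zero every
  non-condiment food landing strictly between 0 and the minimum, and
  re-solves to a fixpoint.  Cheaper, but only an upper bound on the exact
  optimum; the MILP path is the oracle for it.

Both are deterministic for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .food_data import ENERGY_ID, FoodDatabase, purchased_weight
from .scenarios import CompilationError, ConstraintSystem, Scenario, compile_constraints

__all__ = [
    "DietSolution",
    "SolverError",
    "solve_lp",
    "optimize_diet",
    "evaluate_diet",
    "scale_to_energy",
]

#: Relative feasibility tolerance used when reporting binding constraints.
FEASIBILITY_RTOL = 1e-6
#: Grams below which a quantity is treated as exactly zero.
ZERO_G = 1e-7
#: Upper bound substituted for unbounded foods in the MILP linking rows.
BIG_M_G = 10_000.0
#: Maximum rounds of the iterative fix-to-zero heuristic.
MAX_ITERATIVE_ROUNDS = 20


class SolverError(RuntimeError):
    """The LP/MILP backend failed for a numerical reason."""


@dataclass
class DietSolution:
    """An optimized (or merely evaluated) daily diet.

    Quantities are grams edible per day.  ``cost`` is NZ$/day on purchased
    weight; ``ghg`` is kg CO2e/day on purchased weight; nutrient intakes
    are per day in each nutrient's canonical unit.  ``objective_value``
    repeats ``cost`` or ``ghg`` according to the scenario objective.
    """

    quantities: dict[str, float]
    objective_value: float
    cost: float
    ghg: float
    nutrient_intakes: dict[str, float]
    status: str  # optimal | infeasible | unbounded | evaluated
    binding_constraints: list[str] = field(default_factory=list)

    @property
    def n_foods_selected(self) -> int:
        return sum(1 for q in self.quantities.values() if q > ZERO_G)

    def total_grams(self) -> float:
        return float(sum(self.quantities.values()))


def _empty_solution(system: ConstraintSystem, status: str) -> DietSolution:
    return DietSolution(
        quantities={},
        objective_value=float("nan"),
        cost=float("nan"),
        ghg=float("nan"),
        nutrient_intakes={},
        status=status,
    )


def _solution_from_x(system: ConstraintSystem, x: np.ndarray) -> DietSolution:
    x = np.where(np.abs(x) < ZERO_G, 0.0, x)
    cost = float(system.cost_per_g @ x)
    ghg = float(system.ghg_per_g @ x)
    intakes = {nid: float(c @ x) for nid, c in system.nutrient_coeffs.items()}
    a, lb, ub = system.row_matrix()
    vals = a @ x
    binding = []
    for i, row in enumerate(system.rows):
        scale = max(1.0, abs(vals[i]))
        if np.isfinite(lb[i]) and abs(vals[i] - lb[i]) <= FEASIBILITY_RTOL * scale:
            binding.append(row.name)
        elif np.isfinite(ub[i]) and abs(vals[i] - ub[i]) <= FEASIBILITY_RTOL * scale:
            binding.append(row.name)
    objective = cost if system.objective == "min_cost" else ghg
    return DietSolution(
        quantities={fid: float(q) for fid, q in zip(system.food_ids, x)},
        objective_value=objective,
        cost=cost,
        ghg=ghg,
        nutrient_intakes=intakes,
        status="optimal",
        binding_constraints=binding,
    )


def solve_lp(
    system: ConstraintSystem,
    objective: np.ndarray | None = None,
    *,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> DietSolution:
    """Solve the plain LP relaxation of a compiled system.

    ``objective`` defaults to the scenario's cost or GHG vector; custom
    per-food bound overrides support the iterative semicontinuity
    heuristic.  Uses the HiGHS dual simplex, which is deterministic for a
    fixed system.
    """
    c = system.objective_vector() if objective is None else np.asarray(objective, dtype=float)
    lo = system.lower if lower is None else lower
    hi = system.upper if upper is None else upper
    a, lb, ub = system.row_matrix()

    a_ub_parts, b_ub_parts = [], []
    a_eq_parts, b_eq_parts = [], []
    for i in range(len(system.rows)):
        if np.isfinite(lb[i]) and np.isfinite(ub[i]) and lb[i] == ub[i]:
            a_eq_parts.append(a[i])
            b_eq_parts.append(lb[i])
            continue
        if np.isfinite(ub[i]):
            a_ub_parts.append(a[i])
            b_ub_parts.append(ub[i])
        if np.isfinite(lb[i]):
            a_ub_parts.append(-a[i])
            b_ub_parts.append(-lb[i])

    res = linprog(
        c,
        A_ub=np.array(a_ub_parts) if a_ub_parts else None,
        b_ub=np.array(b_ub_parts) if b_ub_parts else None,
        A_eq=np.array(a_eq_parts) if a_eq_parts else None,
        b_eq=np.array(b_eq_parts) if b_eq_parts else None,
        bounds=np.column_stack([lo, hi]),
        method="highs-ds",
    )
    if res.status == 2:
        return _empty_solution(system, "infeasible")
    if res.status == 3:
        return _empty_solution(system, "unbounded")
    if not res.success:
        raise SolverError(
            f"LP solve failed for scenario '{system.scenario_id}': {res.message} "
            f"(n_foods={system.n_foods}, n_rows={len(system.rows)})"
        )
    return _solution_from_x(system, res.x)


def _solve_semicontinuous_milp(system: ConstraintSystem) -> DietSolution:
    n = system.n_foods
    semi = system.semicontinuous & (system.min_if_included > 0)
    idx = np.flatnonzero(semi)
    m = len(idx)
    if m == 0:
        return solve_lp(system)

    # variables: x (grams, n) then y (inclusion binaries, m)
    c = np.concatenate([system.objective_vector(), np.zeros(m)])
    a, lb, ub = system.row_matrix()
    a_full = np.hstack([a, np.zeros((a.shape[0], m))]) if len(system.rows) else np.zeros((0, n + m))
    constraints = []
    if len(system.rows):
        constraints.append(LinearConstraint(a_full, lb, ub))

    # linking: x_i - U_i y_i <= 0 and x_i - min * y_i >= 0
    link_upper = np.zeros((m, n + m))
    link_lower = np.zeros((m, n + m))
    for k, i in enumerate(idx):
        cap = system.upper[i] if np.isfinite(system.upper[i]) else BIG_M_G
        link_upper[k, i] = 1.0
        link_upper[k, n + k] = -cap
        link_lower[k, i] = 1.0
        link_lower[k, n + k] = -system.min_if_included
    constraints.append(LinearConstraint(link_upper, -np.inf, 0.0))
    constraints.append(LinearConstraint(link_lower, 0.0, np.inf))

    var_lb = np.concatenate([system.lower, np.zeros(m)])
    var_ub = np.concatenate(
        [np.where(np.isfinite(system.upper), system.upper, BIG_M_G), np.ones(m)]
    )
    integrality = np.concatenate([np.zeros(n), np.ones(m)])

    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
        options={"mip_rel_gap": 1e-9},
    )
    if res.status == 2:
        return _empty_solution(system, "infeasible")
    if not res.success:
        raise SolverError(
            f"MILP solve failed for scenario '{system.scenario_id}': {res.message}"
        )
    x = np.asarray(res.x[:n])
    # snap sub-threshold numerical residue on switched-off foods to zero
    y = np.round(res.x[n:])
    for k, i in enumerate(idx):
        if y[k] == 0:
            x[i] = 0.0
    return _solution_from_x(system, x)


def _solve_semicontinuous_iterative(system: ConstraintSystem) -> DietSolution:
    lo = system.lower.copy()
    hi = system.upper.copy()
    threshold = system.min_if_included
    sol = solve_lp(system, lower=lo, upper=hi)
    for _ in range(MAX_ITERATIVE_ROUNDS):
        if sol.status != "optimal":
            return sol
        x = np.array([sol.quantities[fid] for fid in system.food_ids])
        violators = system.semicontinuous & (x > ZERO_G) & (x < threshold - 1e-9)
        if not violators.any():
            return sol
        trial = solve_lp(system, lower=lo, upper=np.where(violators, 0.0, hi))
        if trial.status == "optimal":
            hi = np.where(violators, 0.0, hi)
            sol = trial
        else:
            # the diet needs these foods: round them up to the threshold
            lo = np.where(violators, threshold, lo)
            sol = solve_lp(system, lower=lo, upper=hi)
    return sol  # fixpoint not reached within the round cap; last iterate


def _dispatch(system: ConstraintSystem, strategy: str) -> DietSolution:
    if strategy == "milp":
        return _solve_semicontinuous_milp(system)
    if strategy == "iterative":
        return _solve_semicontinuous_iterative(system)
    if strategy == "lp":
        return solve_lp(system)
    raise ValueError(f"unknown strategy '{strategy}' (expected 'milp', 'iterative' or 'lp')")


def _relax_adjustable_minima(
    db: FoodDatabase, scenario: Scenario, strategy: str
) -> DietSolution | None:
    """Lower adjustable minima (cooking salt) to the largest feasible amount.

    The stated salt-in-cooking amounts are desiderata that yield to the
    always-active sodium cap: for each adjustable food we maximize its
    quantity over the system without its own minimum, then re-impose
    ``min(stated, feasible)`` with a hair of slack for the semicontinuous
    re-solve.
    """
    from dataclasses import replace

    adjustable = [
        fid
        for fid in scenario.adjustable_min_ids
        if scenario.per_food_min.get(fid, 0.0) > 0.0 and fid in db
    ]
    if not adjustable:
        return None
    stripped = replace(
        scenario,
        per_food_min={k: v for k, v in scenario.per_food_min.items() if k not in adjustable},
    )
    system = compile_constraints(stripped, db)
    new_minima = dict(stripped.per_food_min)
    for fid in adjustable:
        if fid not in system.food_ids:
            continue
        c = np.zeros(system.n_foods)
        c[system.index(fid)] = -1.0  # maximize this food
        probe = solve_lp(system, c)
        if probe.status != "optimal":
            return probe  # infeasible without the salt minimum too
        feasible = max(0.0, 0.999 * probe.quantities[fid])
        if feasible > ZERO_G:
            new_minima[fid] = min(scenario.per_food_min[fid], feasible)
    relaxed = replace(stripped, per_food_min=new_minima)
    return _dispatch(compile_constraints(relaxed, db), strategy)


def optimize_diet(
    db: FoodDatabase, scenario: Scenario, strategy: str = "milp"
) -> DietSolution:
    """Solve a scenario over a database, honoring the min-if-included rule.

    In a returned optimal solution every non-condiment food without an
    explicit recipe minimum is either 0 g or at least
    ``scenario.min_if_included`` grams.  When forced cooking-salt amounts
    collide with the sodium cap they are lowered to the largest feasible
    amount (see :func:`_relax_adjustable_minima`).
    """
    system = compile_constraints(scenario, db)
    sol = _dispatch(system, strategy)
    if sol.status == "infeasible":
        relaxed = _relax_adjustable_minima(db, scenario, strategy)
        if relaxed is not None:
            return relaxed
    return sol


def evaluate_diet(db: FoodDatabase, quantities: dict[str, float]) -> DietSolution:
    """Cost, emissions and nutrient intakes of a fixed food composition.

    No constraints are checked; this is the comparator path used e.g. for
    the typical-diet estimate.  ``status`` is ``"evaluated"``.
    """
    cost = 0.0
    ghg = 0.0
    intakes: dict[str, float] = {nid: 0.0 for nid in db.nutrient_ids}
    for fid, grams in quantities.items():
        food = db.food(fid)  # raises KeyError for unknown ids
        if grams < 0:
            raise ValueError(f"negative quantity for '{fid}'")
        bought = purchased_weight(grams, food.wastage_mean)
        cost += bought * food.price_mean / 100.0
        ghg += bought * food.ghg_factor / 1000.0
        for nid, per100 in food.nutrient_content.items():
            intakes[nid] = intakes.get(nid, 0.0) + grams * per100 / 100.0
    return DietSolution(
        quantities=dict(quantities),
        objective_value=cost,
        cost=cost,
        ghg=ghg,
        nutrient_intakes=intakes,
        status="evaluated",
    )


def scale_to_energy(
    quantities: dict[str, float], db: FoodDatabase, target_kj: float
) -> dict[str, float]:
    """Rescale a diet so its total energy equals ``target_kj``."""
    current = sum(
        grams * db.food(fid).nutrient_content.get(ENERGY_ID, 0.0) / 100.0
        for fid, grams in quantities.items()
    )
    if current <= 0:
        raise ValueError("cannot scale a zero-energy diet")
    factor = target_kj / current
    return {fid: grams * factor for fid, grams in quantities.items()}
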