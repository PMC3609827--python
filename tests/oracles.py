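"""Independent brute-force oracles for the diet LP.

These never call the package's solver paths: vertex enumeration solves
the LP by checking every basic solution, and the semicontinuous variant
enumerates food subsets on top.  Only usable at toy sizes (<= 5 foods,
<= 4 nutrient rows), which is exactly their job.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from dietopt import FoodDatabase, FoodItem, NutrientRequirement, Scenario

FEAS_TOL = 1e-7


def vertex_enumeration_lp(
    c: np.ndarray, a_ge: np.ndarray, b_ge: np.ndarray, xlb: np.ndarray
) -> tuple[float, np.ndarray] | None:
    """Minimize c.x s.t. a_ge x >= b_ge, x >= xlb by basic-solution enumeration.

    Returns (objective, x) or None if infeasible.  Assumes the problem is
    bounded (all c >= 0 and constraints are lower bounds).
    """
    n = len(c)
    # halfspaces in >= form: rows of a_ge, and identity rows for x_i >= xlb_i
    halfspace_a = np.vstack([a_ge, np.eye(n)])
    halfspace_b = np.concatenate([b_ge, xlb])
    m = len(halfspace_b)
    best: tuple[float, np.ndarray] | None = None
    for combo in combinations(range(m), n):
        a_sq = halfspace_a[list(combo)]
        b_sq = halfspace_b[list(combo)]
        try:
            x = np.linalg.solve(a_sq, b_sq)
        except np.linalg.LinAlgError:
            continue
        slack = halfspace_a @ x - halfspace_b
        if slack.min() < -FEAS_TOL * max(1.0, np.abs(halfspace_b).max()):
            continue
        val = float(c @ x)
        if best is None or val < best[0] - 1e-12:
            best = (val, x)
    return best


def semicontinuous_brute_force(
    c: np.ndarray,
    a_ge: np.ndarray,
    b_ge: np.ndarray,
    min_included: float,
) -> tuple[float, np.ndarray] | None:
    """Exact optimum under the each-food-0-or->=min rule by subset enumeration."""
    n = len(c)
    best: tuple[float, np.ndarray] | None = None
    for mask in range(2**n):
        keep = [(mask >> i) & 1 for i in range(n)]
        idx = [i for i in range(n) if keep[i]]
        if not idx:
            if (b_ge <= FEAS_TOL).all():
                cand = (0.0, np.zeros(n))
                if best is None or cand[0] < best[0]:
                    best = cand
            continue
        sub = vertex_enumeration_lp(
            c[idx],
            a_ge[:, idx],
            b_ge,
            np.full(len(idx), min_included),
        )
        if sub is None:
            continue
        x = np.zeros(n)
        x[idx] = sub[1]
        if best is None or sub[0] < best[0] - 1e-12:
            best = (sub[0], x)
    return best


def random_instance(rng: np.random.Generator):
    """A random feasible 3-5-food, 1-4-nutrient-minimum cost instance.

    Returns (db, scenario, c, a_ge, b_ge) where the matrix form matches the
    compiled system's food order (sorted ids).
    """
    n = int(rng.integers(3, 6))
    k = int(rng.integers(1, 5))
    ids = [f"f{i}" for i in range(n)]  # already sorted
    prices = rng.uniform(0.2, 2.0, n)
    wastage = rng.uniform(0.0, 0.5, n)
    contents = rng.uniform(0.0, 30.0, (k, n))
    nutrient_ids = [f"n{j}" for j in range(k)]
    # choose minima reachable from a reference diet so the instance is feasible
    x_ref = rng.uniform(20.0, 300.0, n)
    minima = (contents / 100.0 @ x_ref) * rng.uniform(0.5, 0.9, k)
    items = [
        FoodItem(
            id=ids[i],
            name=ids[i],
            category="other",
            price_mean=float(prices[i]),
            wastage_mean=float(wastage[i]),
            ghg_factor=1.0,
            nutrient_content={nutrient_ids[j]: float(contents[j, i]) for j in range(k)},
        )
        for i in range(n)
    ]
    reqs = [
        NutrientRequirement(nutrient_ids[j], "g", min_mean=float(minima[j])) for j in range(k)
    ]
    db = FoodDatabase(items=items, requirements=reqs).validate()
    scenario = Scenario(id="random", objective="min_cost")
    c = prices / (100.0 * (1.0 - wastage))
    return db, scenario, c, contents / 100.0, minima
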