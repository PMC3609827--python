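"""Monte Carlo engine over prices, nutrients, wastage and requirements.

Each simulation draw perturbs the database (a "world") and re-runs the
optimizer, so the spread of the optima reflects parameter uncertainty and
population heterogeneity rather than sampling noise in a fixed diet:

* prices — gamma distributions matched by moments to the mean and the
  month-to-month SD; foods without a price SD borrow the median price CV
  of their category;
* nutrient contents — normal with SD equal to 5% of the mean (variety,
  brand, freshness), truncated at zero;
* wastage fractions — beta distributions matched by moments;
* requirement minima — normal with the requirement's heterogeneity SD,
  truncated at zero; the daily energy target is normal(11,450, 184.4) kJ.

All perturbations are independent across foods and nutrients.  Summaries
report the mean, median and the central 95% simulation interval (SI,
2.5th–97.5th percentile) of every output over the feasible draws;
infeasible draws are counted, not redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from statistics import median as _median

import numpy as np

from .food_data import ENERGY_ID, FoodDatabase
from .optimizer import optimize_diet
from .scenarios import Scenario

__all__ = [
    "UncertaintySpec",
    "OutputSummary",
    "SimulationSummary",
    "SimulationError",
    "fit_gamma_moments",
    "fit_beta_moments",
    "sample_world",
    "run_simulation",
]


class SimulationError(RuntimeError):
    """No feasible draw was produced."""


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma ``(shape, scale)`` with the given mean and SD.

    ``shape = mean^2 / sd^2`` and ``scale = sd^2 / mean``.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"mean and sd must be positive, got mean={mean}, sd={sd}")
    return (mean * mean) / (sd * sd), (sd * sd) / mean


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta ``(alpha, beta)`` with the given mean and SD.

    Valid only when ``sd^2 < mean (1 - mean)``; with
    ``nu = mean(1-mean)/sd^2 - 1``, ``alpha = mean nu`` and
    ``beta = (1-mean) nu``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    limit = mean * (1.0 - mean)
    if sd * sd >= limit:
        raise ValueError(
            f"sd too large for a beta distribution: need sd^2 < mean(1-mean) = {limit:.6g}, "
            f"got sd^2 = {sd * sd:.6g}"
        )
    nu = limit / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class UncertaintySpec:
    """Configuration of the Monte Carlo engine."""

    n_iterations: int = 2000
    seed: int = 0
    nutrient_cv: float = 0.05  # SD as a fraction of each nutrient mean
    energy_target_mean: float = 11_450.0  # kJ/day
    energy_target_sd: float = 184.4  # kJ/day
    sample_prices: bool = True
    sample_nutrients: bool = True
    sample_wastage: bool = True
    sample_requirements: bool = True
    strategy: str = "milp"  # solver strategy for each draw

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.nutrient_cv < 0:
            raise ValueError("nutrient_cv must be >= 0")


def _category_price_cvs(db: FoodDatabase) -> dict[str, float]:
    by_cat: dict[str, list[float]] = {}
    for f in db.items:
        if f.price_sd is not None and f.price_sd > 0 and f.price_mean > 0:
            by_cat.setdefault(f.category, []).append(f.price_sd / f.price_mean)
    return {cat: _median(cvs) for cat, cvs in by_cat.items()}


def sample_world(db: FoodDatabase, spec: UncertaintySpec, draw_index: int) -> FoodDatabase:
    """Return one perturbed copy of the database.

    Reproducible from ``(spec.seed, draw_index)``; the original database
    is untouched.  Degenerate inputs (zero SDs) pass through unchanged.
    """
    rng = np.random.default_rng((int(spec.seed), int(draw_index)))
    fallback_cv = _category_price_cvs(db)

    items = []
    for f in db.items:
        price = f.price_mean
        if spec.sample_prices:
            sd = f.price_sd
            if sd is None:
                cv = fallback_cv.get(f.category)
                sd = cv * f.price_mean if cv is not None else 0.0
            if sd > 0:
                shape, scale = fit_gamma_moments(f.price_mean, sd)
                price = float(rng.gamma(shape, scale))

        nutrients = dict(f.nutrient_content)
        if spec.sample_nutrients and spec.nutrient_cv > 0:
            for nid, mean in nutrients.items():
                if mean > 0:
                    nutrients[nid] = max(0.0, float(rng.normal(mean, spec.nutrient_cv * mean)))

        wastage = f.wastage_mean
        if spec.sample_wastage and f.wastage_sd > 0 and 0.0 < f.wastage_mean < 1.0:
            alpha, beta = fit_beta_moments(f.wastage_mean, f.wastage_sd)
            wastage = float(rng.beta(alpha, beta))

        items.append(
            replace(f, price_mean=price, nutrient_content=nutrients, wastage_mean=wastage)
        )

    reqs = []
    for r in db.requirements:
        new_min = r.min_mean
        if spec.sample_requirements and new_min is not None:
            if r.nutrient_id == ENERGY_ID and spec.energy_target_sd > 0:
                new_min = max(
                    0.0, float(rng.normal(spec.energy_target_mean, spec.energy_target_sd))
                )
            elif r.heterogeneity_sd > 0:
                new_min = max(0.0, float(rng.normal(new_min, r.heterogeneity_sd)))
            if r.max_mean is not None:
                new_min = min(new_min, r.max_mean)  # keep the bound pair consistent
        reqs.append(replace(r, min_mean=new_min))

    return FoodDatabase(items=items, requirements=reqs, metadata=dict(db.metadata))


@dataclass
class OutputSummary:
    """Mean, median and central 95% simulation interval of one output."""

    mean: float
    median: float
    lower95: float
    upper95: float

    @classmethod
    def from_draws(cls, values: np.ndarray) -> "OutputSummary":
        lo, mid, hi = np.percentile(values, [2.5, 50.0, 97.5])  # inclusive linear interp
        return cls(mean=float(np.mean(values)), median=float(mid), lower95=float(lo), upper95=float(hi))

    @classmethod
    def ratio_of(cls, num: "OutputSummary", den: "OutputSummary") -> "OutputSummary":
        """Statistic-wise ratio (ratio of means, of medians, of SI bounds)."""

        def div(a: float, b: float) -> float:
            return a / b if b != 0 else math.inf

        return cls(
            mean=div(num.mean, den.mean),
            median=div(num.median, den.median),
            lower95=div(num.lower95, den.lower95),
            upper95=div(num.upper95, den.upper95),
        )


@dataclass
class SimulationSummary:
    """Per-output summaries over the feasible Monte Carlo draws.

    Output keys: ``objective``, ``cost``, ``ghg``, ``fruit_veg_g``,
    ``nutrient:<id>``, ``food:<id>``, ``total_g``, and the statistic-wise
    ratios ``ratio:pufa_sat_fat`` and ``ratio:potassium_sodium`` where the
    ingredients exist.
    """

    scenario_id: str
    n_iterations: int
    n_feasible: int
    n_infeasible: int
    outputs: dict[str, OutputSummary]
    draws: "object | None" = None  # optional per-draw DataFrame


def run_simulation(
    db: FoodDatabase,
    scenario: Scenario,
    spec: UncertaintySpec,
    *,
    keep_draws: bool = False,
) -> SimulationSummary:
    """Optimize the scenario on ``spec.n_iterations`` perturbed worlds.

    Infeasible draws are excluded from the summaries and counted in
    ``n_infeasible``.  Fully deterministic given ``(db, scenario, spec)``.
    """
    import pandas as pd

    fv_ids = {
        f.id for f in db.items if ("vegetable" in f.tags or "fruit" in f.tags)
    }
    records: list[dict[str, float]] = []
    n_infeasible = 0
    for k in range(spec.n_iterations):
        world = sample_world(db, spec, k)
        sol = optimize_diet(world, scenario, strategy=spec.strategy)
        if sol.status != "optimal":
            n_infeasible += 1
            continue
        rec: dict[str, float] = {
            "draw": k,
            "objective": sol.objective_value,
            "cost": sol.cost,
            "ghg": sol.ghg,
            "total_g": sol.total_grams(),
            "fruit_veg_g": sum(sol.quantities.get(fid, 0.0) for fid in fv_ids),
        }
        for nid, v in sol.nutrient_intakes.items():
            rec[f"nutrient:{nid}"] = v
        for fid in db.food_ids:
            rec[f"food:{fid}"] = sol.quantities.get(fid, 0.0)
        records.append(rec)

    if not records:
        raise SimulationError(
            f"scenario '{scenario.id}': all {spec.n_iterations} draws were infeasible"
        )

    frame = pd.DataFrame.from_records(records).set_index("draw")
    outputs = {col: OutputSummary.from_draws(frame[col].to_numpy()) for col in frame.columns}
    if "nutrient:pufa" in outputs and "nutrient:sat_fat" in outputs:
        outputs["ratio:pufa_sat_fat"] = OutputSummary.ratio_of(
            outputs["nutrient:pufa"], outputs["nutrient:sat_fat"]
        )
    if "nutrient:potassium" in outputs and "nutrient:sodium" in outputs:
        outputs["ratio:potassium_sodium"] = OutputSummary.ratio_of(
            outputs["nutrient:potassium"], outputs["nutrient:sodium"]
        )

    return SimulationSummary(
        scenario_id=scenario.id,
        n_iterations=spec.n_iterations,
        n_feasible=len(records),
        n_infeasible=n_infeasible,
        outputs=outputs,
        draws=frame if keep_draws else None,
    )
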