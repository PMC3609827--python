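"""Run configuration and paper-shaped report outputs.

:func:`run_scenarios` drives the whole pipeline for a set of scenarios
and writes:

* ``scenario_table.csv`` — outputs as rows, scenarios as columns, with
  the objective cell of each scenario flagged with ``*``;
* ``cost_ghg_points.csv`` — one (cost, GHG) point per scenario plus the
  typical-diet comparator, for a cost-versus-emissions scatter;
* ``simulation_<id>.csv`` / ``draws_<id>.csv`` — per-output summary and
  per-draw values when uncertainty is on;
* ``summary.json`` — machine-readable bundle every table cell can be
  recomputed from (rounding happens only in the CSVs);
* ``run.log`` — seed, resolved configuration and per-scenario status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .food_data import FoodDatabase, load_food_database
from .optimizer import DietSolution, evaluate_diet, optimize_diet
from .scenarios import BUILTIN_SCENARIO_IDS, Scenario, builtin_scenario, load_scenario
from .synthetic import GeneratorConfig, generate_food_database, generate_typical_diet
from .uncertainty import SimulationSummary, UncertaintySpec, run_simulation

__all__ = ["RunConfig", "ReportBundle", "run_scenarios"]

logger = logging.getLogger("dietopt")

#: Reporting precision: money to cents, emissions to 0.01 kg, grams and
#: intakes to one decimal.  Applied only when writing CSVs.
_ROUND = {"cost": 2, "ghg": 2, "objective": 2}


@dataclass
class RunConfig:
    """Everything one reporting run needs."""

    database_path: str | None = None  # None -> synthetic
    synthetic_seed: int = 0
    scenario_ids: tuple[str, ...] = BUILTIN_SCENARIO_IDS
    scenario_files: tuple[str, ...] = ()  # extra user YAML scenarios
    uncertainty: bool = False
    n_iterations: int = 2000
    simulation_seed: int = 0
    strategy: str = "milp"
    match_paper: bool = False  # e.g. G1 budget cap 4.99 instead of 5.00
    include_typical_diet: bool = True
    output_dir: str = "dietopt_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.scenario_ids and not self.scenario_files:
            raise ValueError("at least one scenario is required")


@dataclass
class ReportBundle:
    """In-memory results plus the paths written."""

    database: FoodDatabase
    solutions: dict[str, DietSolution]
    simulations: dict[str, SimulationSummary]
    typical_diet: DietSolution | None
    failures: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def all_failed(self) -> bool:
        return not self.solutions


def _resolve_database(config: RunConfig) -> FoodDatabase:
    if config.database_path is not None:
        return load_food_database(config.database_path)
    return generate_food_database(GeneratorConfig(seed=config.synthetic_seed))


def _resolve_scenarios(config: RunConfig) -> list[Scenario]:
    out = [builtin_scenario(sid, match_paper=config.match_paper) for sid in config.scenario_ids]
    out.extend(load_scenario(p) for p in config.scenario_files)
    return out


def _solution_record(sol: DietSolution, db: FoodDatabase) -> dict[str, float]:
    fv = sum(
        g
        for fid, g in sol.quantities.items()
        if {"vegetable", "fruit"} & db.food(fid).tags
    )
    rec = {
        "cost": sol.cost,
        "ghg": sol.ghg,
        "fruit_veg_g": fv,
        "total_g": sol.total_grams(),
        "n_foods_selected": sol.n_foods_selected,
    }
    for nid, v in sol.nutrient_intakes.items():
        rec[f"nutrient:{nid}"] = v
    if sol.nutrient_intakes.get("sat_fat"):
        rec["ratio:pufa_sat_fat"] = sol.nutrient_intakes.get("pufa", 0.0) / sol.nutrient_intakes["sat_fat"]
    if sol.nutrient_intakes.get("sodium"):
        rec["ratio:potassium_sodium"] = (
            sol.nutrient_intakes.get("potassium", 0.0) / sol.nutrient_intakes["sodium"]
        )
    return rec


def _write_scenario_table(
    path: Path, solutions: dict[str, DietSolution], db: FoodDatabase
) -> None:
    cols = {}
    for sid, sol in solutions.items():
        rec = _solution_record(sol, db)
        objective_key = "cost" if sol.objective_value == sol.cost else "ghg"
        cells = {}
        for key, v in rec.items():
            digits = _ROUND.get(key, 1)
            text = f"{round(v, digits):.{digits}f}"
            if key == objective_key:
                text += "*"
            cells[key] = text
        cols[sid] = cells
    frame = pd.DataFrame(cols)
    frame.index.name = "output"
    frame.to_csv(path)


def _config_hash(config: RunConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("output_dir", None)  # where results land does not change them
    fields.pop("log_level", None)
    blob = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_scenarios(config: RunConfig) -> ReportBundle:
    """Solve (and optionally simulate) every configured scenario.

    Per-scenario failures are recorded and do not abort the run; the
    bundle's ``all_failed`` flag is the caller's exit-code signal.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_lines = [
        f"config_hash={_config_hash(config)}",
        f"synthetic_seed={config.synthetic_seed}",
        f"simulation_seed={config.simulation_seed}",
        f"strategy={config.strategy}",
        f"match_paper={config.match_paper}",
    ]

    db = _resolve_database(config)
    scenarios = _resolve_scenarios(config)

    solutions: dict[str, DietSolution] = {}
    simulations: dict[str, SimulationSummary] = {}
    failures: dict[str, str] = {}
    for scenario in scenarios:
        log_lines.append(f"scenario={scenario.id} resolved={dataclasses.asdict(scenario)}")
        try:
            sol = optimize_diet(db, scenario, strategy=config.strategy)
        except Exception as exc:  # noqa: BLE001 — recorded per scenario
            failures[scenario.id] = str(exc)
            logger.error("scenario %s failed: %s", scenario.id, exc)
            continue
        if sol.status != "optimal":
            failures[scenario.id] = f"status={sol.status}"
            log_lines.append(f"scenario={scenario.id} status={sol.status}")
            continue
        solutions[scenario.id] = sol
        log_lines.append(
            f"scenario={scenario.id} status=optimal objective={sol.objective_value:.6f} "
            f"n_foods={sol.n_foods_selected}"
        )
        if config.uncertainty:
            spec = UncertaintySpec(
                n_iterations=config.n_iterations,
                seed=config.simulation_seed,
                strategy=config.strategy,
            )
            sim = run_simulation(db, scenario, spec, keep_draws=True)
            simulations[scenario.id] = sim
            log_lines.append(
                f"scenario={scenario.id} sim_feasible={sim.n_feasible} "
                f"sim_infeasible={sim.n_infeasible}"
            )

    typical = None
    if config.include_typical_diet:
        try:
            typical = evaluate_diet(db, generate_typical_diet(db))
        except Exception as exc:  # noqa: BLE001
            failures["typical_diet"] = str(exc)

    paths: dict[str, Path] = {}

    table_path = out_dir / "scenario_table.csv"
    _write_scenario_table(table_path, solutions, db)
    paths["scenario_table"] = table_path

    points = [
        {"scenario": sid, "cost_nzd_per_day": round(s.cost, 2), "ghg_kgco2e_per_day": round(s.ghg, 2)}
        for sid, s in solutions.items()
    ]
    if typical is not None:
        points.append(
            {
                "scenario": "typical_diet",
                "cost_nzd_per_day": round(typical.cost, 2),
                "ghg_kgco2e_per_day": round(typical.ghg, 2),
            }
        )
    points_path = out_dir / "cost_ghg_points.csv"
    pd.DataFrame(points).to_csv(points_path, index=False)
    paths["cost_ghg_points"] = points_path

    for sid, sim in simulations.items():
        rows = [
            {
                "output": key,
                "mean": s.mean,
                "median": s.median,
                "lower95": s.lower95,
                "upper95": s.upper95,
            }
            for key, s in sim.outputs.items()
        ]
        sim_path = out_dir / f"simulation_{sid}.csv"
        pd.DataFrame(rows).to_csv(sim_path, index=False, float_format="%.6g")
        paths[f"simulation_{sid}"] = sim_path
        if sim.draws is not None:
            draws_path = out_dir / f"draws_{sid}.csv"
            sim.draws.to_csv(draws_path, float_format="%.6g")
            paths[f"draws_{sid}"] = draws_path

    summary = {
        "config_hash": _config_hash(config),
        "database_metadata": db.metadata,
        "scenarios": {
            sid: {
                "status": sol.status,
                "objective": sol.objective_value,
                "cost": sol.cost,
                "ghg": sol.ghg,
                "nutrient_intakes": sol.nutrient_intakes,
                "quantities": {k: v for k, v in sol.quantities.items() if v > 0},
                "binding_constraints": sol.binding_constraints,
            }
            for sid, sol in solutions.items()
        },
        "simulations": {
            sid: {
                "n_feasible": sim.n_feasible,
                "n_infeasible": sim.n_infeasible,
                "outputs": {
                    key: dataclasses.asdict(s) for key, s in sim.outputs.items()
                },
            }
            for sid, sim in simulations.items()
        },
        "typical_diet": None
        if typical is None
        else {
            "cost": typical.cost,
            "ghg": typical.ghg,
            "nutrient_intakes": typical.nutrient_intakes,
        },
        "failures": failures,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
    paths["summary"] = summary_path

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    paths["run_log"] = log_path

    return ReportBundle(
        database=db,
        solutions=solutions,
        simulations=simulations,
        typical_diet=typical,
        failures=failures,
        paths=paths,
    )
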