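"""Food and nutrient-requirement data model, validation, and I/O.

Unit conventions used throughout the package:

* nutrient contents are stored **per 100 g edible (prepared, ready-to-eat)
  weight**;
* prices are NZ$ **per 100 g purchased** weight;
* greenhouse-gas (GHG) factors are kg CO2e **per kg purchased** weight;
* the wastage fraction is the share of purchased weight that is never
  eaten (inedible portions plus discarded edible food), so
  ``purchased = edible / (1 - wastage)``.

Daily diets are expressed as grams edible per day.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CATEGORIES",
    "TAGS",
    "CANONICAL_UNITS",
    "ENERGY_ID",
    "FoodItem",
    "NutrientRequirement",
    "FoodDatabase",
    "DatabaseValidationError",
    "SchemaError",
    "load_food_database",
    "save_food_database",
    "purchased_weight",
    "combine_wastage",
]

#: Recognised food categories.
CATEGORIES = frozenset(
    {
        "fruit_veg",
        "cereal_grain",
        "pulse_seed_nut",
        "dairy",
        "meat_fish_egg",
        "fat_oil",
        "condiment",
        "other",
    }
)

#: Canonical tag vocabulary. Tags drive scenario exclusions and aggregate
#: constraints; extra user-defined tags are permitted.
TAGS = frozenset(
    {
        "vegetable",
        "starchy_root",
        "fruit",
        "nut",
        "juice",
        "animal_product",
        "dairy_product",
        "fish",
        "meat",
        "egg",
        "requires_cooking_skill",
        "condiment_exempt_from_min",
        "added_sugar",
    }
)

#: Fixed unit per nutrient id. Loaders reject any other unit for these ids
#: rather than converting silently.
CANONICAL_UNITS: dict[str, str] = {
    "energy": "kJ",
    "protein": "g",
    "fiber": "g",
    "pufa": "g",
    "sat_fat": "g",
    "sodium": "mg",
    "potassium": "mg",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "selenium": "ug",
    "vitamin_a": "ug RE",
    "thiamine": "mg",
    "vitamin_c": "mg",
    "vitamin_e": "mg",
}

ENERGY_ID = "energy"

#: Hard ceiling on the wastage fraction; beyond this a food is essentially
#: not purchasable as nourishment and is treated as a data error.
MAX_WASTAGE = 0.95


class DatabaseValidationError(ValueError):
    """Raised with the full list of invariant violations found in a database."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid food database (%d problem%s):\n  - %s"
            % (len(problems), "s" if len(problems) != 1 else "", "\n  - ".join(problems))
        )


class SchemaError(ValueError):
    """Raised when an input file does not match the documented schema."""


def purchased_weight(edible_g: float, wastage: float) -> float:
    """Purchased grams needed to obtain ``edible_g`` grams eaten.

    ``wastage`` is the fraction of purchased weight lost to inedible
    portions and waste, so the purchased amount is ``edible / (1 - w)``.
    """
    if edible_g < 0:
        raise ValueError(f"edible_g must be >= 0, got {edible_g}")
    if not 0.0 <= wastage <= MAX_WASTAGE:
        raise ValueError(f"wastage must be in [0, {MAX_WASTAGE}], got {wastage}")
    return edible_g / (1.0 - wastage)


def combine_wastage(inedible_fraction: float, waste_fraction: float) -> float:
    """Combine an inedible-portion fraction and a discard fraction.

    The two losses act multiplicatively on the purchased weight:
    ``1 - (1 - inedible)(1 - waste)``.  Provided for databases that store
    the two sources separately; the canonical :class:`FoodItem` field is a
    single effective fraction.
    """
    for name, f in (("inedible_fraction", inedible_fraction), ("waste_fraction", waste_fraction)):
        if not 0.0 <= f < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {f}")
    return 1.0 - (1.0 - inedible_fraction) * (1.0 - waste_fraction)


@dataclass
class FoodItem:
    """One food: price, nutrient profile, wastage, GHG factor and tags."""

    id: str
    name: str
    category: str
    price_mean: float  # NZ$ per 100 g purchased
    wastage_mean: float  # fraction of purchased weight not consumed
    ghg_factor: float  # kg CO2e per kg purchased
    nutrient_content: dict[str, float] = field(default_factory=dict)  # per 100 g edible
    price_sd: float | None = None  # NZ$ per 100 g (monthly variation); None = unknown
    wastage_sd: float = 0.0
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.tags = frozenset(self.tags)

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags

    @property
    def is_condiment(self) -> bool:
        return "condiment_exempt_from_min" in self.tags

    def problems(self) -> list[str]:
        out = []
        if not self.id:
            out.append("food with empty id")
        if self.category not in CATEGORIES:
            out.append(f"food '{self.id}': unknown category '{self.category}'")
        if not self.price_mean > 0:
            out.append(f"food '{self.id}': price_mean must be > 0, got {self.price_mean}")
        if self.price_sd is not None and self.price_sd < 0:
            out.append(f"food '{self.id}': price_sd must be >= 0")
        if not 0.0 <= self.wastage_mean <= MAX_WASTAGE:
            out.append(
                f"food '{self.id}': wastage_mean must be in [0, {MAX_WASTAGE}], "
                f"got {self.wastage_mean}"
            )
        if self.wastage_sd < 0:
            out.append(f"food '{self.id}': wastage_sd must be >= 0")
        if self.ghg_factor < 0:
            out.append(f"food '{self.id}': ghg_factor must be >= 0")
        for nid, amount in self.nutrient_content.items():
            if amount < 0 or not math.isfinite(amount):
                out.append(f"food '{self.id}': nutrient '{nid}' amount {amount} invalid")
        return out


@dataclass
class NutrientRequirement:
    """Daily lower/upper bound for one nutrient with a heterogeneity SD.

    ``min_mean`` is typically an estimated average requirement (EAR);
    ``heterogeneity_sd`` captures between-person variation in the
    requirement (body size, activity level) and feeds the Monte Carlo
    engine.
    """

    nutrient_id: str
    unit: str
    min_mean: float | None = None
    max_mean: float | None = None
    heterogeneity_sd: float = 0.0

    def problems(self) -> list[str]:
        out = []
        if self.min_mean is None and self.max_mean is None:
            out.append(f"requirement '{self.nutrient_id}': needs at least one of min/max")
        if (
            self.min_mean is not None
            and self.max_mean is not None
            and self.min_mean > self.max_mean
        ):
            out.append(
                f"requirement '{self.nutrient_id}': min {self.min_mean} > max {self.max_mean}"
            )
        if self.heterogeneity_sd < 0:
            out.append(f"requirement '{self.nutrient_id}': heterogeneity_sd must be >= 0")
        canonical = CANONICAL_UNITS.get(self.nutrient_id)
        if canonical is not None and self.unit != canonical:
            out.append(
                f"requirement '{self.nutrient_id}': unit must be '{canonical}', got '{self.unit}'"
            )
        return out


@dataclass
class FoodDatabase:
    """A validated set of foods plus the nutrient-requirement table."""

    items: list[FoodItem]
    requirements: list[NutrientRequirement]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {f.id: f for f in self.items}
        self._req_by_id = {r.nutrient_id: r for r in self.requirements}

    # -- lookup -----------------------------------------------------------
    def food(self, food_id: str) -> FoodItem:
        try:
            return self._by_id[food_id]
        except KeyError:
            raise KeyError(f"unknown food id '{food_id}'") from None

    def requirement(self, nutrient_id: str) -> NutrientRequirement:
        try:
            return self._req_by_id[nutrient_id]
        except KeyError:
            raise KeyError(f"unknown nutrient id '{nutrient_id}'") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._by_id

    @property
    def food_ids(self) -> list[str]:
        return [f.id for f in self.items]

    @property
    def nutrient_ids(self) -> list[str]:
        return [r.nutrient_id for r in self.requirements]

    def foods_with_tag(self, tag: str) -> list[FoodItem]:
        return [f for f in self.items if tag in f.tags]

    def copy(self) -> "FoodDatabase":
        items = [
            replace(f, nutrient_content=dict(f.nutrient_content), tags=frozenset(f.tags))
            for f in self.items
        ]
        reqs = [replace(r) for r in self.requirements]
        return FoodDatabase(items=items, requirements=reqs, metadata=dict(self.metadata))

    # -- validation -------------------------------------------------------
    def problems(self) -> list[str]:
        out: list[str] = []
        if not self.items:
            out.append("database has no foods")
        if not self.requirements:
            out.append("database has no nutrient requirements")
        seen: set[str] = set()
        for f in self.items:
            if f.id in seen:
                out.append(f"duplicated food id '{f.id}'")
            seen.add(f.id)
            out.extend(f.problems())
        seen_req: set[str] = set()
        for r in self.requirements:
            if r.nutrient_id in seen_req:
                out.append(f"duplicated nutrient id '{r.nutrient_id}'")
            seen_req.add(r.nutrient_id)
            out.extend(r.problems())
        known = {r.nutrient_id for r in self.requirements}
        for f in self.items:
            for nid in f.nutrient_content:
                if nid not in known:
                    out.append(
                        f"food '{f.id}': nutrient '{nid}' missing from the requirement table"
                    )
        return out

    def validate(self) -> "FoodDatabase":
        problems = self.problems()
        if problems:
            raise DatabaseValidationError(problems)
        return self


# ---------------------------------------------------------------------------
# I/O.  Two on-disk layouts:
#   csv_pair — a directory holding foods.csv + requirements.csv
#   json     — one document holding both tables plus metadata
# ---------------------------------------------------------------------------

_FOOD_COLUMNS = [
    "id",
    "name",
    "category",
    "price_mean",
    "price_sd",
    "wastage_mean",
    "wastage_sd",
    "ghg_factor",
    "tags",
]
_REQ_COLUMNS = ["nutrient_id", "unit", "min", "max", "sd"]
_NUT_PREFIX = "nut_"


def _parse_float(value: str, *, where: str) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"{where}: cannot parse '{value}' as a number") from None


def _load_csv_pair(directory: Path) -> FoodDatabase:
    foods_path = directory / "foods.csv"
    reqs_path = directory / "requirements.csv"
    for p in (foods_path, reqs_path):
        if not p.exists():
            raise SchemaError(f"missing file: {p}")

    with open(reqs_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _REQ_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"requirements.csv: missing column(s) {missing}")
        requirements = []
        for i, row in enumerate(reader, start=2):
            requirements.append(
                NutrientRequirement(
                    nutrient_id=row["nutrient_id"].strip(),
                    unit=row["unit"].strip(),
                    min_mean=_parse_float(row["min"], where=f"requirements.csv line {i}"),
                    max_mean=_parse_float(row["max"], where=f"requirements.csv line {i}"),
                    heterogeneity_sd=_parse_float(row["sd"], where=f"requirements.csv line {i}")
                    or 0.0,
                )
            )

    with open(foods_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        names = reader.fieldnames or []
        missing = [c for c in _FOOD_COLUMNS if c not in names]
        if missing:
            raise SchemaError(f"foods.csv: missing column(s) {missing}")
        nut_cols = [c for c in names if c.startswith(_NUT_PREFIX)]
        items = []
        for i, row in enumerate(reader, start=2):
            where = f"foods.csv line {i}"
            nutrients = {}
            for col in nut_cols:
                val = _parse_float(row[col], where=where)
                if val is not None:
                    nutrients[col[len(_NUT_PREFIX) :]] = val
            tags = frozenset(t.strip() for t in row["tags"].split(";") if t.strip())
            items.append(
                FoodItem(
                    id=row["id"].strip(),
                    name=row["name"].strip(),
                    category=row["category"].strip(),
                    price_mean=_parse_float(row["price_mean"], where=where) or 0.0,
                    price_sd=_parse_float(row["price_sd"], where=where),
                    wastage_mean=_parse_float(row["wastage_mean"], where=where) or 0.0,
                    wastage_sd=_parse_float(row["wastage_sd"], where=where) or 0.0,
                    ghg_factor=_parse_float(row["ghg_factor"], where=where) or 0.0,
                    nutrient_content=nutrients,
                    tags=tags,
                )
            )
    return FoodDatabase(items=items, requirements=requirements)


def _food_from_json(obj: Mapping) -> FoodItem:
    return FoodItem(
        id=obj["id"],
        name=obj.get("name", obj["id"]),
        category=obj["category"],
        price_mean=float(obj["price_mean"]),
        price_sd=None if obj.get("price_sd") is None else float(obj["price_sd"]),
        wastage_mean=float(obj["wastage_mean"]),
        wastage_sd=float(obj.get("wastage_sd", 0.0)),
        ghg_factor=float(obj["ghg_factor"]),
        nutrient_content={k: float(v) for k, v in obj.get("nutrient_content", {}).items()},
        tags=frozenset(obj.get("tags", [])),
    )


def _load_json(path: Path) -> FoodDatabase:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("foods", "requirements"):
        if key not in doc:
            raise SchemaError(f"{path}: missing top-level key '{key}'")
    try:
        items = [_food_from_json(o) for o in doc["foods"]]
        reqs = [
            NutrientRequirement(
                nutrient_id=o["nutrient_id"],
                unit=o["unit"],
                min_mean=None if o.get("min") is None else float(o["min"]),
                max_mean=None if o.get("max") is None else float(o["max"]),
                heterogeneity_sd=float(o.get("sd", 0.0)),
            )
            for o in doc["requirements"]
        ]
    except KeyError as exc:
        raise SchemaError(f"{path}: missing required field {exc}") from None
    return FoodDatabase(items=items, requirements=reqs, metadata=doc.get("metadata", {}))


def load_food_database(path: str | Path, format: str | None = None) -> FoodDatabase:
    """Load and validate a food database.

    ``format`` is ``"csv_pair"`` (``path`` is a directory containing
    ``foods.csv`` and ``requirements.csv``) or ``"json"`` (``path`` is one
    JSON document).  When omitted it is inferred from the path.
    All invariant violations are collected and raised together as a
    :class:`DatabaseValidationError`.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv_pair"
    if format == "csv_pair":
        db = _load_csv_pair(path)
    elif format == "json":
        db = _load_json(path)
    else:
        raise ValueError(f"unknown format '{format}' (expected 'csv_pair' or 'json')")
    return db.validate()


def save_food_database(db: FoodDatabase, path: str | Path, format: str | None = None) -> None:
    """Write a database in the ``csv_pair`` or ``json`` layout."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv_pair"
    if format == "json":
        doc = {
            "metadata": db.metadata,
            "foods": [
                {
                    "id": f.id,
                    "name": f.name,
                    "category": f.category,
                    "price_mean": f.price_mean,
                    "price_sd": f.price_sd,
                    "wastage_mean": f.wastage_mean,
                    "wastage_sd": f.wastage_sd,
                    "ghg_factor": f.ghg_factor,
                    "nutrient_content": f.nutrient_content,
                    "tags": sorted(f.tags),
                }
                for f in db.items
            ],
            "requirements": [
                {
                    "nutrient_id": r.nutrient_id,
                    "unit": r.unit,
                    "min": r.min_mean,
                    "max": r.max_mean,
                    "sd": r.heterogeneity_sd,
                }
                for r in db.requirements
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
        return
    if format != "csv_pair":
        raise ValueError(f"unknown format '{format}'")
    path.mkdir(parents=True, exist_ok=True)
    nutrient_ids = db.nutrient_ids
    with open(path / "foods.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FOOD_COLUMNS + [_NUT_PREFIX + n for n in nutrient_ids])
        for f in db.items:
            writer.writerow(
                [
                    f.id,
                    f.name,
                    f.category,
                    repr(f.price_mean),
                    "" if f.price_sd is None else repr(f.price_sd),
                    repr(f.wastage_mean),
                    repr(f.wastage_sd),
                    repr(f.ghg_factor),
                    ";".join(sorted(f.tags)),
                ]
                + [repr(f.nutrient_content.get(n, 0.0)) for n in nutrient_ids]
            )
    with open(path / "requirements.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQ_COLUMNS)
        for r in db.requirements:
            writer.writerow(
                [
                    r.nutrient_id,
                    r.unit,
                    "" if r.min_mean is None else repr(r.min_mean),
                    "" if r.max_mean is None else repr(r.max_mean),
                    repr(r.heterogeneity_sd),
                ]
            )
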