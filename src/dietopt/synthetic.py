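"""Synthetic food databases with realistic statistical structure.

Real least-cost-diet studies run on proprietary inputs: national food
price surveys, a food-composition database, wastage fractions from
consumer-waste audits, and per-food GHG factors from life-cycle
assessment compilations.  This module generates databases that *emulate*
that structure — 76 food items across the usual retail categories, with
category-typical price levels and month-to-month coefficients of
variation, plant-low/ruminant-high GHG factors, wastage fractions in
(0, 1) with small SDs, and the standard adult-male nutrient-requirement
bounds — so the whole pipeline can run and be tested without any
download.  Values are plausible, not transcriptions of any real table.

Feasibility is guaranteed constructively: a hidden reference diet is
drawn first and the nutrient contents are nudged so that diet satisfies
every requirement row; the reference diet is then discarded.  Rejection
sampling alone stalls once fifteen nutrient rows interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .food_data import ENERGY_ID, FoodDatabase, FoodItem, NutrientRequirement
from .optimizer import optimize_diet, scale_to_energy
from .scenarios import Scenario, builtin_scenario

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "DEFAULT_ENERGY_SHARES",
    "generate_food_database",
    "generate_known_optimum_instance",
    "generate_typical_diet",
    "default_requirements",
]


class GenerationError(RuntimeError):
    """The generator could not produce a feasible database."""


# ---------------------------------------------------------------------------
# Default requirement table: estimated-average-requirement (EAR) style
# bounds for an adult man, with the iron minimum raised to the female EAR
# of 8 mg/day so the same diets work for women.  Heterogeneity SDs carry
# between-person variation in requirements (body size, activity).
# ---------------------------------------------------------------------------

_REQUIREMENTS = [
    # (nutrient_id, unit, min, max, heterogeneity_sd)
    ("energy", "kJ", 11450.0, None, 184.4),
    ("protein", "g", 52.0, None, 5.0),
    ("fiber", "g", 30.0, None, 2.5),
    ("pufa", "g", 13.1, None, 1.3),
    ("sat_fat", "g", None, 30.0, 0.0),
    ("sodium", "mg", None, 2300.0, 0.0),
    ("potassium", "mg", 3800.0, None, 385.0),
    ("calcium", "mg", 840.0, None, 80.0),
    ("iron", "mg", 8.0, None, 0.8),
    ("zinc", "mg", 12.0, None, 1.0),
    ("selenium", "ug", 60.0, None, 6.0),
    ("vitamin_a", "ug RE", 625.0, 3000.0, 123.0),
    ("thiamine", "mg", 1.0, None, 0.1),
    ("vitamin_c", "mg", 30.0, None, 6.6),
    ("vitamin_e", "mg", 10.0, None, 1.0),
]

_NUTRIENT_ORDER = [r[0] for r in _REQUIREMENTS]


def default_requirements() -> list[NutrientRequirement]:
    """The default daily nutrient-requirement table."""
    return [
        NutrientRequirement(nutrient_id=n, unit=u, min_mean=lo, max_mean=hi, heterogeneity_sd=sd)
        for n, u, lo, hi, sd in _REQUIREMENTS
    ]


# ---------------------------------------------------------------------------
# Archetype nutrient profiles, per 100 g edible weight, in canonical units:
# energy kJ; protein/fiber/pufa/sat_fat g; sodium/potassium/calcium/iron/
# zinc mg; selenium ug; vitamin_a ug RE; thiamine/vitamin_c/vitamin_e mg.
# ---------------------------------------------------------------------------

_A = _NUTRIENT_ORDER  # column order for the tuples below

_ARCHETYPES: dict[str, tuple[float, ...]] = {
    #                en     pro   fib   pufa  sat    na     k     ca    fe    zn    se    va    b1    vc    ve
    "starchy_veg": (320, 2.0, 2.2, 0.10, 0.05, 10, 400, 10, 0.5, 0.4, 0.5, 2, 0.10, 15, 0.05),
    "root_veg": (170, 0.8, 3.0, 0.10, 0.03, 60, 300, 35, 0.4, 0.3, 0.5, 850, 0.06, 6, 0.6),
    "brassica": (130, 2.5, 2.8, 0.10, 0.05, 25, 350, 45, 0.9, 0.5, 1.5, 80, 0.07, 60, 1.0),
    "leafy_veg": (110, 2.0, 2.2, 0.10, 0.04, 80, 380, 60, 1.5, 0.4, 0.8, 300, 0.06, 25, 1.2),
    "other_veg": (120, 1.2, 1.8, 0.08, 0.03, 15, 250, 25, 0.4, 0.3, 0.5, 60, 0.05, 20, 0.4),
    "canned_veg": (90, 1.1, 1.2, 0.10, 0.02, 130, 250, 30, 0.7, 0.2, 0.6, 50, 0.06, 12, 0.8),
    "fruit": (250, 0.8, 2.2, 0.10, 0.03, 3, 250, 20, 0.3, 0.1, 0.3, 15, 0.04, 40, 0.5),
    "dried_fruit": (1250, 2.5, 4.0, 0.10, 0.10, 25, 750, 50, 1.8, 0.3, 0.7, 2, 0.10, 2, 0.3),
    "canned_fruit": (300, 0.4, 1.2, 0.03, 0.01, 5, 130, 8, 0.3, 0.1, 0.3, 15, 0.02, 15, 0.8),
    "flour_wholemeal": (1430, 12.5, 9.0, 1.5, 0.3, 3, 350, 30, 3.5, 2.5, 50, 0, 0.40, 0, 0.8),
    "flour_white": (1470, 10.0, 3.5, 0.8, 0.2, 3, 130, 15, 1.0, 0.8, 15, 0, 0.12, 0, 0.3),
    "pasta_dry": (1530, 12.5, 4.0, 0.8, 0.3, 5, 220, 22, 1.8, 1.4, 60, 0, 0.20, 0, 0.3),
    "oats": (1620, 13.0, 10.0, 2.4, 1.2, 4, 400, 52, 4.0, 2.5, 25, 0, 0.60, 0, 1.2),
    "rice_dry": (1520, 7.0, 1.5, 0.3, 0.2, 4, 110, 10, 0.6, 1.1, 12, 0, 0.10, 0, 0.2),
    "bread_wholemeal": (1000, 9.5, 6.5, 1.2, 0.6, 450, 230, 55, 2.8, 1.6, 30, 0, 0.30, 0, 0.5),
    "bread_white": (1010, 8.5, 2.8, 0.9, 0.5, 480, 120, 30, 1.1, 0.8, 20, 0, 0.25, 0, 0.3),
    "cereal_biscuit": (1500, 11.0, 11.0, 1.0, 0.4, 270, 350, 40, 9.0, 1.5, 30, 0, 0.90, 0, 1.0),
    "crackers": (1800, 9.0, 4.0, 2.5, 2.5, 700, 160, 50, 1.8, 1.0, 20, 0, 0.20, 0, 0.8),
    "wheat_germ": (1500, 27.0, 13.0, 5.5, 1.5, 5, 900, 45, 8.0, 12.0, 75, 0, 1.90, 0, 15),
    "legume_dry": (1370, 23.0, 15.0, 0.6, 0.2, 12, 950, 55, 6.0, 3.5, 6, 10, 0.70, 2, 0.5),
    "legume_canned": (380, 6.5, 5.0, 0.5, 0.1, 250, 280, 45, 1.8, 1.0, 2.5, 2, 0.08, 1, 0.3),
    "peanut": (2450, 25.0, 8.0, 14.0, 6.5, 5, 680, 60, 3.5, 3.3, 7, 0, 0.90, 0, 8),
    "peanut_butter": (2550, 24.0, 6.5, 13.0, 9.0, 420, 650, 45, 2.0, 2.9, 6, 0, 0.10, 0, 9),
    "sunflower_seed": (2450, 21.0, 9.0, 23.0, 4.5, 3, 650, 78, 5.2, 5.0, 53, 1, 1.80, 1, 35),
    "almond": (2500, 21.0, 12.0, 12.0, 3.8, 1, 730, 265, 3.7, 3.1, 4, 0, 0.20, 0, 25),
    "milk_powder_skim": (1510, 36.0, 0.0, 0.05, 0.5, 430, 1600, 1230, 0.3, 3.9, 12, 6, 0.40, 6, 0.03),
    "milk_whole": (270, 3.3, 0.0, 0.10, 2.3, 45, 150, 115, 0.03, 0.4, 1.5, 45, 0.04, 1, 0.07),
    "milk_lowfat": (200, 3.6, 0.0, 0.05, 1.0, 45, 160, 125, 0.03, 0.4, 1.5, 20, 0.04, 1, 0.03),
    "cheese": (1700, 25.0, 0.0, 1.0, 21.0, 650, 80, 740, 0.3, 3.5, 15, 350, 0.03, 0, 0.6),
    "yoghurt": (350, 5.0, 0.0, 0.10, 1.8, 60, 220, 160, 0.1, 0.6, 2.5, 30, 0.05, 1, 0.05),
    "ice_cream": (850, 3.5, 0.2, 0.40, 6.5, 70, 180, 120, 0.2, 0.5, 2, 110, 0.04, 1, 0.3),
    "butter": (3030, 0.6, 0.0, 1.5, 52.0, 600, 25, 15, 0.03, 0.1, 1, 680, 0.01, 0, 1.9),
    "red_meat": (900, 20.0, 0.0, 0.6, 4.5, 70, 320, 10, 2.2, 4.5, 8, 5, 0.08, 0, 0.3),
    "processed_meat": (1100, 13.0, 1.0, 1.5, 8.5, 800, 220, 40, 1.5, 2.3, 10, 5, 0.15, 0, 0.3),
    "poultry": (750, 20.0, 0.0, 2.5, 1.8, 75, 260, 12, 0.8, 1.4, 14, 15, 0.07, 0, 0.3),
    "cured_meat": (550, 18.0, 0.0, 0.8, 2.5, 1200, 300, 8, 0.8, 1.8, 15, 0, 0.45, 0, 0.2),
    "canned_fish": (450, 24.0, 0.0, 0.8, 0.4, 320, 250, 12, 1.0, 0.7, 78, 15, 0.03, 0, 0.5),
    "fish": (550, 19.0, 0.0, 1.0, 0.6, 80, 350, 18, 0.4, 0.5, 40, 12, 0.06, 0, 0.6),
    "egg": (600, 12.5, 0.0, 1.5, 3.1, 135, 130, 52, 1.9, 1.1, 23, 170, 0.07, 0, 1.3),
    "veg_oil": (3700, 0.0, 0.0, 28.0, 7.0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 22),
    "olive_oil": (3700, 0.0, 0.0, 9.0, 14.0, 0, 0, 0, 0.1, 0, 0, 0, 0, 0, 14),
    "margarine": (2500, 0.2, 0.0, 18.0, 12.0, 120, 40, 5, 0, 0, 0, 600, 0, 0, 25),
    "coconut_cream_lite": (420, 1.5, 0.5, 0.1, 7.0, 30, 180, 10, 0.8, 0.4, 2, 0, 0.02, 1, 0.2),
    "salt": (0, 0, 0, 0, 0, 38700, 10, 24, 0.3, 0, 0, 0, 0, 0, 0),
    "sugar": (1700, 0, 0, 0, 0, 1, 2, 1, 0, 0, 0, 0, 0, 0, 0),
    "crisps": (2200, 6.0, 4.0, 8.0, 3.5, 550, 1100, 25, 1.5, 0.9, 4, 0, 0.15, 15, 6),
    "juice": (180, 0.4, 0.2, 0.03, 0.01, 4, 140, 8, 0.15, 0.03, 0.1, 5, 0.04, 30, 0.2),
    "chocolate": (2200, 7.0, 3.0, 1.5, 18.0, 70, 420, 190, 2.3, 1.6, 4, 40, 0.06, 0, 1.2),
    "soft_drink": (170, 0, 0, 0, 0, 8, 2, 3, 0.02, 0.01, 0, 0, 0, 0, 0),
}

#: Per-food nutrient overrides applied after the archetype profile.
_OVERRIDES: dict[str, dict[str, float]] = {
    "kiwifruit": {"vitamin_c": 90.0},
    "oranges": {"vitamin_c": 50.0},
    "banana": {"vitamin_c": 12.0, "potassium": 350.0},
}

# ---------------------------------------------------------------------------
# The 76-item roster: id, display name, category, archetype, tags,
# typical price (NZ$/100 g purchased), GHG factor (kg CO2e/kg purchased),
# wastage mean and SD.  Foods priced from bulk/in-store sources rather
# than a monthly index have no price SD and borrow the category-median CV
# in the simulation (fpi=False).
# ---------------------------------------------------------------------------

_R = []  # (id, name, category, archetype, tags, price, ghg, w_mean, w_sd, fpi)


def _r(fid, name, cat, arch, tags, price, ghg, w, wsd, fpi=True):
    _R.append((fid, name, cat, arch, tags, price, ghg, w, wsd, fpi))


_VEG = "vegetable"
_SVEG = "vegetable;starchy_root"

# fruit & vegetables (26)
_r("potatoes", "Potatoes", "fruit_veg", "starchy_veg", _SVEG, 0.20, 0.65, 0.45, 0.0142)
_r("kumara", "Kumara", "fruit_veg", "starchy_veg", _SVEG, 0.35, 0.70, 0.38, 0.030)
_r("taro", "Taro", "fruit_veg", "starchy_veg", _SVEG, 0.55, 0.90, 0.35, 0.030, False)
_r("carrots", "Carrots", "fruit_veg", "root_veg", _VEG, 0.22, 0.45, 0.35, 0.025)
_r("onion", "Onions", "fruit_veg", "other_veg", _VEG, 0.25, 0.45, 0.30, 0.025)
_r("cabbage", "Cabbage", "fruit_veg", "brassica", _VEG, 0.25, 0.40, 0.35, 0.030)
_r("broccoli", "Broccoli", "fruit_veg", "brassica", _VEG, 0.60, 0.55, 0.35, 0.030)
_r("bok_choy", "Bok choy", "fruit_veg", "brassica", _VEG, 0.50, 0.50, 0.30, 0.030, False)
_r("lettuce", "Lettuce", "fruit_veg", "leafy_veg", _VEG, 0.55, 0.60, 0.35, 0.030)
_r("silverbeet", "Silverbeet", "fruit_veg", "leafy_veg", _VEG, 0.45, 0.50, 0.35, 0.030)
_r("tomatoes", "Tomatoes", "fruit_veg", "other_veg", _VEG, 0.70, 1.10, 0.20, 0.020)
_r("canned_tomatoes", "Canned tomatoes", "fruit_veg", "canned_veg", _VEG, 0.35, 1.20, 0.08, 0.010)
_r("frozen_mixed_veg", "Frozen mixed vegetables", "fruit_veg", "other_veg", _VEG, 0.40, 0.90, 0.10, 0.010)
_r("pumpkin", "Pumpkin", "fruit_veg", "other_veg", _VEG, 0.20, 0.40, 0.30, 0.030)
_r("cauliflower", "Cauliflower", "fruit_veg", "brassica", _VEG, 0.45, 0.50, 0.35, 0.030)
_r("celery", "Celery", "fruit_veg", "other_veg", _VEG, 0.45, 0.50, 0.30, 0.030)
_r("courgette", "Courgettes", "fruit_veg", "other_veg", _VEG, 0.60, 0.60, 0.25, 0.020)
_r("capsicum", "Capsicums", "fruit_veg", "other_veg", _VEG, 0.90, 1.00, 0.25, 0.020)
_r("apple", "Apples", "fruit_veg", "fruit", "fruit", 0.30, 0.55, 0.30, 0.020)
_r("banana", "Bananas", "fruit_veg", "fruit", "fruit", 0.25, 0.90, 0.40, 0.020)
_r("oranges", "Oranges", "fruit_veg", "fruit", "fruit", 0.35, 0.60, 0.30, 0.020)
_r("kiwifruit", "Kiwifruit, green", "fruit_veg", "fruit", "fruit", 0.30, 0.55, 0.25, 0.020)
_r("pears", "Pears", "fruit_veg", "fruit", "fruit", 0.35, 0.55, 0.30, 0.020)
_r("frozen_berries", "Frozen berries", "fruit_veg", "fruit", "fruit", 1.00, 1.10, 0.05, 0.010)
_r("sultanas", "Sultanas", "fruit_veg", "dried_fruit", "fruit", 0.75, 1.60, 0.04, 0.010)
_r("canned_peaches", "Canned peaches", "fruit_veg", "canned_fruit", "fruit", 0.45, 1.20, 0.08, 0.010)

# cereals & grains (12)
_RCS = "requires_cooking_skill"
_r("flour_wholemeal", "Flour, wholemeal", "cereal_grain", "flour_wholemeal", _RCS, 0.15, 1.10, 0.05, 0.010)
_r("flour_white", "Flour, white", "cereal_grain", "flour_white", _RCS, 0.12, 1.00, 0.05, 0.010)
_r("pasta", "Pasta, dry", "cereal_grain", "pasta_dry", "", 0.22, 1.30, 0.08, 0.010)
_r("oats", "Oats, wholegrain", "cereal_grain", "oats", "", 0.30, 1.00, 0.05, 0.010)
_r("rice", "Rice, white", "cereal_grain", "rice_dry", "", 0.35, 2.60, 0.08, 0.010)
_r("bread_wholemeal", "Bread, wholemeal", "cereal_grain", "bread_wholemeal", "", 0.35, 1.10, 0.22, 0.020)
_r("bread_white", "Bread, white", "cereal_grain", "bread_white", "", 0.30, 1.00, 0.22, 0.020)
_r("semolina", "Semolina", "cereal_grain", "flour_white", _RCS, 0.30, 1.00, 0.05, 0.010, False)
_r("couscous", "Couscous", "cereal_grain", "flour_white", _RCS, 0.55, 1.10, 0.05, 0.010, False)
_r("breakfast_biscuits", "Wheat breakfast biscuits", "cereal_grain", "cereal_biscuit", "", 0.55, 1.30, 0.03, 0.010)
_r("crackers", "Crackers", "cereal_grain", "crackers", "", 0.70, 1.40, 0.03, 0.010)
_r("wheat_germ", "Wheat germ", "cereal_grain", "wheat_germ", "", 0.60, 1.00, 0.04, 0.010, False)

# pulses, seeds & nuts (8)
_r("dried_peas", "Dried peas", "pulse_seed_nut", "legume_dry", _RCS, 0.35, 0.90, 0.05, 0.010, False)
_r("lentils", "Lentils, dry", "pulse_seed_nut", "legume_dry", _RCS, 0.40, 0.90, 0.05, 0.010, False)
_r("chickpeas_canned", "Chickpeas, canned", "pulse_seed_nut", "legume_canned", "", 0.45, 1.20, 0.10, 0.010)
_r("baked_beans", "Baked beans", "pulse_seed_nut", "legume_canned", "", 0.35, 1.20, 0.10, 0.010)
_r("peanuts", "Peanuts, unsalted", "pulse_seed_nut", "peanut", "nut", 0.90, 1.40, 0.08, 0.010, False)
_r("peanut_butter", "Peanut butter", "pulse_seed_nut", "peanut_butter", "nut", 0.75, 1.50, 0.04, 0.010)
_r("sunflower_seeds", "Sunflower seeds", "pulse_seed_nut", "sunflower_seed", "nut", 0.90, 1.20, 0.05, 0.010, False)
_r("almonds", "Almonds", "pulse_seed_nut", "almond", "nut", 1.80, 1.60, 0.05, 0.010, False)

# dairy (7)
_DAIRY = "animal_product;dairy_product"
_r("skim_milk_powder", "Skim milk powder", "dairy", "milk_powder_skim", _DAIRY, 1.00, 9.00, 0.03, 0.010)
_r("milk_whole", "Milk, whole homogenized", "dairy", "milk_whole", _DAIRY, 0.22, 1.50, 0.12, 0.020)
_r("milk_lowfat", "Milk, low fat", "dairy", "milk_lowfat", _DAIRY, 0.23, 1.40, 0.12, 0.020)
_r("cheese", "Cheese, mild cheddar", "dairy", "cheese", _DAIRY, 1.10, 8.80, 0.10, 0.020)
_r("yoghurt", "Yoghurt, plain", "dairy", "yoghurt", _DAIRY, 0.55, 2.20, 0.10, 0.020)
_r("ice_cream", "Ice cream, low fat", "dairy", "ice_cream", _DAIRY, 0.50, 2.60, 0.06, 0.010)
_r("butter", "Butter, salted", "dairy", "butter", _DAIRY, 0.95, 9.30, 0.05, 0.010)

# meat, fish & eggs (12)
_MEAT = "animal_product;meat"
_FISH = "animal_product;fish"
_r("beef_mince", "Beef mince", "meat_fish_egg", "red_meat", _MEAT, 1.35, 21.0, 0.12, 0.020)
_r("sausages", "Sausages", "meat_fish_egg", "processed_meat", _MEAT, 0.90, 12.0, 0.12, 0.020)
_r("chicken_pieces", "Chicken pieces", "meat_fish_egg", "poultry", _MEAT, 0.95, 4.60, 0.25, 0.030)
_r("lamb_chops", "Lamb chops", "meat_fish_egg", "red_meat", _MEAT, 1.60, 25.0, 0.30, 0.030)
_r("pork_chops", "Pork chops", "meat_fish_egg", "red_meat", _MEAT, 1.30, 6.50, 0.25, 0.030)
_r("bacon", "Bacon", "meat_fish_egg", "processed_meat", _MEAT, 1.60, 7.50, 0.12, 0.020)
_r("ham", "Ham", "meat_fish_egg", "cured_meat", _MEAT, 1.70, 7.00, 0.08, 0.010)
_r("canned_corned_beef", "Corned beef, canned", "meat_fish_egg", "processed_meat", _MEAT, 1.40, 16.0, 0.05, 0.010)
_r("canned_tuna", "Tuna in spring water, canned", "meat_fish_egg", "canned_fish", _FISH, 1.50, 3.40, 0.06, 0.010)
_r("fresh_fish", "Fresh fish fillets", "meat_fish_egg", "fish", _FISH, 2.20, 4.50, 0.20, 0.030)
_r("frozen_fish_fillets", "Frozen fish fillets", "meat_fish_egg", "fish", _FISH, 1.60, 4.20, 0.10, 0.020)
_r("eggs", "Eggs", "meat_fish_egg", "egg", "animal_product;egg", 0.65, 3.60, 0.13, 0.015)

# fats & oils (4)
_r("vegetable_oil", "Vegetable oil", "fat_oil", "veg_oil", "", 0.55, 3.00, 0.02, 0.005)
_r("olive_oil", "Olive oil", "fat_oil", "olive_oil", "", 1.30, 3.20, 0.02, 0.005)
_r("margarine", "Margarine, low salt", "fat_oil", "margarine", "", 0.60, 1.80, 0.04, 0.010)
_r("coconut_cream", "Coconut cream, lite", "fat_oil", "coconut_cream_lite", "", 0.60, 1.60, 0.08, 0.010, False)

# condiments (2)
_r("salt", "Salt", "condiment", "salt", "condiment_exempt_from_min", 0.15, 0.20, 0.01, 0.003)
_r("sugar", "Sugar, white", "condiment", "sugar", "condiment_exempt_from_min;added_sugar", 0.22, 1.10, 0.01, 0.003)

# other (5)
_r("potato_crisps", "Potato crisps", "other", "crisps", "", 1.40, 2.50, 0.03, 0.010)
_r("apple_juice", "Apple juice", "other", "juice", "juice", 0.30, 1.10, 0.05, 0.010)
_r("orange_juice", "Orange juice", "other", "juice", "juice", 0.32, 1.10, 0.05, 0.010)
_r("chocolate", "Chocolate, milk", "other", "chocolate", "", 1.60, 4.50, 0.02, 0.005)
_r("soft_drink", "Soft drink", "other", "soft_drink", "", 0.20, 0.50, 0.02, 0.005)

ROSTER = tuple(_R)
del _R

_DEFAULT_CATEGORY_MIX = {}
for row in ROSTER:
    _DEFAULT_CATEGORY_MIX[row[2]] = _DEFAULT_CATEGORY_MIX.get(row[2], 0) + 1

#: Month-to-month price coefficient of variation by category (fresh produce
#: swings most; packaged staples least).
DEFAULT_PRICE_CV = {
    "fruit_veg": 0.12,
    "cereal_grain": 0.04,
    "pulse_seed_nut": 0.05,
    "dairy": 0.05,
    "meat_fish_egg": 0.06,
    "fat_oil": 0.05,
    "condiment": 0.03,
    "other": 0.05,
}

#: GHG factor windows (kg CO2e per kg purchased) enforcing the
#: plant << dairy < ruminant ordering.
DEFAULT_GHG_RANGES = {
    "fruit_veg": (0.30, 2.0),
    "cereal_grain": (0.70, 3.0),
    "pulse_seed_nut": (0.80, 2.0),
    "dairy": (1.30, 10.0),
    "meat_fish_egg": (3.0, 28.0),
    "fat_oil": (1.40, 3.5),
    "condiment": (0.15, 1.3),
    "other": (0.40, 5.0),
}

#: Wastage-fraction windows by category.
DEFAULT_WASTAGE_RANGES = {
    "fruit_veg": (0.04, 0.50),
    "cereal_grain": (0.02, 0.30),
    "pulse_seed_nut": (0.02, 0.12),
    "dairy": (0.02, 0.15),
    "meat_fish_egg": (0.04, 0.35),
    "fat_oil": (0.01, 0.10),
    "condiment": (0.005, 0.05),
    "other": (0.01, 0.08),
}

#: Energy shares of the typical-diet comparator by category (alcohol
#: excluded), loosely patterned on national adult-survey category shares:
#: grain-heavy, substantial meat and dairy, modest fruit/vegetables.
DEFAULT_ENERGY_SHARES = {
    "cereal_grain": 0.32,
    "meat_fish_egg": 0.20,
    "dairy": 0.13,
    "fruit_veg": 0.11,
    "fat_oil": 0.09,
    "condiment": 0.07,
    "other": 0.05,
    "pulse_seed_nut": 0.03,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic database generator."""

    n_foods: int = len(ROSTER)
    seed: int = 0
    category_mix: dict[str, int] | None = None  # None = roster default
    price_cv_by_category: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRICE_CV))
    ghg_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GHG_RANGES)
    )
    wastage_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WASTAGE_RANGES)
    )
    feasibility_guarantee: bool = True

    def __post_init__(self) -> None:
        mix = self.category_mix if self.category_mix is not None else _DEFAULT_CATEGORY_MIX
        if sum(mix.values()) != self.n_foods:
            raise ValueError(
                f"category_mix counts sum to {sum(mix.values())}, expected n_foods={self.n_foods}"
            )
        for cat, count in mix.items():
            avail = _DEFAULT_CATEGORY_MIX.get(cat, 0)
            if count > avail:
                raise ValueError(f"category '{cat}' has only {avail} roster foods, asked {count}")
        for cat, (lo, hi) in self.ghg_ranges.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid ghg_range for '{cat}'")
        for cat, (lo, hi) in self.wastage_ranges.items():
            if not 0 <= lo <= hi < 1:
                raise ValueError(f"invalid wastage_range for '{cat}'")


# Hidden reference diet used for the constructive feasibility guarantee
# (grams edible/day; roughly a grain-legume-egg-dairy-vegetable day).
_REFERENCE_DIET = {
    "flour_wholemeal": 200.0,
    "pasta": 150.0,
    "oats": 60.0,
    "dried_peas": 120.0,
    "eggs": 80.0,
    "skim_milk_powder": 40.0,
    "carrots": 80.0,
    "broccoli": 80.0,
    "kiwifruit": 80.0,
    "vegetable_oil": 30.0,
    "sunflower_seeds": 30.0,
    "sugar": 20.0,
    "salt": 3.0,
}


def _reference_diet(db: FoodDatabase) -> dict[str, float]:
    ref = {fid: g for fid, g in _REFERENCE_DIET.items() if fid in db}
    if len([f for f in ref if ref[f] >= 10]) >= 5:
        return ref
    # reduced databases: spread a generic day over whatever is available
    ref = {}
    for f in db.items:
        if f.is_condiment:
            ref[f.id] = 3.0 if f.nutrient_content.get(ENERGY_ID, 0.0) == 0 else 20.0
        elif "vegetable" in f.tags or "fruit" in f.tags:
            ref[f.id] = 150.0
        else:
            ref[f.id] = min(150.0, 240.0)
    return ref


def _adjust_for_feasibility(db: FoodDatabase, ref: dict[str, float]) -> None:
    """Scale nutrient contents so the reference diet satisfies every row."""
    target_energy = 1.05 * 11450.0

    def intake(nid: str) -> float:
        return sum(g * db.food(fid).nutrient_content.get(nid, 0.0) / 100.0 for fid, g in ref.items())

    def scale_nutrient(nid: str, factor: float) -> None:
        for f in db.items:
            if nid in f.nutrient_content:
                f.nutrient_content[nid] *= factor

    cur = intake(ENERGY_ID)
    if cur > 0:
        scale_nutrient(ENERGY_ID, target_energy / cur)

    for req in db.requirements:
        nid = req.nutrient_id
        if nid == ENERGY_ID:
            continue
        cur = intake(nid)
        if req.min_mean is not None and req.min_mean > 0:
            want = 1.08 * req.min_mean
            if req.max_mean is not None:
                want = min(want, 0.5 * (req.min_mean + req.max_mean))
            if cur < want:
                if cur <= 0:
                    # no food carries this nutrient: seed it uniformly
                    total_g = sum(g for fid, g in ref.items() if not db.food(fid).is_condiment)
                    per100 = want / (total_g / 100.0)
                    for f in db.items:
                        if not f.is_condiment:
                            f.nutrient_content[nid] = per100
                else:
                    scale_nutrient(nid, want / cur)
                cur = want
        if req.max_mean is not None and cur > 0.85 * req.max_mean:
            scale_nutrient(nid, 0.85 * req.max_mean / cur)


def generate_food_database(config: GeneratorConfig | None = None) -> FoodDatabase:
    """Generate a seed-deterministic, feasible synthetic food database.

    With ``feasibility_guarantee`` on, the returned database admits a
    feasible least-cost (C1-style) diet, verified internally by one solve.
    """
    config = config or GeneratorConfig()
    mix = dict(config.category_mix) if config.category_mix is not None else None

    for attempt in range(50):
        rng = np.random.default_rng((int(config.seed), attempt, 20_130_327))
        items: list[FoodItem] = []
        taken: dict[str, int] = {}
        for fid, name, cat, arch, tags, price, ghg, w, wsd, fpi in ROSTER:
            if mix is not None:
                if taken.get(cat, 0) >= mix.get(cat, 0):
                    continue
                taken[cat] = taken.get(cat, 0) + 1
            profile = dict(zip(_NUTRIENT_ORDER, _ARCHETYPES[arch]))
            profile.update(_OVERRIDES.get(fid, {}))
            nutrients = {
                nid: float(v * rng.lognormal(0.0, 0.10)) if v > 0 else 0.0
                for nid, v in profile.items()
            }
            p = float(price * rng.lognormal(0.0, 0.08))
            g = float(ghg * rng.lognormal(0.0, 0.10))
            glo, ghi = config.ghg_ranges.get(cat, (0.0, math.inf))
            g = min(max(g, glo), ghi)
            wlo, whi = config.wastage_ranges.get(cat, (0.0, 0.95))
            w_eff = min(max(w, wlo), whi)
            cv = config.price_cv_by_category.get(cat, 0.05)
            items.append(
                FoodItem(
                    id=fid,
                    name=name,
                    category=cat,
                    price_mean=p,
                    price_sd=cv * p if fpi else None,
                    wastage_mean=w_eff,
                    wastage_sd=wsd,
                    ghg_factor=g,
                    nutrient_content=nutrients,
                    tags=frozenset(t for t in tags.split(";") if t),
                )
            )
        db = FoodDatabase(
            items=items,
            requirements=default_requirements(),
            metadata={
                "provenance": "dietopt synthetic generator (no real survey values)",
                "seed": int(config.seed),
                "attempt": attempt,
                "n_foods": len(items),
            },
        )
        if not config.feasibility_guarantee:
            return db.validate()
        _adjust_for_feasibility(db, _reference_diet(db))
        db.validate()
        check = builtin_scenario("C1").restricted_to(db)
        if optimize_diet(db, check).status == "optimal":
            return db
    raise GenerationError(
        "no feasible database after 50 attempts; loosen the generator config "
        "(wider GHG/wastage ranges or a richer category mix)"
    )


# ---------------------------------------------------------------------------
# Closed-form oracle instances
# ---------------------------------------------------------------------------


def _mini_db(
    foods: list[tuple[str, float, float, dict[str, float]]],
    requirements: list[NutrientRequirement],
) -> FoodDatabase:
    items = [
        FoodItem(
            id=fid,
            name=fid,
            category="other",
            price_mean=price,
            wastage_mean=0.0,
            ghg_factor=ghg,
            nutrient_content=dict(nutrients),
        )
        for fid, price, ghg, nutrients in foods
    ]
    return FoodDatabase(items=items, requirements=requirements).validate()


def generate_known_optimum_instance(kind: str):
    """Return ``(db, scenario, expected)`` with a closed-form optimum.

    Kinds:

    * ``single_binding_nutrient`` — two foods, one protein floor; the
      cheaper per-gram-of-protein food takes the whole requirement.
    * ``two_constraint_vertex`` — two foods, two binding rows; the optimum
      is the unique vertex solving the 2x2 system.
    * ``budget_capped`` — emission minimization where the budget row binds
      against the energy floor.

    ``expected`` is a dict with ``quantities`` and ``objective_value``
    computed from the defining equations, independent of any LP solver.
    """
    if kind == "single_binding_nutrient":
        req = [NutrientRequirement("protein", "g", min_mean=50.0)]
        db = _mini_db(
            [
                ("food_a", 1.00, 1.0, {"protein": 20.0}),
                ("food_b", 0.60, 1.0, {"protein": 10.0}),
            ],
            req,
        )
        scenario = Scenario(id="oracle_single", objective="min_cost")
        # $/g protein: A 0.05, B 0.06 -> A covers the floor: 50/0.20 g
        qty_a = 50.0 / 0.20
        expected = {
            "quantities": {"food_a": qty_a, "food_b": 0.0},
            "objective_value": qty_a * 1.00 / 100.0,
        }
        return db, scenario, expected

    if kind == "two_constraint_vertex":
        req = [
            NutrientRequirement("protein", "g", min_mean=50.0),
            NutrientRequirement("fiber", "g", min_mean=30.0),
        ]
        db = _mini_db(
            [
                ("food_a", 1.00, 1.0, {"protein": 20.0, "fiber": 2.0}),
                ("food_b", 0.80, 1.0, {"protein": 5.0, "fiber": 10.0}),
            ],
            req,
        )
        scenario = Scenario(id="oracle_vertex", objective="min_cost")
        a = np.array([[0.20, 0.05], [0.02, 0.10]])  # per-gram nutrient matrix
        x = np.linalg.solve(a, np.array([50.0, 30.0]))
        cost = float(x @ np.array([1.00 / 100.0, 0.80 / 100.0]))
        expected = {
            "quantities": {"food_a": float(x[0]), "food_b": float(x[1])},
            "objective_value": cost,
        }
        return db, scenario, expected

    if kind == "budget_capped":
        req = [NutrientRequirement("energy", "kJ", min_mean=11450.0)]
        db = _mini_db(
            [
                ("cheap_dirty", 0.50, 5.0, {"energy": 1500.0}),
                ("clean_dear", 2.00, 1.0, {"energy": 1500.0}),
            ],
            req,
        )
        scenario = Scenario(id="oracle_budget", objective="min_ghg", budget_cap=8.0)
        # binding rows: energy floor and budget cap
        a = np.array([[15.0, 15.0], [0.50 / 100.0, 2.00 / 100.0]])
        x = np.linalg.solve(a, np.array([11450.0, 8.0]))
        ghg = float(x @ np.array([5.0 / 1000.0, 1.0 / 1000.0]))
        expected = {
            "quantities": {"cheap_dirty": float(x[0]), "clean_dear": float(x[1])},
            "objective_value": ghg,
        }
        return db, scenario, expected

    raise ValueError(
        f"unknown kind '{kind}' (expected single_binding_nutrient, two_constraint_vertex "
        "or budget_capped)"
    )


# ---------------------------------------------------------------------------
# Typical-diet comparator
# ---------------------------------------------------------------------------


def generate_typical_diet(
    db: FoodDatabase,
    energy_shares: dict[str, float] | None = None,
    target_kj: float = 11450.0,
) -> dict[str, float]:
    """Fixed (non-optimized) diet built from category energy shares.

    Each category's share of the energy target is split equally across its
    positive-energy members, converted to grams through each food's energy
    density, and the whole diet rescaled so total energy equals
    ``target_kj`` exactly.
    """
    shares = DEFAULT_ENERGY_SHARES if energy_shares is None else energy_shares
    present = {cat: [] for cat in shares}
    for f in db.items:
        if f.category in present and f.nutrient_content.get(ENERGY_ID, 0.0) > 0:
            present[f.category].append(f)
    active = {cat: share for cat, share in shares.items() if share > 0}
    total = sum(active.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"energy shares must sum to 1, got {total}")
    for cat in active:
        if not present[cat]:
            raise GenerationError(
                f"category '{cat}' has no positive-energy food in the database"
            )
    quantities: dict[str, float] = {}
    for cat, share in active.items():
        members = present[cat]
        per_member_kj = share * target_kj / len(members)
        for f in members:
            density = f.nutrient_content[ENERGY_ID] / 100.0  # kJ per gram
            quantities[f.id] = quantities.get(f.id, 0.0) + per_member_kj / density
    return scale_to_energy(quantities, db, target_kj)
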