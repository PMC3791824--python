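"""Revised Children's Diet Quality Index (RC-DQI) component scoring.

Thirteen components totalling 90 points for children 2-18 years old,
scored against age-indexed reference targets: absolute food-group targets
(oz/cup equivalents per day) with proportional deduction for shortfall,
macronutrient percent-of-energy ranges, caps with ratio decay for
overconsumption (added sugar, DHA+EPA relative to alpha-linolenic acid,
excess fruit juice), a categorical iron score against EAR/RDA bands, and a
combined screen-time/energy component scored against an Estimated Energy
Requirement (EER) window.

Every continuous component follows the index's deviation-from-recommendation
philosophy: full points inside the recommended region, proportional deduction
outside it, and zero only at the extreme (zero intake, or unbounded excess).
Iron is the single categorical exception (0/5/10 points).

Two target-table variants are shipped as versioned data files; they differ in
the food-group energy patterns (grain/fruit/vegetable targets and the EER
row) and in two iron bands.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from .intake_model import ChildProfile, UsualIntake

TABLE_VARIANTS = ("table_b", "table_c")

MAX_POINTS: Mapping[str, float] = {
    "added_sugar": 10.0,
    "fat": 2.5,
    "linoleic": 2.5,
    "linolenic": 2.5,
    "dha_epa": 2.5,
    "total_grains": 5.0,
    "whole_grains": 5.0,
    "fruit": 10.0,
    "vegetable": 10.0,
    "excess_juice": 10.0,
    "dairy": 10.0,
    "iron": 10.0,
    "tv_energy": 10.0,
}

COMPONENTS = tuple(MAX_POINTS)

#: Food-group components scored as proportional attainment of an age target.
FOOD_GROUP_COMPONENTS = ("total_grains", "whole_grains", "fruit", "vegetable", "dairy")

TOTAL_MAX = 90.0


def _read_csv(name: str) -> list[dict]:
    text = resources.files("childdqi.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


@dataclass(frozen=True)
class IronBand:
    age_lo: int
    age_hi: int
    ear_mg: float  # at or below: 0 points
    rda_mg: float  # at or above: 10 points


class RCDQITargetTable:
    """Age-indexed scoring rulebook for one RC-DQI table variant.

    Resolves, for every age 2-18: the five food-group targets, the
    age-appropriate juice limit, the EER, the iron EAR/RDA band, the
    macronutrient ranges/caps, and the screen-time imputation hours.
    """

    def __init__(self, variant: str = "table_b"):
        if variant not in TABLE_VARIANTS:
            raise ValueError(f"variant must be one of {TABLE_VARIANTS}, got {variant!r}")
        self.variant = variant
        suffix = variant[-1]  # "b" or "c"
        self._targets: dict[tuple[str, int], float] = {
            (r["component"], int(r["age"])): float(r["target"])
            for r in _read_csv(f"rcdqi_targets_{suffix}.csv")
        }
        self._iron = [
            IronBand(int(r["age_lo"]), int(r["age_hi"]), float(r["ear_mg"]), float(r["rda_mg"]))
            for r in _read_csv(f"rcdqi_iron_{suffix}.csv")
        ]
        self._macro = _read_csv("rcdqi_macro.csv")
        self._tv_impute = [
            (int(r["age_lo"]), int(r["age_hi"]), float(r["hours"]))
            for r in _read_csv("tv_imputation.csv")
        ]

    def _check_age(self, age: int) -> None:
        if not 2 <= age <= 18:
            raise ValueError(f"age must be in [2, 18], got {age}")

    def lookup_target(self, component: str, age: int) -> float:
        """Printed per-day target (or limit, or EER) for one component at one age."""
        self._check_age(age)
        try:
            return self._targets[(component, age)]
        except KeyError:
            raise KeyError(f"no age-indexed target for component {component!r}") from None

    def iron_band(self, age: int) -> IronBand:
        self._check_age(age)
        for band in self._iron:
            if band.age_lo <= age <= band.age_hi:
                return band
        raise AssertionError("iron bands do not cover age range")  # pragma: no cover

    def macro_rule(self, component: str, age: int) -> dict:
        """Range or cap rule for a macronutrient component at one age."""
        self._check_age(age)
        for r in self._macro:
            if r["component"] == component and int(r["age_lo"]) <= age <= int(r["age_hi"]):
                return {
                    "kind": r["kind"],
                    "lo": float(r["lo"]) if r["lo"] else None,
                    "hi": float(r["hi"]),
                    "max_points": float(r["max_points"]),
                }
        raise KeyError(f"no macronutrient rule for {component!r}")

    def tv_imputation_hours(self, age: int) -> float:
        """Screen-time hours assumed when TV viewing was not reported."""
        self._check_age(age)
        for lo, hi, hours in self._tv_impute:
            if lo <= age <= hi:
                return hours
        raise AssertionError("TV imputation bands do not cover age range")  # pragma: no cover


_TABLES: dict[str, RCDQITargetTable] = {}


def get_table(variant: str = "table_b") -> RCDQITargetTable:
    if variant not in _TABLES:
        _TABLES[variant] = RCDQITargetTable(variant)
    return _TABLES[variant]


def lookup_target(component: str, age: int, table: RCDQITargetTable) -> float:
    return table.lookup_target(component, age)


def score_food_group(intake: float, target: float, max_points: float) -> float:
    """Proportional attainment of a food-group target.

    Full points at or above the target; below it, points are deducted in
    proportion to the shortfall, reaching zero only at zero intake.
    """
    if target <= 0:
        raise ValueError(f"target must be > 0, got {target}")
    if intake < 0:
        raise ValueError(f"intake must be >= 0, got {intake}")
    return max_points * min(1.0, intake / target)


def score_range(value: float, lo: float, hi: float, max_points: float) -> float:
    """Full points inside [lo, hi]; ratio decay on either side.

    Below the range the score falls linearly to zero at zero intake; above it
    the score decays as hi/value, so it approaches zero only in the limit.
    """
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    if value < lo:
        return max_points * value / lo
    if value > hi:
        return max_points * hi / value
    return max_points


def score_cap(value: float, cap: float, max_points: float) -> float:
    """Full points at or below a cap; ratio decay above it."""
    if cap <= 0:
        raise ValueError(f"cap must be > 0, got {cap}")
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    if value <= cap:
        return max_points
    return max_points * cap / value


def score_iron(intake: float, age: int, table: RCDQITargetTable) -> float:
    """Categorical iron score: 0 at or below the EAR, 10 at or above the RDA, 5 between."""
    if intake < 0:
        raise ValueError(f"intake must be >= 0, got {intake}")
    band = table.iron_band(age)
    if intake <= band.ear_mg:
        return 0.0
    if intake >= band.rda_mg:
        return 10.0
    return 5.0


def score_tv(tv_hours: Optional[float], age: int, table: RCDQITargetTable) -> float:
    """Screen-time half of the combined TV/energy component.

    Missing hours are imputed by age band before scoring. Up to 2 hours/day
    earns the full 10 points; beyond that the score decays as 2/hours.
    """
    if tv_hours is None:
        tv_hours = table.tv_imputation_hours(age)
    if tv_hours < 0:
        raise ValueError(f"tv_hours must be >= 0, got {tv_hours}")
    if tv_hours <= 2.0:
        return 10.0
    return 10.0 * 2.0 / tv_hours


def score_energy(energy: float, eer: float, formula: str = "proportional") -> float:
    """Energy half of the combined TV/energy component, against the EER window.

    Full points inside [0.9*EER, 1.1*EER]. With the default ``proportional``
    formula the score decays proportionally anchored at the window edges
    (continuous everywhere, zero only at zero intake). The ``literal`` formula
    applies the published percentage-deduction wording as printed, which is
    discontinuous at the window edges; it is kept only so the two readings can
    be compared.
    """
    if eer <= 0:
        raise ValueError(f"eer must be > 0, got {eer}")
    if energy < 0:
        raise ValueError(f"energy must be >= 0, got {energy}")
    lo, hi = 0.9 * eer, 1.1 * eer
    if lo <= energy <= hi:
        return 10.0
    if formula == "proportional":
        if energy < lo:
            return 10.0 * energy / lo
        return 10.0 * hi / energy
    if formula == "literal":
        if energy < lo:
            return max(0.0, 10.0 - (energy / lo * 100.0) / 10.0)
        return max(0.0, 10.0 - (energy / hi * 100.0) / 10.0)
    raise ValueError(f"unknown eer formula {formula!r}")


@dataclass(frozen=True)
class RCDQIComponentScores:
    """Per-component RC-DQI points for one child (max 90 in total)."""

    child_id: str
    added_sugar: float
    fat: float
    linoleic: float
    linolenic: float
    dha_epa: float
    total_grains: float
    whole_grains: float
    fruit: float
    vegetable: float
    excess_juice: float
    dairy: float
    iron: float
    tv_energy: float

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["total"] = self.total
        return d


#: RC-DQI food-group component -> UsualIntake field with the consumed amount.
_FOOD_GROUP_FIELDS = {
    "total_grains": "total_grains",
    "whole_grains": "whole_grains",
    "fruit": "total_fruit",
    "vegetable": "total_veg",
    "dairy": "dairy",
}

_MACRO_FIELDS = {
    "added_sugar": "added_sugar_pct",
    "fat": "total_fat_pct",
    "linoleic": "linoleic_pct",
    "linolenic": "linolenic_pct",
    "dha_epa": "dha_epa_pct_of_ala",
}


def score_rcdqi(
    profile: ChildProfile,
    usual: UsualIntake,
    table_variant: str = "table_b",
    eer_formula: str = "proportional",
) -> RCDQIComponentScores:
    """Score all thirteen RC-DQI components for one child.

    Targets are resolved from the child's age; the combined TV/energy
    component averages the screen-time and EER-window scores.
    """
    table = get_table(table_variant)
    age = profile.age
    scores: dict[str, float] = {}

    for comp, field in _MACRO_FIELDS.items():
        rule = table.macro_rule(comp, age)
        value = getattr(usual, field)
        if rule["kind"] == "cap":
            scores[comp] = score_cap(value, rule["hi"], rule["max_points"])
        else:
            scores[comp] = score_range(value, rule["lo"], rule["hi"], rule["max_points"])

    for comp, field in _FOOD_GROUP_FIELDS.items():
        target = table.lookup_target(comp, age)
        scores[comp] = score_food_group(getattr(usual, field), target, MAX_POINTS[comp])

    scores["excess_juice"] = score_cap(
        usual.fruit_juice, table.lookup_target("juice_limit", age), MAX_POINTS["excess_juice"]
    )
    scores["iron"] = score_iron(usual.iron, age, table)

    tv = score_tv(profile.tv_hours, age, table)
    energy = score_energy(usual.energy, table.lookup_target("eer", age), eer_formula)
    scores["tv_energy"] = (tv + energy) / 2.0

    return RCDQIComponentScores(child_id=usual.child_id, **scores)
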