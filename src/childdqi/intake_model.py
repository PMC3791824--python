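"""Demographic and dietary data model for child diet-quality scoring.

Holds the per-child demographic record (with the recoded age, income, and
ethnic strata used for stratified reporting), the per-recall-day intake
record expressed in MyPyramid-style food-group equivalents, and the
two-day-averaged "usual" intake that both scoring schemes consume.

Intake amounts arrive already disaggregated into food-group equivalents
(cup/oz), energy (kcal), nutrient quantities, and percent-of-energy terms;
no food-code disaggregation happens here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

AGE_GROUPS = ("preschool_2_5", "school_6_11", "teen_12_18")
INCOME_GROUPS = ("low", "medium", "high")
ETHNIC_GROUPS = ("hispanic_other", "nonhispanic_white", "nonhispanic_black")
SEXES = ("male", "female")

#: Raw survey race/ethnicity categories accepted by :func:`recode_ethnicity`.
RAW_ETHNICITIES = (
    "Mexican American",
    "other Hispanic",
    "white",
    "black or African American",
    "American Indian or Alaskan Native",
    "Asian",
    "Native Hawaiian or Pacific Islander",
    "other non-Hispanic",
)

PIR_CAP = 5.0


class SchemaError(ValueError):
    """An input table is missing a required column or holds an invalid value."""


@dataclass(frozen=True)
class ChildProfile:
    """Demographics and recoded strata for one child.

    ``tv_hours`` is daily screen time; ``None`` means not reported (it is
    imputed at scoring time, not here). ``pir`` is the poverty-income ratio,
    truncated at 5.0 in the source data.
    """

    child_id: str
    age: int
    sex: str
    ethnicity_raw: str
    pir: float
    tv_hours: Optional[float] = None

    def __post_init__(self) -> None:
        if not 2 <= self.age <= 18:
            raise ValueError(f"age must be in [2, 18], got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.pir <= PIR_CAP:
            raise ValueError(f"pir must be in [0, {PIR_CAP}], got {self.pir}")
        if self.tv_hours is not None and self.tv_hours < 0:
            raise ValueError("tv_hours must be nonnegative or None")
        recode_ethnicity(self.ethnicity_raw)  # validates

    @property
    def age_group(self) -> str:
        return assign_age_group(self.age)

    @property
    def income_group(self) -> str:
        return assign_income_group(self.pir)

    @property
    def ethnic_group(self) -> str:
        return recode_ethnicity(self.ethnicity_raw)


#: Intake fields shared by DailyIntake and UsualIntake, with a short note on units.
AMOUNT_FIELDS = (
    "energy",              # kcal
    "total_fruit",         # cup equivalents (includes juice)
    "whole_fruit",         # cup equivalents, no juice
    "fruit_juice",         # fluid ounces
    "total_veg",           # cup equivalents
    "dgo_veg_legumes",     # dark-green/orange vegetables and legumes, cup equiv
    "total_grains",        # oz equivalents
    "whole_grains",        # oz equivalents
    "dairy",               # cup equivalents
    "meat_beans",          # oz equivalents
    "oils",                # grams
    "sat_fat_pct",         # % of energy
    "sodium",              # grams
    "sofaas_pct",          # % of energy from solid fats, alcohol, added sugars
    "added_sugar_pct",     # % of energy
    "total_fat_pct",       # % of energy
    "linoleic_pct",        # % of energy
    "linolenic_pct",       # % of energy
    "dha_epa_pct_of_ala",  # DHA+EPA as % of alpha-linolenic acid
    "iron",                # mg
)

#: Fields already expressed relative to energy; never converted to densities.
PERCENT_FIELDS = (
    "sat_fat_pct",
    "sofaas_pct",
    "added_sugar_pct",
    "total_fat_pct",
    "linoleic_pct",
    "linolenic_pct",
    "dha_epa_pct_of_ala",
)

_BOUNDED_PERCENT_FIELDS = tuple(f for f in PERCENT_FIELDS if f != "dha_epa_pct_of_ala")


def _check_amounts(obj) -> None:
    for name in AMOUNT_FIELDS:
        v = getattr(obj, name)
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    if obj.energy <= 0:
        raise ValueError("energy must be > 0")
    if obj.whole_fruit > obj.total_fruit + 1e-9:
        raise ValueError("whole_fruit cannot exceed total_fruit")
    if obj.whole_grains > obj.total_grains + 1e-9:
        raise ValueError("whole_grains cannot exceed total_grains")
    for name in _BOUNDED_PERCENT_FIELDS:
        if getattr(obj, name) > 100:
            raise ValueError(f"{name} must be <= 100")


@dataclass(frozen=True)
class DailyIntake:
    """One 24-hour recall day's food-group and nutrient amounts for one child."""

    child_id: str
    day: int
    energy: float
    total_fruit: float = 0.0
    whole_fruit: float = 0.0
    fruit_juice: float = 0.0
    total_veg: float = 0.0
    dgo_veg_legumes: float = 0.0
    total_grains: float = 0.0
    whole_grains: float = 0.0
    dairy: float = 0.0
    meat_beans: float = 0.0
    oils: float = 0.0
    sat_fat_pct: float = 0.0
    sodium: float = 0.0
    sofaas_pct: float = 0.0
    added_sugar_pct: float = 0.0
    total_fat_pct: float = 0.0
    linoleic_pct: float = 0.0
    linolenic_pct: float = 0.0
    dha_epa_pct_of_ala: float = 0.0
    iron: float = 0.0

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        _check_amounts(self)


@dataclass(frozen=True)
class UsualIntake:
    """Field-wise arithmetic mean of a child's available recall days."""

    child_id: str
    n_days_used: int
    energy: float
    total_fruit: float = 0.0
    whole_fruit: float = 0.0
    fruit_juice: float = 0.0
    total_veg: float = 0.0
    dgo_veg_legumes: float = 0.0
    total_grains: float = 0.0
    whole_grains: float = 0.0
    dairy: float = 0.0
    meat_beans: float = 0.0
    oils: float = 0.0
    sat_fat_pct: float = 0.0
    sodium: float = 0.0
    sofaas_pct: float = 0.0
    added_sugar_pct: float = 0.0
    total_fat_pct: float = 0.0
    linoleic_pct: float = 0.0
    linolenic_pct: float = 0.0
    dha_epa_pct_of_ala: float = 0.0
    iron: float = 0.0

    def __post_init__(self) -> None:
        if self.n_days_used < 1:
            raise ValueError("n_days_used must be >= 1")
        _check_amounts(self)


def average_days(records: Sequence[DailyIntake]) -> UsualIntake:
    """Average one child's daily records field-wise into a usual intake.

    All records must belong to the same child; the mean is unweighted, so
    the result is invariant to record order.
    """
    if not records:
        raise ValueError("need at least one daily record")
    ids = {r.child_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix child_ids: {sorted(ids)}")
    means = {
        name: sum(getattr(r, name) for r in records) / len(records)
        for name in AMOUNT_FIELDS
    }
    return UsualIntake(child_id=records[0].child_id, n_days_used=len(records), **means)


def density_per_1000kcal(amount: float, energy: float) -> float:
    """Express an absolute intake amount per 1000 kcal of energy.

    Percent-of-energy fields are already energy-relative and must not be
    passed through this function.
    """
    if energy <= 0:
        raise ValueError(f"energy must be > 0, got {energy}")
    return amount * 1000.0 / energy


def assign_age_group(age: int) -> str:
    """Map completed years of age onto the three analysis age groups."""
    if not 2 <= age <= 18:
        raise ValueError(f"age must be in [2, 18], got {age}")
    if age <= 5:
        return "preschool_2_5"
    if age <= 11:
        return "school_6_11"
    return "teen_12_18"


def assign_income_group(pir: float) -> str:
    """Classify the poverty-income ratio into the food-assistance income strata.

    Low income (<=1.85 PIR) corresponds to income eligibility for USDA food
    assistance; high income is >=3.5 PIR; everything in between is medium.
    """
    if pir < 0:
        raise ValueError(f"pir must be >= 0, got {pir}")
    if pir <= 1.85:
        return "low"
    if pir >= 3.5:
        return "high"
    return "medium"


_ETHNICITY_MAP = {
    "mexican american": "hispanic_other",
    "other hispanic": "hispanic_other",
    "american indian or alaskan native": "hispanic_other",
    "asian": "hispanic_other",
    "native hawaiian or pacific islander": "hispanic_other",
    "other non-hispanic": "hispanic_other",
    "white": "nonhispanic_white",
    "black or african american": "nonhispanic_black",
}


def recode_ethnicity(ethnicity_raw: str) -> str:
    """Collapse raw survey race/ethnicity categories into three eating-culture groups.

    Mexican American, other Hispanic, and all remaining non-white/non-black
    categories form the Hispanic/other group; non-Hispanic white and
    non-Hispanic black are kept separate.
    """
    key = str(ethnicity_raw).strip().lower()
    try:
        return _ETHNICITY_MAP[key]
    except KeyError:
        raise ValueError(f"unknown ethnicity category: {ethnicity_raw!r}") from None


# ---------------------------------------------------------------------------
# CSV loaders


CHILDREN_COLUMNS = ("child_id", "age", "sex", "ethnicity_raw", "pir", "tv_hours")
INTAKE_COLUMNS = ("child_id", "day") + AMOUNT_FIELDS


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {', '.join(missing)}")


def profiles_from_frame(df: pd.DataFrame) -> list[ChildProfile]:
    """Build validated profiles from a children table.

    Non-integer ages are floored to completed years with a warning; a missing
    ``tv_hours`` value means screen time was not reported.
    """
    _require_columns(df, CHILDREN_COLUMNS, "children table")
    profiles = []
    for row in df.itertuples(index=False):
        age = float(row.age)
        if age != int(age):
            warnings.warn(
                f"child {row.child_id}: non-integer age {age} floored to {int(age)}",
                stacklevel=2,
            )
        tv = None if pd.isna(row.tv_hours) else float(row.tv_hours)
        profiles.append(
            ChildProfile(
                child_id=str(row.child_id),
                age=int(age),
                sex=str(row.sex),
                ethnicity_raw=str(row.ethnicity_raw),
                pir=float(row.pir),
                tv_hours=tv,
            )
        )
    return profiles


def load_children(path) -> list[ChildProfile]:
    """Read a children.csv file into validated profiles."""
    return profiles_from_frame(pd.read_csv(path))


def usual_from_frame(df: pd.DataFrame, require_two_days: bool = True) -> dict[str, UsualIntake]:
    """Average a child-day intake table into per-child usual intakes.

    By default children with fewer than two recall days are excluded, matching
    the study inclusion rule; pass ``require_two_days=False`` to keep them for
    sensitivity runs. Returns usual intakes keyed by child_id.
    """
    _require_columns(df, INTAKE_COLUMNS, "intake table")
    usual: dict[str, UsualIntake] = {}
    n_excluded = 0
    for child_id, group in df.groupby("child_id", sort=True):
        records = [
            DailyIntake(
                child_id=str(child_id),
                day=int(row.day),
                **{name: float(getattr(row, name)) for name in AMOUNT_FIELDS},
            )
            for row in group.itertuples(index=False)
        ]
        if require_two_days and len(records) < 2:
            n_excluded += 1
            continue
        usual[str(child_id)] = average_days(records)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} child(ren) with fewer than 2 recall days",
            stacklevel=2,
        )
    return usual


def load_intake(path, require_two_days: bool = True) -> dict[str, UsualIntake]:
    """Read an intake.csv file of child-days and average it per child."""
    return usual_from_frame(pd.read_csv(path), require_two_days=require_two_days)
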