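"""Healthy Eating Index 2005 component scoring.

Twelve components on a per-1000-kcal density basis, totalling 100 points.
Nine adequacy components (more is better) prorate linearly from zero intake
(0 points) up to a density standard (full points); three moderation
components (saturated fat, sodium, energy from solid fats / alcoholic
beverages / added sugars) earn full points at or below a favourable bound,
zero at or above an unfavourable one, and prorate linearly between the two.

Standards are shipped as a versioned data file (``data/hei2005_standards.csv``)
rather than being hard-coded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .intake_model import UsualIntake, density_per_1000kcal

ADEQUACY = "adequacy"
MODERATION = "moderation"

#: HEI component -> the UsualIntake field it is computed from.
COMPONENT_FIELDS: Mapping[str, str] = {
    "total_fruit": "total_fruit",
    "whole_fruit": "whole_fruit",
    "total_veg": "total_veg",
    "dgo_veg_legumes": "dgo_veg_legumes",
    "total_grains": "total_grains",
    "whole_grains": "whole_grains",
    "milk": "dairy",
    "meat_beans": "meat_beans",
    "oils": "oils",
    "sat_fat": "sat_fat_pct",
    "sodium": "sodium",
    "sofaas": "sofaas_pct",
}

#: Components whose input is already a percent of energy (no density step).
PERCENT_COMPONENTS = frozenset({"sat_fat", "sofaas"})

COMPONENTS = tuple(COMPONENT_FIELDS)


@dataclass(frozen=True)
class HEIStandard:
    """Scoring rule for one component: points, direction, and density anchors.

    For adequacy, ``max_standard`` is the density earning full points and the
    zero anchor is zero intake. For moderation, ``max_standard`` is the
    favourable (low) bound and ``min_standard`` the unfavourable (high) bound
    earning zero.
    """

    component: str
    max_points: float
    direction: str
    max_standard: float
    min_standard: float | None
    units: str

    def __post_init__(self) -> None:
        if self.direction not in (ADEQUACY, MODERATION):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.max_standard <= 0:
            raise ValueError("max_standard must be positive")
        if self.direction == MODERATION:
            if self.min_standard is None or self.min_standard <= self.max_standard:
                raise ValueError("moderation needs min_standard > max_standard")


def load_standards() -> dict[str, HEIStandard]:
    """Load the packaged HEI-2005 standards table."""
    text = resources.files("childdqi.data").joinpath("hei2005_standards.csv").read_text()
    out: dict[str, HEIStandard] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["component"]] = HEIStandard(
            component=row["component"],
            max_points=float(row["max_points"]),
            direction=row["direction"],
            max_standard=float(row["max_standard"]),
            min_standard=float(row["min_standard"]) if row["min_standard"] else None,
            units=row["units"],
        )
    return out


_STANDARDS = None


def standards() -> dict[str, HEIStandard]:
    global _STANDARDS
    if _STANDARDS is None:
        _STANDARDS = load_standards()
    return _STANDARDS


def score_adequacy(density: float, standard: HEIStandard) -> float:
    """Linear proration from zero intake (0 points) to the standard (full points).

    Zero points are earned only by zero intake; meeting or exceeding the
    standard earns the maximum.
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    if standard.direction != ADEQUACY:
        raise ValueError(f"{standard.component} is not an adequacy component")
    return standard.max_points * min(1.0, density / standard.max_standard)


def score_moderation(value: float, standard: HEIStandard) -> float:
    """Linear proration between the favourable and unfavourable bounds.

    At or below ``max_standard`` earns full points; at or above
    ``min_standard`` earns zero; one linear segment in between.
    """
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    if standard.direction != MODERATION:
        raise ValueError(f"{standard.component} is not a moderation component")
    lo, hi = standard.max_standard, standard.min_standard
    if value <= lo:
        return standard.max_points
    if value >= hi:
        return 0.0
    return standard.max_points * (hi - value) / (hi - lo)


@dataclass(frozen=True)
class HEIComponentScores:
    """Per-component HEI-2005 points for one child."""

    child_id: str
    total_fruit: float
    whole_fruit: float
    total_veg: float
    dgo_veg_legumes: float
    total_grains: float
    whole_grains: float
    milk: float
    meat_beans: float
    oils: float
    sat_fat: float
    sodium: float
    sofaas: float

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["total"] = self.total
        return d


def score_hei(
    usual: UsualIntake, proration: str = "paper_linear"
) -> HEIComponentScores:
    """Score all twelve HEI-2005 components for one child's usual intake.

    Density components are first expressed per 1000 kcal; percent-of-energy
    components pass through unchanged. ``proration`` selects the moderation
    interpolation: ``paper_linear`` (single segment between the printed
    anchors, the default) or ``technical_piecewise`` (the official technical
    report's multi-breakpoint curve; reserved, not implemented).
    """
    if proration == "technical_piecewise":
        raise NotImplementedError(
            "technical_piecewise proration is reserved but not implemented"
        )
    if proration != "paper_linear":
        raise ValueError(f"unknown proration mode {proration!r}")
    stds = standards()
    scores: dict[str, float] = {}
    for comp, field in COMPONENT_FIELDS.items():
        raw = getattr(usual, field)
        value = raw if comp in PERCENT_COMPONENTS else density_per_1000kcal(raw, usual.energy)
        std = stds[comp]
        if std.direction == ADEQUACY:
            scores[comp] = score_adequacy(value, std)
        else:
            scores[comp] = score_moderation(value, std)
    return HEIComponentScores(child_id=usual.child_id, **scores)
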