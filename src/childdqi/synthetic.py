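"""Synthetic NHANES-like child dietary survey generator.

Emulates the structure of a two-day 24-hour-recall survey of children 2-18:
per-child demographics (age sampled by age-group proportions, sex, raw
race/ethnicity, poverty-income ratio truncated at 5.0, daily TV hours with a
missingness rate) and two per-day intake records disaggregated into food-group
equivalents, energy, and nutrient terms.

The statistical skeleton, chosen to mirror how such data behave rather than
to calibrate any population value:

* Episodically consumed food groups are zero-inflated: with probability
  ``p_zero`` a child is a structural non-consumer of a group (zero on both
  days); consumers' amounts are gamma-distributed.
* A per-child latent diet-quality factor z ~ Normal(0, 1) shifts every
  component's log-mean by ``lam * z``, inducing weak positive correlation
  among adequacy components (negative loadings are used for
  moderation-direction quantities such as SoFAAS).
* Food-group amounts are drawn as densities (per 1000 kcal) and multiplied by
  the day's energy, so amounts co-vary with energy as in real recalls.
* Hierarchical components (whole fruit within total fruit, dark-green/orange
  vegetables within total vegetables, whole grains within total grains) are
  generated as per-child beta shares of the parent amount, which guarantees
  the part <= whole invariants.
* Day 2 correlates with day 1 through the shared child-level mean; the
  within-person day-to-day coefficient of variation is configurable.
* Energy is lognormal around an age-indexed mean anchored near published
  child energy requirements.

Everything is driven by a single top-level seed; a given (config, seed) pair
reproduces its output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .intake_model import AMOUNT_FIELDS
from .rcdqi import get_table

AGE_GROUP_RANGES = {
    "preschool_2_5": (2, 5),
    "school_6_11": (6, 11),
    "teen_12_18": (12, 18),
}

#: Study-shaped age-group proportions (1,405 : 1,586 : 2,945 children).
STUDY_AGE_COUNTS = (1405, 1586, 2945)
STUDY_N = sum(STUDY_AGE_COUNTS)

_RAW_BY_GROUP = {
    "hispanic_other": ("Mexican American", "other Hispanic", "Asian", "other non-Hispanic"),
    "nonhispanic_white": ("white",),
    "nonhispanic_black": ("black or African American",),
}


@dataclass(frozen=True)
class ComponentModel:
    """Generative model for one intake component.

    ``mean`` is the population mean on the component's natural scale: a
    density per 1000 kcal for food groups and sodium, a percent of energy for
    percent fields, mg/day for iron. ``p_zero`` is the structural
    non-consumer probability; ``lam`` the loading on the latent quality
    factor (negative for quantities where more is worse); ``sigma_between``
    the between-child lognormal spread.
    """

    mean: float
    p_zero: float = 0.0
    lam: float = 0.0
    sigma_between: float = 0.45

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must be in [0, 1]")
        if self.sigma_between < 0:
            raise ValueError("sigma_between must be >= 0")


#: Density-scale components (amount/day = density * energy/1000).
_DENSITY_COMPONENTS = (
    "total_fruit", "fruit_juice", "total_veg", "total_grains",
    "dairy", "meat_beans", "oils", "sodium",
)
#: Beta-share components carving a child-constant fraction out of a parent.
_SHARE_COMPONENTS = {
    "whole_fruit_share": "total_fruit",
    "dgo_share": "total_veg",
    "whole_grains_share": "total_grains",
}
_PERCENT_COMPONENTS = (
    "sat_fat_pct", "sofaas_pct", "added_sugar_pct", "total_fat_pct",
    "linoleic_pct", "linolenic_pct", "dha_epa_pct_of_ala",
)
_ABSOLUTE_COMPONENTS = ("iron",)


def _default_components() -> dict[str, ComponentModel]:
    """Typical US-child intake levels, expressed on each component's scale."""
    return {
        # cup/oz/gram equivalents per 1000 kcal
        "total_fruit": ComponentModel(mean=0.55, p_zero=0.10, lam=0.17),
        "fruit_juice": ComponentModel(mean=3.5, p_zero=0.30, lam=0.0),
        "total_veg": ComponentModel(mean=0.65, p_zero=0.02, lam=0.17),
        "total_grains": ComponentModel(mean=3.4, p_zero=0.0, lam=0.17, sigma_between=0.30),
        "dairy": ComponentModel(mean=1.05, p_zero=0.01, lam=0.17),
        "meat_beans": ComponentModel(mean=2.2, p_zero=0.01, lam=0.15, sigma_between=0.35),
        "oils": ComponentModel(mean=8.0, p_zero=0.02, lam=0.10, sigma_between=0.40),
        "sodium": ComponentModel(mean=1.5, lam=-0.15, sigma_between=0.25),
        # shares of a parent amount (mean is the mean share in (0, 1))
        "whole_fruit_share": ComponentModel(mean=0.55, p_zero=0.15, lam=0.20),
        "dgo_share": ComponentModel(mean=0.15, p_zero=0.10, lam=0.20),
        "whole_grains_share": ComponentModel(mean=0.12, p_zero=0.22, lam=0.17),
        # percent of energy (DHA+EPA is percent of alpha-linolenic acid)
        "sat_fat_pct": ComponentModel(mean=11.0, lam=-0.15, sigma_between=0.20),
        "sofaas_pct": ComponentModel(mean=35.0, lam=-0.30, sigma_between=0.25),
        "added_sugar_pct": ComponentModel(mean=16.0, lam=-0.30, sigma_between=0.35),
        "total_fat_pct": ComponentModel(mean=32.0, lam=0.0, sigma_between=0.15),
        "linoleic_pct": ComponentModel(mean=5.5, lam=0.0, sigma_between=0.30),
        "linolenic_pct": ComponentModel(mean=0.65, lam=0.10, sigma_between=0.35),
        "dha_epa_pct_of_ala": ComponentModel(mean=6.0, p_zero=0.10, lam=0.10, sigma_between=0.60),
        # absolute per-day quantities
        "iron": ComponentModel(mean=13.0, lam=0.25, sigma_between=0.30),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic survey draw."""

    n_children: int = 1000
    seed: int = 0
    age_group_props: tuple[float, float, float] = tuple(
        c / STUDY_N for c in STUDY_AGE_COUNTS
    )
    ethnic_props: tuple[float, float, float] = (0.35, 0.35, 0.30)  # hisp/other, white, black
    pir_mu: float = 0.6     # log-scale location of the PIR lognormal
    pir_sigma: float = 0.7
    components: Mapping[str, ComponentModel] = field(default_factory=_default_components)
    day_cv: float = 0.35          # within-person day-to-day CV of consumed amounts
    share_concentration: float = 3.0  # beta concentration of part-of-whole shares
    energy_scale: float = 1.0     # multiplier on the age-indexed mean energy
    energy_sigma: float = 0.12    # between-child lognormal spread of energy
    energy_day_cv: float = 0.15
    tv_median_hours: float = 2.5
    tv_sigma: float = 0.5
    tv_missing_rate: float = 0.08

    def __post_init__(self) -> None:
        for name, props in (("age_group_props", self.age_group_props),
                            ("ethnic_props", self.ethnic_props)):
            if len(props) != 3 or any(p < 0 for p in props):
                raise ValueError(f"{name} must be 3 nonnegative proportions")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.day_cv < 0 or self.energy_day_cv < 0:
            raise ValueError("day-to-day CVs must be >= 0")
        if not 0 <= self.tv_missing_rate <= 1:
            raise ValueError("tv_missing_rate must be in [0, 1]")
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")


def preset_study_shape(n_children: int = STUDY_N, seed: int = 0) -> SimConfig:
    """Configuration shaped like the study sample.

    Age-group proportions follow the 1,405/1,586/2,945 split, whole grains
    and juice carry moderate zero-inflation, and the latent-quality loadings
    put within-index component correlations in the weakly-positive band that
    characterises real recall data.
    """
    return SimConfig(n_children=n_children, seed=seed)


def _lognormal_factor(rng: np.random.Generator, sigma: float, shift: np.ndarray) -> np.ndarray:
    """exp(shift + sigma*eps), mean-corrected so E[factor | shift=0] = 1."""
    eps = rng.standard_normal(shift.shape[0])
    return np.exp(shift + sigma * eps - 0.5 * sigma**2)


def _gamma_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 gamma multiplicative noise with the given CV (1.0 if cv == 0)."""
    if cv == 0:
        return np.ones(size)
    shape = 1.0 / cv**2
    return rng.gamma(shape, 1.0 / shape, size=size)


def expected_zero_rate(config: SimConfig, component: str) -> float:
    """Structural-zero probability for one of the five comparable food groups.

    Whole grains compound the total-grain and whole-grain-share zero
    probabilities, since either makes whole-grain intake zero.
    """
    c = config.components
    simple = {
        "fruit": "total_fruit",
        "vegetables": "total_veg",
        "total_grains": "total_grains",
        "dairy": "dairy",
    }
    if component in simple:
        return c[simple[component]].p_zero
    if component == "whole_grains":
        return 1.0 - (1.0 - c["total_grains"].p_zero) * (1.0 - c["whole_grains_share"].p_zero)
    raise KeyError(f"unknown comparable component {component!r}")


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic survey: a children table and a two-day intake table.

    Returns ``(children, intake)`` in the loader schemas of
    :mod:`childdqi.intake_model`. Deterministic given the config (which
    includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    # demographics -----------------------------------------------------
    group_idx = rng.choice(3, size=n, p=np.asarray(config.age_group_props))
    groups = np.array(list(AGE_GROUP_RANGES), dtype=object)[group_idx]
    ages = np.array([
        rng.integers(AGE_GROUP_RANGES[g][0], AGE_GROUP_RANGES[g][1] + 1) for g in groups
    ])
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    eth_idx = rng.choice(3, size=n, p=np.asarray(config.ethnic_props))
    eth_groups = np.array(list(_RAW_BY_GROUP), dtype=object)[eth_idx]
    ethnicity_raw = np.array(
        [_RAW_BY_GROUP[g][rng.integers(len(_RAW_BY_GROUP[g]))] for g in eth_groups],
        dtype=object,
    )
    pir = np.minimum(5.0, rng.lognormal(config.pir_mu, config.pir_sigma, size=n))
    tv = rng.lognormal(np.log(config.tv_median_hours), config.tv_sigma, size=n)
    tv_missing = rng.random(n) < config.tv_missing_rate
    tv_out = np.where(tv_missing, np.nan, np.round(tv, 2))

    child_ids = np.array([f"c{i:06d}" for i in range(n)], dtype=object)
    children = pd.DataFrame(
        {
            "child_id": child_ids,
            "age": ages,
            "sex": sexes,
            "ethnicity_raw": ethnicity_raw,
            "pir": np.round(pir, 3),
            "tv_hours": tv_out,
        }
    )

    # latent diet quality ----------------------------------------------
    z = rng.standard_normal(n)

    # energy: child-level mean near the age-indexed requirement ----------
    eer_table = get_table("table_b")
    eer = np.array([eer_table.lookup_target("eer", int(a)) for a in ages])
    child_energy = (
        config.energy_scale * eer * _lognormal_factor(rng, config.energy_sigma, np.zeros(n))
    )
    energy_days = child_energy[:, None] * _gamma_noise(rng, config.energy_day_cv, (n, 2))
    energy_days = np.maximum(energy_days, 50.0)  # recalls are never ~zero energy

    # per-component child means and day draws ---------------------------
    def child_day_values(model: ComponentModel, clip_pct: bool = False) -> np.ndarray:
        consumer = rng.random(n) >= model.p_zero
        mean = model.mean * _lognormal_factor(rng, model.sigma_between, model.lam * z)
        days = mean[:, None] * _gamma_noise(rng, config.day_cv, (n, 2))
        days *= consumer[:, None]
        if clip_pct:
            days = np.minimum(days, 95.0)
        return days

    comp = dict(config.components)
    values: dict[str, np.ndarray] = {}
    for name in _DENSITY_COMPONENTS:
        values[name] = child_day_values(comp[name]) * energy_days / 1000.0
    for name in _ABSOLUTE_COMPONENTS:
        values[name] = child_day_values(comp[name])
    for name in _PERCENT_COMPONENTS:
        values[name] = child_day_values(comp[name], clip_pct=True)

    # shares: child-constant beta fraction of the parent amount
    for share_name, parent in _SHARE_COMPONENTS.items():
        model = comp[share_name]
        consumer = rng.random(n) >= model.p_zero
        m = np.clip(model.mean * np.exp(model.lam * z), 0.01, 0.95)
        kappa = config.share_concentration
        share = rng.beta(m * kappa, (1 - m) * kappa)
        # consumers' shares are floored at 0.1%: a recall never records a
        # physically meaningless 1e-12 oz of a consumed food
        share = np.clip(share, 1e-3, 1.0) * consumer
        values[share_name] = share[:, None] * values[parent]

    # SoFAAS must be able to cover added sugar; keep it the larger of the two
    values["sofaas_pct"] = np.maximum(values["sofaas_pct"], values["added_sugar_pct"])

    # amounts are written at full precision: rounding would turn very small
    # consumed amounts into spurious zero-consumer records
    intake = pd.DataFrame(
        {
            "child_id": np.repeat(child_ids, 2),
            "day": np.tile([1, 2], n),
            "energy": np.round(energy_days.reshape(-1), 1),
            "total_fruit": values["total_fruit"].reshape(-1),
            "whole_fruit": values["whole_fruit_share"].reshape(-1),
            "fruit_juice": values["fruit_juice"].reshape(-1),
            "total_veg": values["total_veg"].reshape(-1),
            "dgo_veg_legumes": values["dgo_share"].reshape(-1),
            "total_grains": values["total_grains"].reshape(-1),
            "whole_grains": values["whole_grains_share"].reshape(-1),
            "dairy": values["dairy"].reshape(-1),
            "meat_beans": values["meat_beans"].reshape(-1),
            "oils": values["oils"].reshape(-1),
            "sat_fat_pct": values["sat_fat_pct"].reshape(-1),
            "sodium": values["sodium"].reshape(-1),
            "sofaas_pct": values["sofaas_pct"].reshape(-1),
            "added_sugar_pct": values["added_sugar_pct"].reshape(-1),
            "total_fat_pct": values["total_fat_pct"].reshape(-1),
            "linoleic_pct": values["linoleic_pct"].reshape(-1),
            "linolenic_pct": values["linolenic_pct"].reshape(-1),
            "dha_epa_pct_of_ala": values["dha_epa_pct_of_ala"].reshape(-1),
            "iron": values["iron"].reshape(-1),
        }
    )
    assert tuple(intake.columns) == ("child_id", "day") + AMOUNT_FIELDS
    return children, intake


def with_component(config: SimConfig, name: str, **changes) -> SimConfig:
    """Copy of ``config`` with one component model's parameters changed."""
    comps = dict(config.components)
    comps[name] = replace(comps[name], **changes)
    return replace(config, components=comps)


def with_all_p_zero(config: SimConfig, p_zero: float) -> SimConfig:
    """Copy of ``config`` with every component's zero-inflation set to ``p_zero``."""
    comps = {k: replace(v, p_zero=p_zero) for k, v in config.components.items()}
    return replace(config, components=comps)
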