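"""Shared fixtures: hand-built diets at the scoring anchors, small synthetic draws."""

import pytest
from hypothesis import settings

from childdqi import ChildProfile, UsualIntake
from childdqi.rcdqi import get_table

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_usual(child_id="c1", n_days_used=2, energy=2000.0, **amounts) -> UsualIntake:
    """UsualIntake with unspecified amounts left at zero."""
    return UsualIntake(child_id=child_id, n_days_used=n_days_used, energy=energy, **amounts)


@pytest.fixture
def perfect_hei_usual() -> UsualIntake:
    """A diet meeting every adequacy standard and every moderation bound (HEI 100)."""
    return make_usual(
        energy=2000.0,
        total_fruit=1.6,       # 0.8 c / 1000 kcal
        whole_fruit=0.8,       # 0.4
        total_veg=2.2,         # 1.1
        dgo_veg_legumes=0.8,   # 0.4
        total_grains=6.0,      # 3.0 oz
        whole_grains=3.0,      # 1.5 oz
        dairy=2.6,             # 1.3 c
        meat_beans=5.0,        # 2.5 oz
        oils=24.0,             # 12 g
        sat_fat_pct=7.0,
        sodium=1.4,            # 0.7 g / 1000 kcal
        sofaas_pct=20.0,
    )


@pytest.fixture
def worst_hei_usual() -> UsualIntake:
    """Zero consumption with moderation quantities at their zero-score bounds (HEI 0)."""
    return make_usual(
        energy=2000.0,
        sat_fat_pct=15.0,
        sodium=4.0,            # 2.0 g / 1000 kcal
        sofaas_pct=50.0,
    )


def perfect_rcdqi_inputs(age: int, variant: str = "table_b"):
    """(profile, usual) pair that earns every RC-DQI point at the given age."""
    t = get_table(variant)
    tg = t.lookup_target("total_grains", age)
    wg = t.lookup_target("whole_grains", age)
    profile = ChildProfile(
        child_id="c1", age=age, sex="female", ethnicity_raw="white", pir=2.0, tv_hours=1.0
    )
    usual = make_usual(
        energy=t.lookup_target("eer", age),
        total_fruit=t.lookup_target("fruit", age),
        whole_fruit=min(t.lookup_target("fruit", age), 0.5),
        fruit_juice=t.lookup_target("juice_limit", age),
        total_veg=t.lookup_target("vegetable", age),
        total_grains=tg,
        whole_grains=min(wg, tg),
        dairy=t.lookup_target("dairy", age),
        added_sugar_pct=8.0,
        total_fat_pct=32.0 if age <= 3 else 30.0,
        linoleic_pct=7.0,
        linolenic_pct=0.9,
        dha_epa_pct_of_ala=5.0,
        iron=t.iron_band(age).rda_mg,
    )
    return profile, usual


@pytest.fixture
def perfect_rcdqi_age4():
    return perfect_rcdqi_inputs(4)
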