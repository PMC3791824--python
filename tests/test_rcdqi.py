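"""RC-DQI scoring: age-indexed targets, proportional deduction, categorical iron,
combined TV/energy component, and the table-b/table-c variant contract."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from childdqi import rcdqi
from childdqi.intake_model import ChildProfile
from tests.conftest import make_usual, perfect_rcdqi_inputs

TB = rcdqi.get_table("table_b")
TC = rcdqi.get_table("table_c")


class TestTargetLookup:
    @pytest.mark.parametrize(
        "component,age,target",
        [
            ("total_grains", 2, 3.0),
            ("total_grains", 9, 6.0),
            ("total_grains", 14, 7.0),
            ("whole_grains", 4, 2.0),
            ("fruit", 2, 1.5),
            ("fruit", 9, 2.0),
            ("vegetable", 2, 1.0),
            ("vegetable", 14, 4.0),
            ("dairy", 8, 2.0),
            ("dairy", 9, 3.0),
            ("juice_limit", 6, 6.0),
            ("juice_limit", 7, 12.0),
            ("eer", 2, 1072.0),
            ("eer", 18, 1690.0),
        ],
    )
    def test_table_b_cells(self, component, age, target):
        assert TB.lookup_target(component, age) == target

    @pytest.mark.parametrize(
        "component,age,target",
        [
            ("total_grains", 4, 5.0),
            ("total_grains", 14, 9.0),
            ("whole_grains", 14, 4.5),
            ("fruit", 14, 3.0),
            ("vegetable", 9, 4.0),
            ("eer", 2, 1120.0),
            ("eer", 18, 2383.0),
        ],
    )
    def test_table_c_cells(self, component, age, target):
        assert TC.lookup_target(component, age) == target

    def test_age_out_of_range(self):
        with pytest.raises(ValueError):
            TB.lookup_target("fruit", 1)
        with pytest.raises(ValueError):
            TB.lookup_target("fruit", 19)

    def test_every_age_resolves_every_component(self):
        for table in (TB, TC):
            for age in range(2, 19):
                for comp in ("total_grains", "whole_grains", "fruit", "vegetable",
                             "dairy", "juice_limit", "eer"):
                    assert table.lookup_target(comp, age) > 0
                assert table.iron_band(age).rda_mg > table.iron_band(age).ear_mg
                assert table.tv_imputation_hours(age) > 0


class TestFoodGroup:
    @pytest.mark.parametrize(
        "intake,target,maxp,points",
        [(2.0, 2.0, 10.0, 10.0), (0.0, 2.0, 10.0, 0.0), (1.0, 2.0, 10.0, 5.0),
         (6.0, 6.0, 5.0, 5.0), (9.0, 6.0, 5.0, 5.0)],
    )
    def test_proportional_deduction(self, intake, target, maxp, points):
        assert rcdqi.score_food_group(intake, target, maxp) == pytest.approx(points)

    @given(intake=st.floats(0, 20), target=st.floats(0.5, 10), maxp=st.sampled_from([5.0, 10.0]))
    def test_zero_iff_zero_and_bounds(self, intake, target, maxp):
        s = rcdqi.score_food_group(intake, target, maxp)
        assert 0 <= s <= maxp
        assert (s == 0.0) == (intake == 0.0)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            rcdqi.score_food_group(1.0, 0.0, 10.0)


class TestRangeAndCap:
    def test_range_anchors(self):
        assert rcdqi.score_range(35.0, 30.0, 40.0, 2.5) == 2.5
        assert rcdqi.score_range(0.0, 30.0, 40.0, 2.5) == 0.0
        # below-range branch: 2.5 * 15/30
        assert rcdqi.score_range(15.0, 30.0, 40.0, 2.5) == pytest.approx(1.25)

    def test_cap_anchors(self):
        assert rcdqi.score_cap(10.0, 10.0, 10.0) == 10.0
        # ratio decay above the cap: 10 * 10/20
        assert rcdqi.score_cap(20.0, 10.0, 10.0) == pytest.approx(5.0)
        assert rcdqi.score_cap(6.0, 6.0, 10.0) == 10.0

    @pytest.mark.parametrize("fn,args", [
        (rcdqi.score_range, (5.0, 0.0, 10.0, 2.5)),
        (rcdqi.score_range, (5.0, 10.0, 5.0, 2.5)),
        (rcdqi.score_cap, (5.0, 0.0, 10.0)),
    ])
    def test_invalid_bounds_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_continuity_at_breakpoints(self):
        """Every continuous scoring rule is continuous across its anchors."""
        eps = 1e-9
        for x0 in (30.0, 40.0):
            lo_side = rcdqi.score_range(x0 - eps, 30.0, 40.0, 2.5)
            hi_side = rcdqi.score_range(x0 + eps, 30.0, 40.0, 2.5)
            assert lo_side == pytest.approx(hi_side, abs=1e-6)
        assert rcdqi.score_cap(10.0 - eps, 10.0, 10.0) == pytest.approx(
            rcdqi.score_cap(10.0 + eps, 10.0, 10.0), abs=1e-6
        )
        assert rcdqi.score_tv(2.0 - eps, 5, TB) == pytest.approx(
            rcdqi.score_tv(2.0 + eps, 5, TB), abs=1e-6
        )
        eer = 1000.0
        for edge in (900.0, 1100.0):
            assert rcdqi.score_energy(edge - 1e-6, eer) == pytest.approx(
                rcdqi.score_energy(edge + 1e-6, eer), abs=1e-6
            )

    @given(v=st.floats(0, 60))
    def test_range_monotone_toward_interval(self, v):
        """Moving toward the recommended interval never lowers the score."""
        s = rcdqi.score_range(v, 30.0, 40.0, 2.5)
        closer = min(max(v, 30.0), 40.0)
        assert rcdqi.score_range(closer, 30.0, 40.0, 2.5) >= s - 1e-12


class TestIron:
    @pytest.mark.parametrize(
        "age,intake,points",
        [
            (2, 2.0, 0.0), (2, 3.0, 0.0), (2, 5.0, 5.0), (2, 7.0, 10.0),
            (5, 4.1, 0.0), (5, 9.9, 5.0), (5, 10.0, 10.0),
            (10, 5.7, 0.0), (10, 7.9, 5.0), (10, 8.0, 10.0),
            (16, 7.9, 0.0), (16, 14.9, 5.0), (16, 15.0, 10.0),
        ],
    )
    def test_table_b_bands(self, age, intake, points):
        assert rcdqi.score_iron(intake, age, TB) == points

    @pytest.mark.parametrize(
        "age,intake,points",
        [(10, 5.9, 0.0), (10, 7.9, 5.0), (10, 8.0, 10.0),
         (16, 7.7, 0.0), (16, 10.9, 5.0), (16, 11.0, 10.0)],
    )
    def test_table_c_bands(self, age, intake, points):
        assert rcdqi.score_iron(intake, age, TC) == points

    def test_only_three_levels(self):
        grid = np.linspace(0, 30, 500)
        assert {rcdqi.score_iron(float(x), 9, TB) for x in grid} == {0.0, 5.0, 10.0}


class TestTVAndEnergy:
    def test_tv_anchors(self):
        assert rcdqi.score_tv(2.0, 4, TB) == 10.0
        assert rcdqi.score_tv(0.0, 4, TB) == 10.0
        assert rcdqi.score_tv(4.0, 4, TB) == pytest.approx(5.0)  # decay 10 * 2/4

    @pytest.mark.parametrize("age,hours", [(4, 2.0), (10, 4.0), (16, 3.5)])
    def test_missing_tv_imputed_by_age_band(self, age, hours):
        assert TB.tv_imputation_hours(age) == hours
        assert rcdqi.score_tv(None, age, TB) == rcdqi.score_tv(hours, age, TB)

    def test_energy_window_and_decay(self):
        eer = 1000.0
        assert rcdqi.score_energy(eer, eer) == 10.0
        assert rcdqi.score_energy(900.0, eer) == 10.0   # window edge
        assert rcdqi.score_energy(1100.0, eer) == 10.0
        assert rcdqi.score_energy(450.0, eer) == pytest.approx(5.0)  # half the low edge
        assert rcdqi.score_energy(2200.0, eer) == pytest.approx(5.0)
        assert rcdqi.score_energy(0.0, eer) == 0.0

    def test_literal_formula_is_discontinuous_at_window(self):
        """The published percentage-deduction wording collapses at the edges."""
        eer = 1000.0
        assert rcdqi.score_energy(899.999, eer, formula="literal") == pytest.approx(
            0.0, abs=1e-2
        )
        assert rcdqi.score_energy(900.0, eer, formula="literal") == 10.0

    @given(energy=st.floats(0, 5000))
    def test_energy_zero_only_at_zero(self, energy):
        s = rcdqi.score_energy(energy, 1500.0)
        assert 0 <= s <= 10
        assert (s == 0.0) == (energy == 0.0)


class TestScoreRCDQI:
    @pytest.mark.parametrize("age", [2, 4, 9, 14, 18])
    @pytest.mark.parametrize("variant", ["table_b", "table_c"])
    def test_meeting_every_target_totals_90(self, age, variant):
        profile, usual = perfect_rcdqi_inputs(age, variant)
        scores = rcdqi.score_rcdqi(profile, usual, table_variant=variant)
        for comp in rcdqi.COMPONENTS:
            assert getattr(scores, comp) == pytest.approx(rcdqi.MAX_POINTS[comp]), comp
        assert scores.total == pytest.approx(90.0)

    def test_zero_consumption_zeroes_every_deficiency_component(self):
        """Zero intake zeroes every shortfall-scored component; the cap-type
        components (added sugar, juice, DHA/EPA) reward absence with full
        points by construction."""
        profile = ChildProfile("c1", 7, "male", "white", 1.0, tv_hours=24.0)
        usual = make_usual(energy=1e-6)
        scores = rcdqi.score_rcdqi(profile, usual)
        for comp in ("fat", "linoleic", "linolenic", "total_grains", "whole_grains",
                     "fruit", "vegetable", "dairy", "iron"):
            assert getattr(scores, comp) == pytest.approx(0.0), comp
        for comp in ("added_sugar", "excess_juice", "dha_epa"):
            assert getattr(scores, comp) == pytest.approx(rcdqi.MAX_POINTS[comp]), comp
        # screen time can never reach exactly zero under ratio decay
        assert scores.tv_energy == pytest.approx((10.0 * 2.0 / 24.0) / 2.0, abs=1e-6)

    def test_age9_grain_example(self):
        profile = ChildProfile("c1", 9, "female", "white", 2.0, tv_hours=1.0)
        usual = make_usual(energy=1415.0, total_grains=6.0)
        scores = rcdqi.score_rcdqi(profile, usual, table_variant="table_b")
        assert scores.total_grains == pytest.approx(5.0)

    def test_variants_differ_only_where_tables_differ(self):
        """Age 2 rows match between tables; age 14 rows diverge for grains/fruit/veg."""
        profile2, usual2 = perfect_rcdqi_inputs(2, "table_b")
        b = rcdqi.score_rcdqi(profile2, usual2, table_variant="table_b")
        c = rcdqi.score_rcdqi(profile2, usual2, table_variant="table_c")
        # at age 2 only the EER differs between the printed tables
        for comp in rcdqi.COMPONENTS:
            if comp == "tv_energy":
                continue
            assert getattr(b, comp) == pytest.approx(getattr(c, comp)), comp

        profile14 = ChildProfile("c1", 14, "male", "white", 2.0, tv_hours=1.0)
        usual14 = make_usual(
            energy=1718.0, total_grains=7.0, whole_grains=3.5, total_fruit=2.0,
            total_veg=4.0, dairy=3.0,
        )
        b14 = rcdqi.score_rcdqi(profile14, usual14, table_variant="table_b")
        c14 = rcdqi.score_rcdqi(profile14, usual14, table_variant="table_c")
        assert b14.total_grains == pytest.approx(5.0)
        assert c14.total_grains == pytest.approx(5.0 * 7.0 / 9.0)
        assert b14.fruit == pytest.approx(10.0)
        assert c14.fruit == pytest.approx(10.0 * 2.0 / 3.0)
        # dairy target is identical in both tables
        assert b14.dairy == c14.dairy

    @given(
        age=st.integers(2, 18),
        fruit=st.floats(0, 6, allow_subnormal=False),
        veg=st.floats(0, 6, allow_subnormal=False),
        grains=st.floats(0, 12, allow_subnormal=False),
        wg_frac=st.one_of(st.just(0.0), st.floats(1e-6, 1)),
        dairy=st.floats(0, 6, allow_subnormal=False),
        energy=st.floats(500, 4000),
        tv=st.floats(0, 16),
    )
    def test_total_bounded_and_zero_contract(
        self, age, fruit, veg, grains, wg_frac, dairy, energy, tv
    ):
        profile = ChildProfile("c1", age, "female", "white", 2.0, tv_hours=tv)
        usual = make_usual(
            energy=energy, total_fruit=fruit, total_veg=veg, total_grains=grains,
            whole_grains=grains * wg_frac, dairy=dairy,
        )
        scores = rcdqi.score_rcdqi(profile, usual)
        assert 0 <= scores.total <= 90 + 1e-9
        for comp in ("fruit", "vegetable", "total_grains", "whole_grains", "dairy"):
            intake = {
                "fruit": fruit, "vegetable": veg, "total_grains": grains,
                "whole_grains": grains * wg_frac, "dairy": dairy,
            }[comp]
            assert (getattr(scores, comp) == 0.0) == (intake == 0.0), comp
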