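"""Nutrient-profile scoring: categories, point tables, the score identity."""

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from nutriswitch import (FvnlComposition, NpscCategory, PointTables,
                         ScoredDatabase, baseline_points, determine_category,
                         fvnl_percent, modifying_points, score_record)
from nutriswitch.npsc import (CHEESE_CALCIUM_CUTOFF_MG, FvnlLookup, StepTable,
                              point_tables_from_dict)

from conftest import make_panel, make_record


def oracle_points(value, thresholds):
    """Independent step-table oracle: one point per threshold strictly exceeded."""
    return sum(1 for t in thresholds if value > t)


class TestStepTable:
    @settings(max_examples=200, derandomize=True)
    @given(value=st.floats(0, 5000))
    def test_matches_linear_scan_oracle(self, value):
        table = PointTables().energy
        assert table.points(value) == oracle_points(value, table.thresholds)

    def test_equality_with_threshold_awards_no_point(self):
        # energy table steps at 335 kJ: a point needs strictly more
        table = PointTables().energy
        assert table.points(335.0) == 0
        assert table.points(335.0001) == 1
        assert table.points(670.0) == 1  # one full step completed, second not exceeded

    def test_caps(self):
        t = PointTables()
        assert t.energy.points(1e9) == 10
        assert t.saturated_fat.points(1e9) == 30
        assert t.sugars.points(1e9) == 10
        assert t.sodium.points(1e9) == 30
        assert t.protein.points(1e9) == 5
        assert t.fiber.points(1e9) == 2

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            StepTable((1.0, 1.0, 2.0))


class TestCategoryDetermination:
    def test_beverage_is_category_1(self, small_db):
        assert determine_category(small_db.records["9300000000086"],
                                  small_db.categories) is NpscCategory.BEVERAGES

    def test_oils_are_category_3_unconditionally(self, small_db):
        assert determine_category(small_db.records["9300000000062"],
                                  small_db.categories) is NpscCategory.OILS_SPREADS_CHEESE

    @pytest.mark.parametrize("calcium,expected", [
        (400.0, NpscCategory.OILS_SPREADS_CHEESE),
        (321.0, NpscCategory.OILS_SPREADS_CHEESE),
        (320.0, NpscCategory.OTHER_FOODS),   # cutoff is strict
        (100.0, NpscCategory.OTHER_FOODS),
    ])
    def test_cheese_calcium_gate_is_strict(self, small_db, calcium, expected):
        rec = make_record(category_id="cheese",
                          nutrients=dict(total_fat_g=30, saturated_fat_g=20,
                                         calcium_mg=calcium))
        assert determine_category(rec, small_db.categories) is expected

    def test_cheese_without_calcium_is_an_error(self, small_db):
        rec = make_record(category_id="cheese")
        with pytest.raises(ValueError, match="calcium"):
            determine_category(rec, small_db.categories)

    def test_ordinary_food_is_category_2(self, small_db):
        assert determine_category(small_db.records["9300000000017"],
                                  small_db.categories) is NpscCategory.OTHER_FOODS


class TestBaselinePoints:
    def test_all_zero_panel_scores_zero(self):
        b = baseline_points(make_panel(), NpscCategory.OTHER_FOODS)
        assert (b.energy, b.saturated_fat, b.sugars, b.sodium) == (0, 0, 0, 0)
        assert b.total == 0

    def test_total_is_sum_of_components(self):
        panel = make_panel(energy_kj=1700, saturated_fat_g=21, carbohydrate_g=30,
                           sugars_g=22, sodium_mg=700, total_fat_g=33)
        b = baseline_points(panel, NpscCategory.OTHER_FOODS)
        assert b.total == b.energy + b.saturated_fat + b.sugars + b.sodium
        t = PointTables()
        assert b.energy == oracle_points(1700, t.energy.thresholds)
        assert b.saturated_fat == oracle_points(21, t.saturated_fat.thresholds)
        assert b.sugars == oracle_points(22, t.sugars.thresholds)
        assert b.sodium == oracle_points(700, t.sodium.thresholds)

    def test_extreme_saturated_fat_hits_cap(self):
        b = baseline_points(make_panel(total_fat_g=500, saturated_fat_g=500),
                            NpscCategory.OTHER_FOODS)
        assert b.saturated_fat == 30


class TestFvnlPercent:
    def test_pure_fvnl_is_100(self):
        assert fvnl_percent(FvnlComposition(100, 0, 0)) == 100.0

    def test_no_fvnl_is_0(self):
        assert fvnl_percent(FvnlComposition(0, 0, 100)) == 0.0

    def test_concentrated_components_double_weighted(self):
        # hand evaluation: 100*(40 + 2*10) / (40 + 2*10 + 50) = 6000/110
        assert fvnl_percent(FvnlComposition(40, 10, 50)) == pytest.approx(6000 / 110)

    def test_all_zero_composition_is_undefined(self):
        with pytest.raises(ValueError):
            fvnl_percent(FvnlComposition(0, 0, 0))


class TestModifyingPoints:
    def test_v_points_restricted_to_value_set(self):
        lookup = FvnlLookup()
        assert {lookup.points(p) for p in range(0, 101)} <= {0, 1, 2, 5, 8}
        assert lookup.points(100) == 8

    def test_zero_inputs_give_zero_points(self):
        v, p, f = modifying_points(make_panel(fiber_g=0.0), 0.0,
                                   NpscCategory.OTHER_FOODS)
        assert (v, p, f) == (0, 0, 0)

    def test_fiber_cap(self):
        _, _, f = modifying_points(make_panel(fiber_g=1000.0), 0.0,
                                   NpscCategory.OTHER_FOODS)
        assert f == 2

    def test_absent_fiber_contributes_nothing(self):
        _, _, f = modifying_points(make_panel(), 0.0, NpscCategory.OTHER_FOODS)
        assert f == 0

    def test_protein_cap_rule_disabled_by_default(self):
        panel = make_panel(protein_g=20, sodium_mg=3000)
        base = baseline_points(panel, NpscCategory.OTHER_FOODS)
        assert base.total > 13
        _, p, _ = modifying_points(panel, 0.0, NpscCategory.OTHER_FOODS,
                                   baseline_total=base.total)
        assert p == 5

    def test_protein_cap_rule_withholds_p_when_enabled(self):
        tables = PointTables(protein_cap_rule_enabled=True)
        panel = make_panel(protein_g=20, sodium_mg=3000)
        base = baseline_points(panel, NpscCategory.OTHER_FOODS, tables)
        _, p_low_v, _ = modifying_points(panel, 0.0, NpscCategory.OTHER_FOODS,
                                         tables, baseline_total=base.total)
        _, p_high_v, _ = modifying_points(panel, 100.0, NpscCategory.OTHER_FOODS,
                                          tables, baseline_total=base.total)
        assert p_low_v == 0 and p_high_v == 5


panel_strategy = st.builds(
    lambda e, sf, f_extra, c, s_frac, na, pr, fb: make_panel(
        energy_kj=e, saturated_fat_g=sf, total_fat_g=sf + f_extra,
        carbohydrate_g=c, sugars_g=c * s_frac, sodium_mg=na,
        protein_g=pr, fiber_g=fb),
    e=st.floats(0, 4000), sf=st.floats(0, 40), f_extra=st.floats(0, 40),
    c=st.floats(0, 90), s_frac=st.floats(0, 1), na=st.floats(0, 3000),
    pr=st.floats(0, 40), fb=st.floats(0, 20))


class TestScoreRecord:
    def test_all_zero_record_scores_zero(self, small_db):
        rec = make_record(category_id="bread", nutrients=dict(fiber_g=0.0))
        score = score_record(rec, small_db)
        assert score.final_score == 0

    def test_final_score_identity_on_hand_built_records(self, small_db):
        for rec in small_db.records.values():
            if rec.category_id == "cheese" and rec.panel.calcium_mg is None:
                continue  # needs imputation first
            s = score_record(rec, small_db)
            assert s.final_score == s.baseline.total - s.v_points - s.p_points - s.f_points

    def test_step4_arithmetic(self, small_db):
        # a record engineered to give baseline 12, V 2, P 1, F 1 -> final 8
        panel = make_panel(energy_kj=1100,                     # 3 energy points
                           saturated_fat_g=3.5, total_fat_g=4,  # 3
                           carbohydrate_g=40, sugars_g=10,      # 2
                           sodium_mg=380,                       # 4
                           protein_g=2.0,                       # P 1
                           fiber_g=1.0,                         # F 1
                           fvnl=FvnlComposition(65, 0, 35))     # 65% fvnl -> V 2
        rec = make_record(category_id="cereal", panel=panel)
        s = score_record(rec, small_db)
        assert s.baseline.total == 12
        assert (s.v_points, s.p_points, s.f_points) == (2, 1, 1)
        assert s.final_score == 8

    @settings(max_examples=100, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(panel=panel_strategy, extra_sodium=st.floats(1, 2000))
    def test_more_sodium_never_lowers_the_score(self, small_db, panel, extra_sodium):
        rec1 = make_record(category_id="bread", panel=panel)
        panel2 = replace(panel, sodium_mg=panel.sodium_mg + extra_sodium)
        rec2 = make_record(category_id="bread", panel=panel2)
        assert (score_record(rec2, small_db).final_score
                >= score_record(rec1, small_db).final_score)

    @settings(max_examples=100, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(panel=panel_strategy, extra_fiber=st.floats(1, 30))
    def test_more_fiber_never_raises_the_score(self, small_db, panel, extra_fiber):
        rec1 = make_record(category_id="bread", panel=panel)
        panel2 = replace(panel, fiber_g=(panel.fiber_g or 0) + extra_fiber)
        rec2 = make_record(category_id="bread", panel=panel2)
        assert (score_record(rec2, small_db).final_score
                <= score_record(rec1, small_db).final_score)

    def test_grid_equivalence_with_brute_force_recomputation(self, small_db):
        """On a coarse nutrient grid the composed scorer equals a from-scratch
        recomputation straight from the raw threshold lists."""
        t = PointTables()
        for energy in (0, 400, 1400, 3400):
            for satfat in (0, 2.5, 11):
                for sugars in (0, 5, 23):
                    for sodium in (0, 135, 950):
                        for protein in (0, 3.3, 9):
                            panel = make_panel(energy_kj=energy, saturated_fat_g=satfat,
                                               total_fat_g=satfat, carbohydrate_g=sugars,
                                               sugars_g=sugars, sodium_mg=sodium,
                                               protein_g=protein, fiber_g=1.0)
                            rec = make_record(category_id="bread", panel=panel)
                            expected = (oracle_points(energy, t.energy.thresholds)
                                        + oracle_points(satfat, t.saturated_fat.thresholds)
                                        + oracle_points(sugars, t.sugars.thresholds)
                                        + oracle_points(sodium, t.sodium.thresholds)
                                        - oracle_points(protein, t.protein.thresholds)
                                        - oracle_points(1.0, t.fiber.thresholds))
                            assert score_record(rec, small_db).final_score == expected

    def test_imputed_inputs_flow_into_score(self, small_db):
        scored = ScoredDatabase.prepare(small_db)
        assert "fiber_g" in scored.scores["9300000000024"].imputed_inputs
        assert scored.scores["9300000000017"].imputed_inputs == frozenset({"fvnl"})


class TestConfig:
    def test_point_tables_from_dict(self):
        d = {"energy": {"increment": 335, "cap": 10},
             "sodium": {"thresholds": [90, 180, 270]},
             "fvnl": {"steps": [[40, 1], [60, 2], [67, 5], [80, 8]]},
             "protein_cap_rule_enabled": True}
        t = point_tables_from_dict(d)
        assert t.energy == PointTables().energy
        assert t.sodium.cap == 3
        assert t.protein_cap_rule_enabled

    def test_v_values_outside_set_rejected(self):
        with pytest.raises(ValueError):
            FvnlLookup(((40.0, 3),))
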