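"""Benefit-transfer valuation and coefficient-of-sensitivity elasticity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lulcesv import (DEFAULT_LEGEND, CoefficientTable, build_esv_report,
                     build_sensitivity_table, coefficient_sensitivity,
                     esv_by_class, esv_by_function, esv_percent_change,
                     esv_total, implied_area, load_coefficients,
                     round_half_away, sensitivity_from_class_esv)
from lulcesv.legend import BARREN, BUILT_UP, CULTIVATED, FORESTLAND, GRASSLAND, WATER

# Published per-epoch class areas (ha) for the highland case-study landscape;
# cultivated-land areas for 1984/2021 are not published, so its published ESVs
# (US$ millions) are injected through implied areas where needed.
AREAS_1984 = pd.Series({FORESTLAND: 10706.4, GRASSLAND: 26319.6, WATER: 6806.7,
                        CULTIVATED: 0.0, BUILT_UP: 0.0, BARREN: 0.0})
AREAS_2021 = pd.Series({FORESTLAND: 5005.31, GRASSLAND: 15051.85, WATER: 914.89,
                        CULTIVATED: 0.0, BUILT_UP: 0.0, BARREN: 0.0})
CULTIVATED_ESV = {"1984": 7.4e6, "2021": 9.6e6}


@pytest.fixture(scope="module")
def coeffs() -> CoefficientTable:
    return load_coefficients()


class TestLoadCoefficients:
    def test_packaged_class_totals(self, coeffs):
        totals = coeffs.class_totals
        assert totals[FORESTLAND] == pytest.approx(986.69, abs=0.01)
        assert totals[CULTIVATED] == pytest.approx(225.56, abs=0.01)
        assert totals[GRASSLAND] == pytest.approx(293.25, abs=0.01)
        assert totals[WATER] == pytest.approx(8103.5, abs=0.01)
        assert totals[BUILT_UP] == 0.0 and totals[BARREN] == 0.0

    def test_water_hydrological_regulation_cell(self, coeffs):
        assert coeffs.vc.loc[WATER, "Hr"] == 5445
        assert coeffs.vc.loc[FORESTLAND, "Hr"] == 6
        assert coeffs.vc.loc[GRASSLAND, "Hr"] == 3

    def test_seventeen_functions(self, coeffs):
        assert len(coeffs.functions) == 17

    def test_total_row_mismatch_rejected(self, tmp_path, coeffs):
        path = tmp_path / "bad.csv"
        coeffs.to_csv(path)
        df = pd.read_csv(path)
        df.loc[df.function == "TOTAL", "forestland"] = 900.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="forestland"):
            load_coefficients(path)

    def test_all_zero_table_warns(self, tmp_path):
        rows = [{"function": f, "forestland": 0.0} for f in ("WS", "FP")]
        path = tmp_path / "zero.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.warns(UserWarning, match="zero"):
            table = load_coefficients(path)
        assert (table.class_totals == 0).all()

    def test_csv_round_trip(self, tmp_path, coeffs):
        path = tmp_path / "vc.csv"
        coeffs.to_csv(path)
        again = load_coefficients(path)
        pd.testing.assert_frame_equal(again.vc, coeffs.vc, check_like=True)


class TestEsv:
    def test_published_class_values_1984(self, coeffs):
        esv_m = esv_by_class(AREAS_1984, coeffs) / 1e6
        assert round_half_away(esv_m[FORESTLAND], 1) == 10.6
        assert round_half_away(esv_m[GRASSLAND], 1) == 7.7
        # published table prints 55.1; the printed area and coefficient give 55.16
        assert esv_m[WATER] == pytest.approx(55.1, abs=0.1)

    def test_published_class_values_2021(self, coeffs):
        esv_m = esv_by_class(AREAS_2021, coeffs) / 1e6
        assert round_half_away(esv_m[FORESTLAND], 1) == 4.9
        assert round_half_away(esv_m[GRASSLAND], 1) == 4.4
        assert round_half_away(esv_m[WATER], 1) == 7.4

    def test_zero_coefficient_class_contributes_nothing(self, coeffs):
        areas = pd.Series({BUILT_UP: 12345.0})
        assert esv_by_class(areas, coeffs)[BUILT_UP] == 0.0

    def test_published_function_values_1984(self, coeffs):
        esv_f = esv_by_function(AREAS_1984, coeffs) / 1e6
        assert round_half_away(esv_f["Hr"], 1) == 37.2
        assert round_half_away(esv_f["WS"], 1) == 14.5

    def test_function_value_2021_hydrological_regulation(self, coeffs):
        esv_f = esv_by_function(AREAS_2021, coeffs) / 1e6
        assert round_half_away(esv_f["Hr"], 1) == 5.1

    def test_unknown_class_raises(self, coeffs):
        with pytest.raises(KeyError):
            esv_by_class(pd.Series({99: 1.0}), coeffs)

    def test_single_cell_total(self):
        vc = pd.DataFrame({"WS": {1: 2.0}})
        table = CoefficientTable(vc, DEFAULT_LEGEND)
        assert esv_total(pd.Series({1: 10.0}), table) == pytest.approx(20.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_conservation_identity(self, seed):
        rng = np.random.default_rng(seed)
        vc = pd.DataFrame(rng.random((4, 5)) * 100, index=[1, 2, 3, 4],
                          columns=["f1", "f2", "f3", "f4", "f5"])
        table = CoefficientTable(vc, DEFAULT_LEGEND)
        areas = pd.Series(rng.random(4) * 1e4, index=[1, 2, 3, 4])
        by_class = esv_by_class(areas, table).sum()
        by_function = esv_by_function(areas, table).sum()
        total = esv_total(areas, table)
        assert by_class == pytest.approx(total, rel=1e-12)
        assert by_function == pytest.approx(total, rel=1e-12)

    def test_monotone_in_area(self, coeffs):
        base = esv_total(AREAS_1984, coeffs)
        bigger = AREAS_1984.copy()
        bigger[GRASSLAND] += 100.0
        assert esv_total(bigger, coeffs) >= base


class TestPercentChange:
    def test_published_water_change_with_rounding(self):
        assert round_half_away(esv_percent_change(55.1e6, 7.4e6, "paper"), 1) == -86.6
        # the unrounded computed 1984 value gives the same printed change
        assert round_half_away(esv_percent_change(55.158e6, 7.41e6, "paper"), 1) == -86.6

    def test_published_forest_change(self):
        assert round_half_away(esv_percent_change(10.6e6, 4.9e6, "paper"), 1) == -53.8

    def test_equal_values_zero(self):
        assert esv_percent_change(5.0, 5.0) == 0.0

    def test_zero_start_rejected(self):
        with pytest.raises(ValueError):
            esv_percent_change(0.0, 1.0)

    def test_raw_mode_uses_exact_values(self):
        assert esv_percent_change(200.0, 150.0, "raw") == pytest.approx(-25.0)


class TestSensitivity:
    def test_published_water_cs_1984(self, coeffs):
        areas = AREAS_1984.copy()
        areas[CULTIVATED] = implied_area(CULTIVATED_ESV["1984"], coeffs, CULTIVATED)
        row = coefficient_sensitivity(areas, coeffs, WATER, 0.5)
        assert round_half_away(row.cs, 2) == 0.68
        assert not row.elastic

    def test_published_water_cs_2021(self, coeffs):
        areas = AREAS_2021.copy()
        areas[CULTIVATED] = implied_area(CULTIVATED_ESV["2021"], coeffs, CULTIVATED)
        row = coefficient_sensitivity(areas, coeffs, WATER, 0.5)
        assert round_half_away(row.cs, 2) == 0.28

    def test_zero_coefficient_class_cs_is_zero(self, coeffs):
        row = coefficient_sensitivity(AREAS_1984, coeffs, BARREN, 0.5)
        assert row.cs == 0.0 and not row.elastic

    @pytest.mark.parametrize("p", [0.1, -0.1, 0.5, -0.5, 0.9, -0.9])
    def test_cs_identity_share_of_total(self, coeffs, p):
        # proportional row perturbation: CS_k = ESV_k / ESV_total exactly
        row = coefficient_sensitivity(AREAS_1984, coeffs, WATER, p)
        share = esv_by_class(AREAS_1984, coeffs)[WATER] / esv_total(AREAS_1984, coeffs)
        assert row.cs == pytest.approx(share, rel=1e-12)

    def test_cs_symmetric_in_perturbation_sign(self, coeffs):
        up = coefficient_sensitivity(AREAS_1984, coeffs, FORESTLAND, 0.5)
        dn = coefficient_sensitivity(AREAS_1984, coeffs, FORESTLAND, -0.5)
        assert up.cs == pytest.approx(dn.cs, rel=1e-12)

    def test_cs_sums_to_one_over_all_classes(self, coeffs):
        total = sum(coefficient_sensitivity(AREAS_1984, coeffs, k, 0.5).cs
                    for k in DEFAULT_LEGEND.codes)
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_all_case_study_classes_inelastic(self, coeffs):
        areas = AREAS_1984.copy()
        areas[CULTIVATED] = implied_area(CULTIVATED_ESV["1984"], coeffs, CULTIVATED)
        for k in DEFAULT_LEGEND.codes:
            assert coefficient_sensitivity(areas, coeffs, k, 0.5).cs < 1.0

    def test_from_class_esv_matches_area_route(self, coeffs):
        class_esv = esv_by_class(AREAS_1984, coeffs).to_dict()
        a = coefficient_sensitivity(AREAS_1984, coeffs, WATER, 0.5)
        b = sensitivity_from_class_esv(class_esv, WATER, 0.5)
        assert a.cs == pytest.approx(b.cs, rel=1e-12)

    def test_zero_baseline_rejected(self, coeffs):
        zero = pd.Series(0.0, index=DEFAULT_LEGEND.codes)
        with pytest.raises(ValueError, match="baseline"):
            coefficient_sensitivity(zero, coeffs, WATER, 0.5)


class TestReports:
    def test_report_conservation_and_shapes(self, coeffs):
        areas = pd.DataFrame({"1984": AREAS_1984, "2021": AREAS_2021})
        report = build_esv_report(areas, coeffs, rounding="paper")
        for ep in ("1984", "2021"):
            assert report.esv_class[ep].sum() == pytest.approx(report.totals[ep], rel=1e-12)
            assert report.esv_function[ep].sum() == pytest.approx(report.totals[ep], rel=1e-12)
        assert "1984-2021" in report.change_class_pct.columns

    def test_sensitivity_table_verdicts(self, coeffs):
        areas = pd.DataFrame({"1984": AREAS_1984})
        sens = build_sensitivity_table(areas, coeffs, 0.5)
        assert set(sens.verdict) == {"inelastic"}
        np.testing.assert_allclose(sens.cs, sens.cs_minus, rtol=1e-12)

    def test_implied_area_round_trip(self, coeffs):
        area = implied_area(7.4e6, coeffs, CULTIVATED)
        assert esv_by_class(pd.Series({CULTIVATED: area}), coeffs)[CULTIVATED] == pytest.approx(7.4e6)
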