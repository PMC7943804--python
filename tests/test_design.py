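"""Strata, lag matrices, spline basis, and design assembly."""

import numpy as np
import pandas as pd
import pytest

import stormlag as sl
from stormlag.design import DesignOptions
from stormlag.exposure import UNEXPOSED


class TestStrata:
    def test_same_calendar_day_across_years_shares_stratum(self):
        assert sl.assign_strata("37103", "2005-09-15") == sl.assign_strata(
            "37103", "1999-09-15"
        )

    def test_distinct_counties_distinct_strata(self):
        assert sl.assign_strata("37103", "2005-09-15") != sl.assign_strata(
            "37107", "2005-09-15"
        )

    def test_leap_day_forms_its_own_stratum(self):
        key = sl.assign_strata("37103", "2004-02-29")
        assert key == ("37103", 2, 29)
        assert key != sl.assign_strata("37103", "2004-02-28")
        assert key != sl.assign_strata("37103", "2004-03-01")


def _series(exposed_days, start="2000-01-01", n=30, county="01001"):
    dates = pd.date_range(start, periods=n, freq="D")
    flag = np.zeros(n)
    flag[list(exposed_days)] = 1.0
    return pd.DataFrame({"county_id": county, "date": dates, "exposed": flag})


class TestLagMatrix:
    def test_single_exposure_propagates_one_per_lag(self):
        lm = sl.build_lag_matrix(_series([10]))
        for l in range(8):
            col = lm[f"lag{l}"].to_numpy()
            assert col.sum() == 1.0
            assert col[10 + l] == 1.0

    def test_all_unexposed_gives_zero_matrix(self):
        lm = sl.build_lag_matrix(_series([]))
        assert lm.filter(like="lag").to_numpy().sum() == 0.0

    def test_overlapping_exposures_set_multiple_columns(self):
        lm = sl.build_lag_matrix(_series([10, 13]))
        row = lm.iloc[13]
        assert row["lag0"] == 1.0 and row["lag3"] == 1.0

    def test_shift_identity_against_brute_force(self):
        rng = np.random.default_rng(4)
        days = np.flatnonzero(rng.random(60) < 0.2)
        df = _series(days, n=60)
        lm = sl.build_lag_matrix(df)
        flag = df["exposed"].to_numpy()
        for l in range(8):
            expected = np.concatenate([np.zeros(l), flag[: 60 - l]])
            np.testing.assert_array_equal(lm[f"lag{l}"].to_numpy(), expected)

    def test_edge_lags_before_grid_are_unexposed(self):
        lm = sl.build_lag_matrix(_series([0]))
        assert lm.iloc[0]["lag0"] == 1.0
        assert all(lm.iloc[0][f"lag{l}"] == 0.0 for l in range(1, 8))

    def test_noncontiguous_grid_rejected(self):
        df = _series([5]).drop(index=10)
        with pytest.raises(ValueError, match="contiguous"):
            sl.build_lag_matrix(df)


class TestNaturalSpline:
    def test_df2_on_years_gives_two_columns(self):
        years = np.arange(1999, 2015, dtype=float)
        basis, knots = sl.natural_spline_basis(years, df=2)
        assert basis.shape == (16, 2)
        np.testing.assert_allclose(knots, [1999.0, 2006.5, 2014.0])

    def test_linear_beyond_boundary_knots(self):
        """Second differences vanish outside the boundary knots."""
        x = np.linspace(1990, 2025, 701)
        basis, knots = sl.natural_spline_basis(
            x, df=2, knots=np.array([1999.0, 2006.5, 2014.0])
        )
        h = x[1] - x[0]
        for j in range(basis.shape[1]):
            col = basis[:, j]
            second = (col[2:] - 2 * col[1:-1] + col[:-2]) / h**2
            outside = (x[1:-1] < 1999.0 - h) | (x[1:-1] > 2014.0 + h)
            assert np.abs(second[outside]).max() < 1e-6

    def test_basis_is_piecewise_cubic_with_continuous_curvature(self):
        """Independent characterization: each column restricted to a knot
        interval is exactly cubic, and curvature is continuous at the
        internal knot."""
        knots = np.array([0.0, 3.0, 10.0])
        x = np.linspace(0.0, 10.0, 1001)
        basis, _ = sl.natural_spline_basis(x, df=2, knots=knots)
        for j in range(2):
            col = basis[:, j]
            for lo, hi in [(0.0, 3.0), (3.0, 10.0)]:
                m = (x >= lo) & (x <= hi)
                coef = np.polyfit(x[m], col[m], 3)
                np.testing.assert_allclose(np.polyval(coef, x[m]), col[m], atol=1e-8)
            # curvature continuity at the internal knot
            left = np.polyder(np.polyfit(x[(x >= 0) & (x <= 3)], col[(x >= 0) & (x <= 3)], 3), 2)
            right = np.polyder(np.polyfit(x[(x >= 3) & (x <= 10)], col[(x >= 3) & (x <= 10)], 3), 2)
            assert np.polyval(left, 3.0) == pytest.approx(np.polyval(right, 3.0), abs=1e-6)

    def test_reproducible_given_knots(self):
        x = np.linspace(0, 1, 50)
        b1, k = sl.natural_spline_basis(x, df=2)
        b2, _ = sl.natural_spline_basis(x, df=2, knots=k)
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            sl.natural_spline_basis(np.array([1.0, 1.0, 2.0]), df=2)


class TestBuildDesign:
    def test_binary_lag0_temperature_column_count(self, small_panel, small_exposure):
        panel, _ = small_panel
        design = sl.build_design(panel, small_exposure)
        # 8 lags + 1 temperature + 6 DOW + 2 spline
        assert design.X.shape[1] == 17
        assert len(design.columns) == 17

    def test_three_category_has_two_lag_blocks(self, small_panel, small_exposure):
        panel, _ = small_panel
        design = sl.build_design(
            panel, small_exposure, DesignOptions(exposure_mode="three_category")
        )
        gale = [c for c in design.columns if c.startswith("gale_lag")]
        hurr = [c for c in design.columns if c.startswith("hurricane_lag")]
        assert len(gale) == 8 and len(hurr) == 8
        assert design.X.shape[1] == 8 + 8 + 1 + 6 + 2

    @pytest.mark.parametrize(
        "temperature_mode, n_cols", [("lags0_7", 24), ("none", 16)]
    )
    def test_temperature_mode_column_count(
        self, small_panel, small_exposure, temperature_mode, n_cols
    ):
        panel, _ = small_panel
        design = sl.build_design(
            panel, small_exposure, DesignOptions(temperature_mode=temperature_mode)
        )
        assert design.X.shape[1] == n_cols

    def test_zero_count_strata_dropped_others_untouched(self, small_panel, small_exposure):
        panel, _ = small_panel
        design = sl.build_design(panel, small_exposure)
        sums = np.bincount(design.stratum, weights=design.y)
        assert (sums > 0).all()
        # force one county-calendar-day stratum to zero and rebuild
        county = panel["county_id"].iloc[0]
        target = (
            (panel["county_id"] == county)
            & (panel["date"].dt.month == 7)
            & (panel["date"].dt.day == 4)
        )
        zeroed = panel.copy()
        zeroed.loc[target, "count"] = 0
        d2 = sl.build_design(zeroed, small_exposure)
        dd = pd.to_datetime(d2.rows["date"])
        assert not (
            (d2.rows["county_id"] == county) & (dd.dt.month == 7) & (dd.dt.day == 4)
        ).any()
        assert d2.n_strata_dropped >= design.n_strata_dropped + 1

    def test_row_order_invariance(self, small_panel, small_exposure):
        panel, _ = small_panel
        shuffled = panel.sample(frac=1, random_state=0)
        d1 = sl.build_design(panel, small_exposure)
        d2 = sl.build_design(shuffled, small_exposure)
        np.testing.assert_array_equal(d1.y, d2.y)
        np.testing.assert_allclose(d1.X, d2.X)
        np.testing.assert_array_equal(d1.stratum, d2.stratum)

    def test_lag_columns_satisfy_shift_identity(self, small_panel, small_exposure):
        panel, _ = small_panel
        design = sl.build_design(panel, small_exposure)
        # reconstruct within one county from the exposure panel directly
        frame = design.frame()
        rows = design.rows
        county = rows["county_id"].iloc[0]
        m = (rows["county_id"] == county).to_numpy()
        sub = frame[m].reset_index(drop=True)
        dates = pd.to_datetime(rows.loc[m, "date"]).reset_index(drop=True)
        exp_map = small_exposure[small_exposure["county_id"] == county].set_index(
            "date"
        )["binary_exposed"]
        for i in range(len(sub)):
            for l in (0, 3, 7):
                antecedent = dates[i] - pd.Timedelta(days=l)
                expect = float(exp_map.get(antecedent, 0.0))
                assert sub.loc[i, f"exposure_lag{l}"] == expect

    def test_misaligned_exposure_raises(self, small_panel, small_exposure):
        panel, _ = small_panel
        with pytest.raises(ValueError, match="missing from exposure"):
            sl.build_design(panel, small_exposure.iloc[: len(small_exposure) // 2])

    def test_design_csv_roundtrip(self, tmp_path, small_panel, small_exposure):
        panel, _ = small_panel
        design = sl.build_design(panel, small_exposure)
        design.to_csv(tmp_path / "design.csv", tmp_path / "columns.txt")
        back = pd.read_csv(tmp_path / "design.csv")
        assert len(back) == len(design.y)
        registry = (tmp_path / "columns.txt").read_text().split()
        assert registry == design.columns
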