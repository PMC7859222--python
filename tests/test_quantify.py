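"""Quantification and statistics: closed-form oracles and calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircoloc import (cohens_d, copies_per_cell, delta_delta_ct, dunnett,
                      excess_ratio, linear_fit_ci, standard_curve_quantify,
                      steel_dwass, welch_t)


class TestCopiesPerCell:
    def test_hand_evaluated_closed_form(self):
        # 1e-6 mol/L * 6.022e23 /mol * 1e-15 L = ~602 copies
        est = copies_per_cell(1e-6, 1.0)
        assert est.copies_per_cell == pytest.approx(602.214076, rel=1e-9)

    def test_zero_concentration_gives_zero(self):
        assert copies_per_cell(0.0, 2.6e3).copies_per_cell == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            copies_per_cell(-1.0, 1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(c=st.floats(1e-12, 1e-3), v=st.floats(1.0, 1e5), k=st.floats(0.1, 10.0))
    def test_linear_in_each_argument(self, c, v, k):
        base = copies_per_cell(c, v).copies_per_cell
        assert copies_per_cell(k * c, v).copies_per_cell == pytest.approx(k * base)
        assert copies_per_cell(c, k * v).copies_per_cell == pytest.approx(k * base)


class TestExcessRatio:
    def test_identity_and_zero(self):
        assert excess_ratio(5.0, 5.0) == 1.0
        assert excess_ratio(0.0, 1e5) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            excess_ratio(1.0, 0.0)


def _ct_table(control_dct, treated_dct, ref=10.0):
    rows = []
    for i, d in enumerate(control_dct):
        rows.append(dict(sample_id=f"c{i}", group="normal", compartment="EV",
                         target="miR-122", ct_target=ref + d, ct_reference=ref))
    for i, d in enumerate(treated_dct):
        rows.append(dict(sample_id=f"t{i}", group="anti-Ago", compartment="EV",
                         target="miR-122", ct_target=ref + d, ct_reference=ref))
    return pd.DataFrame(rows)


class TestDeltaDeltaCt:
    def test_hand_computed_three_plus_three_table(self):
        """Treated dCt shifted by +2 over control -> mean log2 FC is -2,
        control mean is 0, and nothing is flagged."""
        res = delta_delta_ct(_ct_table([0.9, 1.0, 1.1], [2.9, 3.0, 3.1]),
                             control_group="normal")
        ctrl = res.per_sample[res.per_sample.group == "normal"]
        trt = res.per_sample[res.per_sample.group == "anti-Ago"]
        assert ctrl.log2_fc.mean() == pytest.approx(0.0)
        assert trt.log2_fc.mean() == pytest.approx(-2.0)
        assert not res.per_sample.outlier.any()
        grp = res.group_summary.set_index("group")
        assert grp.loc["anti-Ago", "mean_log2_fc"] == pytest.approx(-2.0)

    def test_one_cycle_drop_raises_log2fc_by_one(self):
        base = _ct_table([1.0, 1.0], [2.0, 2.0])
        shifted = base.copy()
        shifted.loc[shifted.sample_id == "t0", "ct_target"] -= 1.0
        r0 = delta_delta_ct(base, "normal").per_sample.set_index("sample_id")
        r1 = delta_delta_ct(shifted, "normal").per_sample.set_index("sample_id")
        assert (r1.loc["t0", "log2_fc"] - r0.loc["t0", "log2_fc"]
                ) == pytest.approx(1.0)

    def test_reference_shift_invariance(self):
        """Adding a constant to every reference Ct leaves log2 FC unchanged."""
        t = _ct_table([0.9, 1.0, 1.1], [2.9, 3.0, 3.1])
        t2 = t.copy()
        t2["ct_reference"] += 3.7
        t2["ct_target"] += 3.7  # keep dCt interpretable; shift both
        r1 = delta_delta_ct(t, "normal").per_sample.log2_fc
        r2 = delta_delta_ct(t2, "normal").per_sample.log2_fc
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_planted_outlier_is_flagged_and_clean_samples_are_not(self):
        """A sample 5 clean-SDs off its group is excluded; nothing else is."""
        clean = [2.9, 3.0, 2.95]  # treated log2fc {-1.9, -2.0, -1.95}, sd 0.05
        planted = [2.9 - 0.25, 3.0, 2.95]  # 5 x 0.05 shift on the top sample
        res = delta_delta_ct(_ct_table([0.9, 1.0, 1.1], planted), "normal")
        flagged = res.per_sample[res.per_sample.outlier]
        assert list(flagged.sample_id) == ["t0"]
        grp = res.group_summary.set_index("group")
        assert grp.loc["anti-Ago", "n"] == 2
        assert grp.loc["anti-Ago", "outlier_sample_ids"] == "t0"
        res_clean = delta_delta_ct(_ct_table([0.9, 1.0, 1.1], clean), "normal")
        assert not res_clean.per_sample.outlier.any()

    def test_missing_reference_names_samples(self):
        t = _ct_table([1.0, 1.0], [2.0, 2.0])
        t.loc[t.sample_id == "c1", "ct_reference"] = np.nan
        with pytest.raises(ValueError, match="c1"):
            delta_delta_ct(t, "normal")

    def test_missing_control_stratum_rejected(self):
        t = _ct_table([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            delta_delta_ct(t, "no-such-group")


class TestStandardCurve:
    def test_two_point_interpolation_identity(self):
        res = standard_curve_quantify([(1.0, 30.0), (10.0, 26.0)], [30.0, 26.0])
        np.testing.assert_allclose(res.amounts, [1.0, 10.0])

    def test_perfect_doubling_slope_gives_100_percent_efficiency(self):
        m = -1.0 / math.log10(2.0)  # -3.3219...
        standards = [(10.0 ** k, 40.0 + m * k) for k in range(1, 5)]
        res = standard_curve_quantify(standards, [])
        assert res.efficiency == pytest.approx(1.0, abs=1e-3)

    def test_midway_ct_gives_geometric_mean_amount(self):
        res = standard_curve_quantify([(1.0, 30.0), (100.0, 24.0)], [27.0])
        assert res.amounts[0] == pytest.approx(10.0)  # sqrt(1*100)

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            standard_curve_quantify([(1.0, 30.0), (1.0, 29.0)], [28.0])


class TestWelchAndCohen:
    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)
        assert cohens_d(x, [v + 0.0 for v in x]) == 0.0

    def test_matches_closed_form_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        # Welch formulas evaluated from first principles
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 4
        t_hand = (x.mean() - y.mean()) / math.sqrt(se2)
        df_hand = se2 ** 2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        from scipy import stats as sps
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand))

    def test_cohens_d_pooled_by_df(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        pooled = math.sqrt((2 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 5)
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled)

    def test_one_pooled_sd_shift_gives_d_of_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = x.std(ddof=1)
        assert cohens_d(x + s, x) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    def test_affine_invariance_of_t_and_d(self, shift, scale):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=9)
        t0, df0, p0 = welch_t(x, y)
        t1, df1, p1 = welch_t(scale * x + shift, scale * y + shift)
        assert t1 == pytest.approx(t0, rel=1e-9)
        assert df1 == pytest.approx(df0, rel=1e-9)
        assert cohens_d(scale * x + shift, scale * y + shift) == pytest.approx(
            cohens_d(x, y), rel=1e-9)


class TestDunnett:
    def test_identical_groups_give_identical_p(self):
        g = {"ctrl": [1.0, 2.0, 3.0, 4.0], "a": [2.0, 3.0, 4.0, 5.0],
             "b": [2.0, 3.0, 4.0, 5.0]}
        df = dunnett(g, "ctrl", seed=0)
        p = df.set_index("comparison").p_adjusted
        # the multivariate-t quantile integration carries ~1e-4 noise
        assert p["a vs ctrl"] == pytest.approx(p["b vs ctrl"], abs=1e-3)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(1)
        g = {"ctrl": rng.normal(size=10), "same": rng.normal(size=10),
             "shifted": rng.normal(loc=5.0, size=10)}
        df = dunnett(g, "ctrl", seed=0).set_index("comparison")
        assert df.loc["shifted vs ctrl", "p_adjusted"] < 0.01

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            dunnett({"a": [1, 2, 3]}, "ctrl")


class TestSteelDwass:
    def test_label_permutation_preserves_p_set(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(size=8) for k in "abc"}
        p1 = sorted(steel_dwass(g).p_adjusted)
        p2 = sorted(steel_dwass({k: g[k] for k in "cab"}).p_adjusted)
        np.testing.assert_allclose(p1, p2)

    def test_dominant_group_is_detected(self):
        rng = np.random.default_rng(3)
        g = {"a": rng.normal(size=12), "b": rng.normal(size=12),
             "c": rng.normal(loc=6.0, size=12)}
        df = steel_dwass(g)
        pair = df[(df.group_a == "a") & (df.group_b == "c")]
        assert float(pair.p_adjusted.iloc[0]) < 0.01

    def test_ties_proceed_with_midranks(self):
        g = {"a": [1.0, 1.0, 2.0, 2.0], "b": [1.0, 2.0, 2.0, 2.0]}
        df = steel_dwass(g)
        assert ((df.p_adjusted >= 0) & (df.p_adjusted <= 1)).all()


class TestLinearFit:
    def test_exact_line_recovered_with_zero_width_band(self):
        x = np.arange(10.0)
        fit = linear_fit_ci(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        lo, hi = fit.confidence_band(x)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-8)

    def test_band_narrowest_at_mean_x(self, rng):
        x = np.linspace(0, 1, 30)
        y = 3 * x + rng.normal(scale=0.3, size=30)
        fit = linear_fit_ci(x, y)
        grid = np.linspace(0, 1, 101)
        lo, hi = fit.confidence_band(grid)
        widths = hi - lo
        assert abs(grid[np.argmin(widths)] - x.mean()) < 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_ci(np.ones(5), np.arange(5.0))
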