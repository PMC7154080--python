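"""t-maps, BH-FDR, mixed repeated-measures ANOVA, correlation grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plimse.stats import (
    bh_fdr,
    corr_grid,
    linear_fit,
    posthoc_map,
    rm_anova_mixed,
    ttest_independent,
)


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = ttest_independent(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_toy_matches_pooled_variance_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = ttest_independent(a, b)
        # textbook pooled-variance computation
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 4))

    def test_negation_flips_sign_only(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 1
        t1, p1 = ttest_independent(a, b)
        t2, p2 = ttest_independent(-a, -b)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent(np.ones(5), np.ones(5) * 2)

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.standard_normal(8)
        b = 5.0 * rng.standard_normal(30)
        assert ttest_independent(a, b)[1] != ttest_independent(a, b, welch=True)[1]


from conftest import bh_stepup_oracle as bh_oracle


class TestBHFDR:
    def test_single_p_reduces_to_direct_comparison(self):
        mask, thr = bh_fdr(np.array([0.03]), 0.05)
        assert mask[0] and thr == 0.03

    def test_all_ones_rejects_nothing(self):
        mask, thr = bh_fdr(np.ones(10), 0.05)
        assert not mask.any() and thr == 0.0

    def test_600_uniform_pvalues_match_stepup_oracle(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=600)  # 120 pairs x 5 bands worth of tests
        p[:30] = rng.uniform(0, 1e-3, 30)  # some true effects
        mask, thr = bh_fdr(p, 0.05)
        np.testing.assert_array_equal(mask, bh_oracle(p, 0.05))
        assert thr == p[mask].max()

    def test_mask_monotone_in_q(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200) ** 2
        m05, _ = bh_fdr(p, 0.05)
        m01, _ = bh_fdr(p, 0.01)
        assert np.all(~m01 | m05)  # q=0.01 mask is a subset of q=0.05 mask

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]), 0.05)
        with pytest.raises(ValueError):
            bh_fdr(np.array([]), 0.05)


def make_mixed_data(rng, n_groups=(8, 8), j1=4, j2=None, effect=0.0):
    rows = []
    for gi, (g, n) in enumerate(zip("AB", n_groups)):
        for s in range(n):
            sid = f"{g}{s}"
            base = rng.normal()
            for l1 in range(j1):
                for l2 in range(j2 or 1):
                    y = base + rng.normal() + effect * gi * l1
                    row = {"subject": sid, "group": g, "w1": f"a{l1}", "y": y}
                    if j2:
                        row["w2"] = f"b{l2}"
                    rows.append(row)
    return pd.DataFrame(rows)


def gg_epsilon_oracle(cov):
    """Classical double-centering formula for the Box epsilon."""
    j = cov.shape[0]
    mean_diag = np.trace(cov) / j
    grand = cov.mean()
    row = cov.mean(axis=1)
    num = j ** 2 * (mean_diag - grand) ** 2
    den = (j - 1) * ((cov ** 2).sum() - 2 * j * (row ** 2).sum() + j ** 2 * grand ** 2)
    return num / den


class TestMixedAnova:
    def test_two_level_within_factor_has_unit_epsilon(self, rng):
        df = make_mixed_data(rng, j1=2)
        res = rm_anova_mixed(df, "y", "subject", "group", ["w1"])
        row = res.effect("w1")
        assert row["eps"] == 1.0
        assert row["p_gg"] == pytest.approx(row["p_unc"])

    def test_matches_reference_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        for sizes in [(8, 8), (9, 7)]:
            df = make_mixed_data(rng, n_groups=sizes, j1=4, effect=0.4)
            res = rm_anova_mixed(df, "y", "subject", "group", ["w1"])
            ref = pg.mixed_anova(data=df, dv="y", within="w1", subject="subject",
                                 between="group")
            for mine, theirs in [("group", "group"), ("w1", "w1"),
                                 ("group x w1", "Interaction")]:
                row = res.effect(mine)
                ref_row = ref[ref["Source"] == theirs].iloc[0]
                assert row["ss"] == pytest.approx(ref_row["SS"])
                assert row["F"] == pytest.approx(ref_row["F"])
                assert row["p_unc"] == pytest.approx(ref_row["p_unc"])

    def test_epsilon_matches_double_centering_formula(self, rng):
        df = make_mixed_data(rng, j1=5)
        res = rm_anova_mixed(df, "y", "subject", "group", ["w1"])
        wide = df.pivot_table(index=["subject", "group"], columns="w1", values="y")
        groups = wide.index.get_level_values("group").to_numpy()
        pooled = np.zeros((5, 5))
        dof = 0
        for g in "AB":
            z = wide.to_numpy()[groups == g]
            z = z - z.mean(axis=0)
            pooled += z.T @ z
            dof += z.shape[0] - 1
        pooled /= dof
        assert res.effect("w1")["eps"] == pytest.approx(gg_epsilon_oracle(pooled))

    def test_sums_of_squares_decomposition_is_exact(self, rng):
        for j2 in (None, 3):
            df = make_mixed_data(rng, n_groups=(9, 7), j1=4, j2=j2, effect=0.3)
            within = ["w1"] if j2 is None else ["w1", "w2"]
            res = rm_anova_mixed(df, "y", "subject", "group", within)
            assert res.ss_decomposed == pytest.approx(res.ss_total)

    def test_two_within_factor_design_reports_all_effects(self, rng):
        df = make_mixed_data(rng, j1=3, j2=4)
        res = rm_anova_mixed(df, "y", "subject", "group", ["w1", "w2"])
        effects = set(res.table["effect"])
        assert effects == {"group", "w1", "group x w1", "w2", "group x w2",
                           "w1 x w2", "group x w1 x w2"}
        assert np.all((res.table["eps"] > 0) & (res.table["eps"] <= 1))

    def test_injected_within_effect_is_detected(self, rng):
        df = make_mixed_data(rng, j1=4, effect=1.0)
        res = rm_anova_mixed(df, "y", "subject", "group", ["w1"])
        assert res.effect("group x w1")["p_gg"] < 0.05

    def test_missing_cell_rejected(self, rng):
        df = make_mixed_data(rng, j1=3)
        with pytest.raises(ValueError):
            rm_anova_mixed(df.iloc[1:], "y", "subject", "group", ["w1"])


class TestPostHocMap:
    @pytest.mark.parametrize("shape,n_tests", [
        ((16, 5), 80),     # electrodes x bands (node degree)
        ((16, 20), 320),   # electrodes x scales (SampEn)
        ((120, 5), 600),   # electrode pairs x bands (PLI)
    ])
    def test_grid_sizes_match_layouts(self, rng, shape, n_tests):
        values = rng.standard_normal((12,) + shape)
        groups = np.array(["HC"] * 6 + ["AD"] * 6)
        layout = {"row": list(range(shape[0])), "col": list(range(shape[1]))}
        grid = posthoc_map(values, groups, layout)
        assert grid.n_tests == n_tests
        assert grid.statistic.shape == shape
        assert set(grid.masks) == {0.05, 0.01}

    def test_undefined_cells_are_flagged_not_fatal(self, rng):
        values = rng.standard_normal((8, 3, 2))
        values[:, 0, 0] = np.nan
        groups = np.array(["HC"] * 4 + ["AD"] * 4)
        grid = posthoc_map(values, groups,
                           {"row": [0, 1, 2], "col": [0, 1]})
        assert grid.n_excluded == 1
        assert np.isnan(grid.p[0, 0])
        assert not grid.masks[0.05][0, 0]

    def test_reduced_group_yields_negative_t(self, rng):
        values = rng.standard_normal((20, 2, 2))
        values[10:] -= 3.0  # AD rows listed second
        groups = np.array(["HC"] * 10 + ["AD"] * 10)
        grid = posthoc_map(values, groups, {"row": [0, 1], "col": [0, 1]})
        assert np.all(grid.statistic < 0)  # t = mean(AD) - mean(HC)


class TestCorrGrid:
    def test_full_grid_has_1600_cells(self, rng):
        sampen = rng.standard_normal((10, 16, 20))
        nd = rng.standard_normal((10, 5, 16))
        grid = corr_grid(sampen, nd, list(range(16)), list(range(5)),
                         list(range(20)))
        assert grid.statistic.shape == (16, 5, 20)
        assert grid.n_tests == 1600

    def test_perfectly_linear_pair_gives_r1(self, rng):
        nd = rng.standard_normal((8, 1, 1))
        sampen = 2.0 * nd.transpose(0, 2, 1) + 1.0
        grid = corr_grid(sampen, nd, [0], [0], [0])
        assert grid.statistic[0, 0, 0] == pytest.approx(1.0)

    def test_matches_definitional_covariance_oracle(self, rng):
        sampen = rng.standard_normal((9, 2, 3))
        nd = rng.standard_normal((9, 2, 2))
        grid = corr_grid(sampen, nd, [0, 1], [0, 1], [0, 1, 2])
        for e in range(2):
            for b in range(2):
                for s in range(3):
                    x, y = sampen[:, e, s], nd[:, b, e]
                    r = (((x - x.mean()) * (y - y.mean())).sum()
                         / np.sqrt(((x - x.mean()) ** 2).sum()
                                   * ((y - y.mean()) ** 2).sum()))
                    assert grid.statistic[e, b, s] == pytest.approx(r)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            corr_grid(rng.standard_normal((2, 1, 1)),
                      rng.standard_normal((2, 1, 1)), [0], [0], [0])


class TestLinearFit:
    def test_two_points(self):
        slope, intercept, r = linear_fit(np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        assert (slope, intercept, r) == (2.0, 0.0, 1.0)

    def test_slope_converges_with_vanishing_noise(self, rng):
        x = rng.uniform(size=200)
        y = 3.0 * x + 1e-9 * rng.standard_normal(200)
        slope, _, _ = linear_fit(x, y)
        assert slope == pytest.approx(3.0, abs=1e-6)

    def test_slope_equals_r_times_sd_ratio(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        slope, _, r = linear_fit(x, y)
        assert slope == pytest.approx(r * np.std(y) / np.std(x))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit(np.ones(5), np.arange(5.0))
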