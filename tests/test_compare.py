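import numpy as np
import pytest
from scipy import stats

import octogrowth as og

from conftest import gompertz_data


class TestArssCompare:
    def test_duplicated_group_gives_f_zero_p_one(self, gompertz_all):
        ages, m = gompertz_data(gompertz_all, 60, 0.15, seed=31)
        res = og.arss_compare({"a": (ages, m), "b": (ages, m)}, weighting="data_sq")
        assert res.rss_separate == pytest.approx(res.rss_pooled, rel=1e-8)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.999

    def test_linear_model_equals_chow_test(self, rng):
        # closed-form Chow oracle on a small instance
        n1, n2 = 30, 25
        x1 = rng.uniform(1.0, 100.0, n1)
        y1 = 5.0 + 0.5 * x1 + rng.normal(0.0, 1.0, n1)
        x2 = rng.uniform(1.0, 100.0, n2)
        y2 = 9.0 + 0.3 * x2 + rng.normal(0.0, 1.0, n2)

        def rss(x, y):
            X = np.column_stack([np.ones_like(x), x])
            r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return float(r @ r)

        rss_p = rss(np.concatenate([x1, x2]), np.concatenate([y1, y2]))
        rss_s = rss(x1, y1) + rss(x2, y2)
        k, N = 2, n1 + n2
        f_chow = ((rss_p - rss_s) / k) / (rss_s / (N - 2 * k))

        res = og.arss_compare(
            {"g1": (x1, y1), "g2": (x2, y2)}, model="linear", weighting="none"
        )
        assert res.f_statistic == pytest.approx(f_chow, abs=1e-10, rel=1e-10)
        assert res.df_num == k and res.df_den == N - 2 * k
        assert res.p_value == pytest.approx(float(stats.f.sf(f_chow, k, N - 2 * k)))

    def test_group_relabeling_invariance(self, gompertz_all):
        a1, m1 = gompertz_data(gompertz_all, 60, 0.15, seed=41)
        a2, m2 = gompertz_data(gompertz_all, 70, 0.15, seed=42)
        r1 = og.arss_compare({"x": (a1, m1), "y": (a2, m2)})
        r2 = og.arss_compare({"warm": (a2, m2), "cool": (a1, m1)})
        assert r1.f_statistic == pytest.approx(r2.f_statistic, rel=1e-10)

    def test_separate_rss_never_exceeds_pooled(self, gompertz_all):
        for seed in range(5):
            a1, m1 = gompertz_data(gompertz_all, 50, 0.2, seed=seed)
            a2, m2 = gompertz_data(gompertz_all, 55, 0.2, seed=seed + 100)
            res = og.arss_compare({"a": (a1, m1), "b": (a2, m2)})
            assert res.rss_separate <= res.rss_pooled * (1 + 1e-12)

    def test_detects_genuinely_different_curves(self, gompertz_all):
        slow = og.GrowthParams(model="gompertz", m_inf=171.55, gamma=9.81, g1=0.010)
        fast = og.GrowthParams(model="gompertz", m_inf=171.55, gamma=9.81, g1=0.020)
        a1, m1 = gompertz_data(slow, 100, 0.15, seed=51)
        a2, m2 = gompertz_data(fast, 100, 0.15, seed=52)
        res = og.arss_compare({"slow": (a1, m1), "fast": (a2, m2)})
        assert res.p_value < 1e-6

    def test_alt_df_convention_logged(self, gompertz_all):
        a1, m1 = gompertz_data(gompertz_all, 60, 0.15, seed=61)
        a2, m2 = gompertz_data(gompertz_all, 60, 0.15, seed=62)
        res = og.arss_compare({"a": (a1, m1), "b": (a2, m2)})
        assert res.df_den_alt == 120 - 3  # pooled-residual convention N - k
        assert 0.0 <= res.p_value_alt <= 1.0

    def test_single_group_rejected(self, gompertz_all):
        a, m = gompertz_data(gompertz_all, 50, 0.15, seed=71)
        with pytest.raises(ValueError):
            og.arss_compare({"only": (a, m)})


class TestBoxCox:
    def test_lognormal_sample_pulls_lambda_to_zero(self, rng):
        y = np.exp(rng.normal(2.0, 0.6, 500))
        _, lam = og.boxcox_transform(y)
        assert -0.15 <= lam <= 0.15

    def test_normal_sample_keeps_lambda_near_one(self, rng):
        y = rng.normal(50.0, 4.0, 500)
        _, lam = og.boxcox_transform(y)
        assert abs(lam - 1.0) <= 0.5

    def test_zero_value_rejected(self):
        with pytest.raises(ValueError):
            og.boxcox_transform([1.0, 0.0, 2.0])

    def test_transform_formula(self):
        y = np.array([1.0, 2.0, 4.0])
        z, lam = og.boxcox_transform(y)
        if lam == 0.0:
            assert np.allclose(z, np.log(y))
        else:
            assert np.allclose(z, (y**lam - 1.0) / lam)


class TestNormalizeResponse:
    def test_normal_data_untouched(self, rng):
        y = rng.normal(20.0, 2.0, 200)
        out, lam, p = og.compare.normalize_response(y)
        assert lam is None and p >= 0.05
        assert np.array_equal(out, y)

    def test_skewed_data_transformed(self, rng):
        y = np.exp(rng.normal(2.0, 0.8, 300))
        out, lam, p = og.compare.normalize_response(y)
        assert p < 0.05 and lam is not None
        assert -0.3 <= lam <= 0.3  # lognormal pulls lambda towards 0


class TestTwoWayAnova:
    def test_constant_response_guarded(self):
        y = [5.0] * 8
        a = ["w", "w", "c", "c"] * 2
        b = ["f", "m"] * 4
        table = og.two_way_anova(y, a, b, names=("season", "sex"))
        for term in ("season", "sex"):
            assert table.table.loc[term, "F"] == 0.0
            assert table.table.loc[term, "PR(>F)"] == 1.0

    def test_balanced_design_matches_hand_decomposition(self, rng):
        # 2x2 balanced, r=5: classical mean-decomposition sums of squares
        levels_a, levels_b, r = ["w", "c"], ["f", "m"], 5
        rows = []
        means = {("w", "f"): 10.0, ("w", "m"): 12.0, ("c", "f"): 9.0, ("c", "m"): 15.0}
        for la in levels_a:
            for lb in levels_b:
                for _ in range(r):
                    rows.append((la, lb, means[(la, lb)] + rng.normal(0, 1.0)))
        a = [x[0] for x in rows]
        b = [x[1] for x in rows]
        y = np.array([x[2] for x in rows])
        table = og.two_way_anova(y, a, b, names=("A", "B")).table

        ybar = y.mean()
        abar = {la: y[[x[0] == la for x in rows]].mean() for la in levels_a}
        bbar = {lb: y[[x[1] == lb for x in rows]].mean() for lb in levels_b}
        cbar = {
            (la, lb): y[[(x[0], x[1]) == (la, lb) for x in rows]].mean()
            for la in levels_a
            for lb in levels_b
        }
        ss_a = r * len(levels_b) * sum((abar[la] - ybar) ** 2 for la in levels_a)
        ss_b = r * len(levels_a) * sum((bbar[lb] - ybar) ** 2 for lb in levels_b)
        ss_ab = r * sum(
            (cbar[(la, lb)] - abar[la] - bbar[lb] + ybar) ** 2
            for la in levels_a
            for lb in levels_b
        )
        assert table.loc["A", "sum_sq"] == pytest.approx(ss_a, rel=1e-8)
        assert table.loc["B", "sum_sq"] == pytest.approx(ss_b, rel=1e-8)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(ss_ab, rel=1e-8)
        # df partition: terms + residual sum to N - 1
        assert table["df"].sum() == len(y) - 1

    def test_single_level_factor_reduces_to_one_way(self, rng):
        y = np.concatenate([rng.normal(10, 1, 12), rng.normal(12, 1, 12)])
        a = ["w"] * 12 + ["c"] * 12
        b = ["only"] * 24
        table = og.two_way_anova(y, a, b, names=("season", "sex")).table
        f_oracle = stats.f_oneway(y[:12], y[12:])
        assert table.loc["season", "F"] == pytest.approx(f_oracle.statistic, rel=1e-8)
        assert table.loc["season", "PR(>F)"] == pytest.approx(f_oracle.pvalue, rel=1e-6)

    def test_empty_cell_flags_interaction_inestimable(self, rng):
        a = ["w"] * 10 + ["c"] * 5
        b = ["f"] * 5 + ["m"] * 5 + ["f"] * 5  # no (c, m) cell
        y = rng.normal(10, 1, 15)
        res = og.two_way_anova(y, a, b, names=("season", "sex"))
        assert res.inestimable == ("season:sex",)
        assert "season" in res.table.index
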