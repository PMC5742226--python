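import numpy as np
import pytest
from scipy import stats

from rupestre.habitat_stats import (
    check_assumptions,
    one_tailed_t,
    significance_flag,
    tukey_contrast,
    two_way_anova,
)


class TestOneTailedT:
    def test_symmetric_values_give_half(self):
        r = one_tailed_t([-2.0, -1.0, 1.0, 2.0])
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(0.5)
        assert r.flag == "NS"

    def test_summary_variant_n5(self):
        # n=5 values with mean 0.92 and SE 0.92: t ≈ 0.997, upper-tail p ≈ 0.188
        mean, se, n = 0.92, 0.92, 5
        sd = se * np.sqrt(n)
        base = np.array([-1.2, -0.5, 0.0, 0.5, 1.2])
        vals = (base - base.mean()) / base.std(ddof=1) * sd + mean
        r = one_tailed_t(vals)
        assert r.count == 5 and r.df == 4
        assert r.mean == pytest.approx(0.92)
        assert r.se == pytest.approx(0.92)
        assert r.t_stat == pytest.approx(1.0, abs=0.01)
        assert r.p_value == pytest.approx(0.188, abs=0.005)

    def test_closed_form_check(self):
        vals = [1, 1, 1, 1, 2]
        r = one_tailed_t(vals)
        n = 5
        m = np.mean(vals)
        s = np.std(vals, ddof=1)
        t = m / (s / np.sqrt(n))
        assert r.t_stat == pytest.approx(t)
        assert r.p_value == pytest.approx(float(stats.t.sf(t, n - 1)))

    def test_internal_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(0.5, 1.0, size=rng.integers(3, 30))
            r = one_tailed_t(vals)
            assert r.se == pytest.approx(r.sd / np.sqrt(r.count))
            assert r.df == r.count - 1
            assert r.t_stat == pytest.approx(r.mean / r.se)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            one_tailed_t([1.0, 1.0, 1.0])

    def test_two_sided_option(self):
        vals = [-3.0, -1.0, -2.0, -2.5]
        r1 = one_tailed_t(vals)
        r2 = one_tailed_t(vals, alternative="two-sided")
        assert r1.p_value > 0.5  # mean < 0, upper tail
        assert r2.p_value == pytest.approx(2 * (1 - r1.p_value))


def test_significance_flags():
    assert significance_flag(0.2) == "NS"
    assert significance_flag(0.04) == "*"
    assert significance_flag(0.004) == "**"
    assert significance_flag(0.0004) == "***"


def sequential_ss_oracle(y, factors):
    """Type I sums of squares by incremental least-squares projection."""
    n = len(y)
    y = np.asarray(y, float)
    blocks = [np.ones((n, 1))]
    ss = []
    rss_prev = float(((y - y.mean()) ** 2).sum())
    for cols in factors:
        blocks.append(cols)
        X = np.hstack(blocks)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        ss.append(rss_prev - rss)
        rss_prev = rss
    return ss, rss_prev


def dummies(levels):
    labs = sorted(set(levels))
    return np.column_stack([[1.0 if l == lab else 0.0 for l in levels]
                            for lab in labs[1:]])


class TestTwoWayAnova:
    def test_identical_cell_means_no_effects(self):
        sub = ["c"] * 4 + ["q"] * 4
        phy = ["open", "open", "forest", "forest"] * 2
        y = [1.0, 1.1, 0.9, 1.0, 1.05, 0.95, 1.0, 1.0]
        rows = two_way_anova(y, sub, phy)
        fs = {r.term: r.f_value for r in rows if r.term != "error"}
        assert all(f < 1.5 for f in fs.values())

    def test_additive_design_zero_interaction(self):
        sub_eff = {"c": 0.0, "q": 2.0}
        phy_eff = {"open": 0.0, "forest": 1.0}
        sub, phy, y = [], [], []
        for s in ("c", "q"):
            for p in ("open", "forest"):
                for _ in range(3):
                    sub.append(s), phy.append(p)
                    y.append(sub_eff[s] + phy_eff[p])
        rows = two_way_anova(y, sub, phy)
        inter = next(r for r in rows if r.term == "interaction")
        assert inter.sum_sq == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_matches_projection_oracle(self):
        rng = np.random.default_rng(42)
        counts = {("c", "open"): 5, ("c", "forest"): 9,
                  ("q", "open"): 11, ("q", "forest"): 22}
        sub, phy = [], []
        for (s, p), k in counts.items():
            sub += [s] * k
            phy += [p] * k
        y = rng.normal(size=len(sub)) + (np.array(sub) == "q") * 0.8
        rows = two_way_anova(y, sub, phy)

        Xs = dummies(sub)
        Xp = dummies(phy)
        Xi = Xs * Xp
        ss, rss = sequential_ss_oracle(y, [Xs, Xp, Xi])
        got = {r.term: r.sum_sq for r in rows}
        assert got["substrate"] == pytest.approx(ss[0], rel=1e-8)
        assert got["physiognomy"] == pytest.approx(ss[1], rel=1e-8)
        assert got["interaction"] == pytest.approx(ss[2], rel=1e-8)
        assert got["error"] == pytest.approx(rss, rel=1e-8)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(1)
        sub = rng.choice(["c", "q"], size=30).tolist()
        phy = rng.choice(["open", "forest"], size=30).tolist()
        y = rng.normal(size=30)
        rows = two_way_anova(y, sub, phy)
        total = float(((y - np.mean(y)) ** 2).sum())
        assert sum(r.sum_sq for r in rows) == pytest.approx(total, rel=1e-8)

    def test_dfs_and_f_ratio(self):
        rng = np.random.default_rng(2)
        sub = ["c"] * 20 + ["q"] * 27
        phy = (["open", "forest"] * 24)[:47]
        y = rng.normal(size=47)
        rows = two_way_anova(y, sub, phy)
        err = next(r for r in rows if r.term == "error")
        assert err.df == 47 - 4
        assert sum(r.df for r in rows) == 46
        for r in rows:
            if r.term != "error":
                assert r.f_value == pytest.approx(r.mean_square / err.mean_square)

    def test_empty_cell_rejected(self):
        sub = ["c", "c", "q", "q"]
        phy = ["open", "open", "open", "open"]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova([1.0, 2.0, 3.0, 4.0], sub, phy)


class TestTukey:
    def test_identical_means_p_one(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["a"] * 3 + ["b"] * 3
        tk = tukey_contrast(y, g, mse=1.0, df_error=4)
        assert tk.iloc[0]["p_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_two_equal_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        y = np.concatenate([a, b])
        g = ["a"] * 10 + ["b"] * 10
        mse = (a.var(ddof=1) * 9 + b.var(ddof=1) * 9) / 18
        tk = tukey_contrast(y, g, mse=mse, df_error=18)
        t_stat, p_two = stats.ttest_ind(a, b)
        assert tk.iloc[0]["q"] == pytest.approx(np.sqrt(2) * abs(t_stat))
        assert tk.iloc[0]["p_adj"] == pytest.approx(p_two, rel=1e-6)

    def test_large_separation_significant(self):
        y = [0.0, 0.01, -0.01, 5.0, 5.01, 4.99]
        g = ["a"] * 3 + ["b"] * 3
        tk = tukey_contrast(y, g, mse=1e-4, df_error=4)
        assert tk.iloc[0]["p_adj"] < 0.001

    def test_four_level_mode(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(m, 1, 8) for m in (0, 0, 0, 3)])
        g = sum([[h] * 8 for h in ("FC", "FQ", "OC", "OQ")], [])
        mse = 1.0
        tk = tukey_contrast(y, g, mse=mse, df_error=28)
        assert len(tk) == 6
        worst = tk.sort_values("q").iloc[-1]
        assert {worst["level_a"], worst["level_b"]} == {"FC", "OQ"} or worst["p_adj"] < 0.01

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_contrast([1.0, 2.0], ["a", "b"], mse=1.0, df_error=0)


class TestAssumptions:
    def test_common_normal_groups_pass(self):
        rng = np.random.default_rng(11)
        groups = {h: rng.normal(0, 1, 12) for h in ("FC", "FQ", "OC", "OQ")}
        rep = check_assumptions(groups)
        shap = rep[rep["test"] == "shapiro"]
        assert (shap["p"] > 0.001).all()
        lev = rep[rep["test"] == "levene"].iloc[0]
        assert lev["p"] > 0.01

    def test_variance_outlier_detected(self):
        rng = np.random.default_rng(12)
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 1, 15),
            "c": rng.normal(0, 10, 15),
        }
        rep = check_assumptions(groups)
        lev = rep[rep["test"] == "levene"].iloc[0]
        assert lev["p"] < 0.05

    def test_constant_group_flagged(self):
        rep = check_assumptions({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        row = rep[(rep["test"] == "shapiro") & (rep["group"] == "a")].iloc[0]
        assert np.isnan(row["p"]) and "undefined" in row["note"]
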