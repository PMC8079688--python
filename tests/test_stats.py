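"""Statistical layer: worked examples, oracle equivalence, invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scistats

from eegbattery.stats import (
    anova_two_way,
    holm_sidak,
    ks_normality,
    mannwhitney_exact,
    normality_gated_comparison,
    rmcorr,
    welch_t,
)


class TestWelch:
    def test_identical_groups_null(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_computed_example(self):
        # equal variances, shift 1: t = -1 with Welch-Satterthwaite df = 8
        r = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.statistic == pytest.approx(-1.0, abs=1e-12)
        assert r.df == pytest.approx(8.0, abs=1e-9)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 3, 20)
        r = welch_t(x, y)
        ref = scistats.ttest_ind(x, y, equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    @given(c=st.floats(0.1, 10), d=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, c, d):
        x = np.array([1.0, 2.5, 3.0, 7.0])
        y = np.array([2.0, 4.0, 4.5, 9.0, 1.0])
        r0 = welch_t(x, y)
        r1 = welch_t(c * x + d, c * y + d)
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-9)

    def test_degenerate_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])


def _brute_force_mw_p(x, y):
    """Exact two-tailed Mann-Whitney p by enumerating every rank assignment."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = scistats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_small_example_enumeration(self):
        # x below y entirely: U = 0; 2 of C(4,2)=6 arrangements as extreme
        r = mannwhitney_exact([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 6, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 2), (5, 4), (6, 3)])
    def test_matches_brute_force(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(1.0, 1.0, size=n2)
        r = mannwhitney_exact(x, y)
        assert r.flags["method"] == "exact"
        assert r.p_value == pytest.approx(_brute_force_mw_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("x,u_target,p_expect", [
        # one x above all 5 y's, one above a single y: U = 6
        ([1, 2, 3, 4, 5, 6, 10.5, 20.0], 6, 0.0451),
        # one x above all 5 y's: U = 5
        ([1, 2, 3, 4, 5, 6, 7, 20.0], 5, 0.0295),
    ])
    def test_published_exact_values(self, x, u_target, p_expect):
        """U = 6 and U = 5 at group sizes 8 and 5 give the known exact
        two-tailed p-values 0.0451 and 0.0295."""
        y = np.arange(10.0, 15.0)
        r = mannwhitney_exact(np.asarray(x, float), y)
        assert r.statistic == u_target
        assert r.p_value == pytest.approx(p_expect, abs=5e-5)

    def test_ties_fall_back_to_normal_approx(self):
        r = mannwhitney_exact([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert r.flags["method"] == "normal_approx"
        assert 0.0 <= r.p_value <= 1.0


class TestKsNormality:
    def test_affine_invariance_of_d(self, rng):
        x = rng.normal(3.0, 2.0, 40)
        d0 = ks_normality(x).statistic
        d1 = ks_normality(5.0 * x - 7.0).statistic
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_constant_sample_routed_nonnormal(self):
        r = ks_normality(np.full(10, 3.0))
        assert r.flags["normal"] is False and r.flags.get("constant")

    def test_uniform_samples_rejected(self, rng):
        rej = sum(not ks_normality(rng.uniform(size=100)).flags["normal"]
                  for _ in range(100))
        assert rej > 50

    def test_normal_samples_mostly_pass(self, rng):
        rej = sum(not ks_normality(rng.standard_normal(30)).flags["normal"]
                  for _ in range(200))
        assert rej < 30  # ~5% expected


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.3])[0] == pytest.approx(0.3)

    def test_hand_example(self):
        adj = holm_sidak([0.02, 0.5])
        assert adj[0] == pytest.approx(1 - 0.98**2, abs=1e-12)  # 0.0396
        assert adj[1] == pytest.approx(0.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominate_raw_and_monotone(self, ps):
        adj = holm_sidak(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _anova_projection_oracle(df, repeated=None):
    """Brute-force SS via projection matrices (hat-matrix differences)."""
    y = df["y"].to_numpy()
    def proj(cols):
        X = np.column_stack(cols)
        return X @ np.linalg.pinv(X.T @ X) @ X.T
    one = np.ones_like(y)
    d_a = pd.get_dummies(df["A"]).to_numpy(float)
    d_b = pd.get_dummies(df["B"]).to_numpy(float)
    d_ab = pd.get_dummies(df["A"].astype(str) + "*" + df["B"].astype(str)).to_numpy(float)
    p0 = proj([one])
    pa = proj([one, d_a])
    pb = proj([one, d_b])
    pab_add = proj([one, d_a, d_b])
    pcell = proj([one, d_ab])
    ss_a = y @ (pa - p0) @ y
    ss_b = y @ (pb - p0) @ y
    ss_int = y @ (pcell - pab_add) @ y
    ss_err = y @ (np.eye(len(y)) - pcell) @ y
    return ss_a, ss_b, ss_int, ss_err


class TestAnova:
    def test_constant_cells_all_f_zero(self):
        df = pd.DataFrame({"A": list("aabb") * 3, "B": list("xyxy") * 3,
                           "y": 5.0, "subject": range(12)})
        tab = anova_two_way(df).table.set_index("effect")
        assert (tab.loc[["A", "B", "A:B"], "F"] == 0).all()

    def test_additive_means_zero_interaction(self):
        rows = []
        for a, va in (("a", 1.0), ("b", 3.0)):
            for b, vb in (("x", 0.0), ("y", 10.0)):
                for r in range(4):
                    rows.append({"A": a, "B": b, "y": va + vb, "subject": len(rows)})
        tab = anova_two_way(pd.DataFrame(rows)).table.set_index("effect")
        assert tab.loc["A:B", "SS"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_projection_oracle(self, rng):
        for _ in range(10):
            df = pd.DataFrame({
                "A": np.repeat(["a1", "a2", "a3"], 8),
                "B": np.tile(np.repeat(["b1", "b2"], 4), 3),
                "y": rng.normal(size=24),
                "subject": np.arange(24),
            })
            tab = anova_two_way(df).table.set_index("effect")
            ss_a, ss_b, ss_int, ss_err = _anova_projection_oracle(df)
            assert tab.loc["A", "SS"] == pytest.approx(ss_a, rel=1e-8)
            assert tab.loc["B", "SS"] == pytest.approx(ss_b, rel=1e-8)
            assert tab.loc["A:B", "SS"] == pytest.approx(ss_int, rel=1e-8, abs=1e-10)
            assert tab.loc["error", "SS"] == pytest.approx(ss_err, rel=1e-8)

    def test_unbalanced_refused(self, rng):
        df = pd.DataFrame({"A": list("aaabb"), "B": list("xyxyx"),
                           "y": rng.normal(size=5), "subject": range(5)})
        with pytest.raises(ValueError, match="unbalanced"):
            anova_two_way(df)

    def test_mixed_design_df_partition(self, rng):
        # 6 subjects x 2 groups x 2 within levels; dfs follow the mixed layout
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "A": np.repeat(["g1"] * 6 + ["g2"] * 6, 2),
            "B": np.tile(["s1", "s2"], 12),
            "y": rng.normal(size=24),
        })
        tab = anova_two_way(df, repeated="B").table.set_index("effect")
        assert tab.loc["A", "df"] == 1
        assert tab.loc["subjects(between)", "df"] == 10
        assert tab.loc["B", "df"] == 1
        assert tab.loc["A:B", "df"] == 1
        assert tab.loc["subjects:within", "df"] == 10
        assert tab["SS"].sum() == pytest.approx(((df.y - df.y.mean()) ** 2).sum())

    def test_mixed_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "group": np.repeat(["g1"] * 5 + ["g2"] * 5, 3),
            "w": np.tile(["w1", "w2", "w3"], 10),
            "y": rng.normal(size=30),
        })
        tab = anova_two_way(df, dv="y", factor_a="group", factor_b="w",
                            repeated="w").table.set_index("effect")
        ref = pg.mixed_anova(df, dv="y", between="group", within="w",
                             subject="subject").set_index("Source")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert tab.loc["w", "F"] == pytest.approx(ref.loc["w", "F"], rel=1e-6)
        assert tab.loc["group:w", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)


class TestRmcorr:
    def test_perfect_common_slope(self):
        df = pd.DataFrame({
            "subject": ["a"] * 3 + ["b"] * 3,
            "x": [0, 1, 2, 0, 1, 2],
            "y": [5, 3, 1, 9, 7, 5],  # slope -2 with different intercepts
        })
        r = rmcorr(df)
        assert r.r_rm == pytest.approx(-1.0)
        assert r.slope == pytest.approx(-2.0)

    def test_df_formula(self, rng):
        df = pd.DataFrame({"subject": ["a"] * 5 + ["b"] * 5,
                           "x": rng.normal(size=10), "y": rng.normal(size=10)})
        assert rmcorr(df).df == 10 - 2 - 1

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame({"subject": np.repeat(np.arange(6), 10),
                           "x": rng.normal(size=60)})
        df["y"] = -0.4 * df["x"] + rng.normal(size=60) + df["subject"].to_numpy() * 1.5
        mine = rmcorr(df)
        ref = pg.rm_corr(df, x="x", y="y", subject="subject")
        assert mine.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert mine.df == int(ref["dof"].iloc[0])
        assert mine.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_shift_invariance_per_subject(self, rng):
        df = pd.DataFrame({"subject": np.repeat(["a", "b", "c"], 8),
                           "x": rng.normal(size=24), "y": rng.normal(size=24)})
        r0 = rmcorr(df).r_rm
        shifted = df.copy()
        offs = {"a": 10.0, "b": -4.0, "c": 100.0}
        shifted["x"] = shifted["x"] + shifted["subject"].map(offs)
        shifted["y"] = shifted["y"] + shifted["subject"].map(offs) * 2
        assert rmcorr(shifted).r_rm == pytest.approx(r0, abs=1e-9)

    def test_constant_x_subject_dropped(self, rng):
        df = pd.DataFrame({"subject": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                           "x": [1.0] * 4 + list(rng.normal(size=8)),
                           "y": rng.normal(size=12)})
        with pytest.warns(UserWarning, match="constant x"):
            r = rmcorr(df)
        assert r.dropped_subjects == ["a"]


def test_normality_gate_routes_heavy_tailed_to_mannwhitney(rng):
    x = rng.standard_normal(25)
    y = np.exp(rng.standard_normal(25) * 2.0)  # grossly non-normal
    res = normality_gated_comparison(x, y)
    assert res["selected"] == "mannwhitney_u"
    assert {"welch_t", "mannwhitney_u"} <= set(res)
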