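"""Statistical tests against independent oracles: closed forms,
OLS-projection sums of squares, pingouin, and hand rank computations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from pairbond import stats as st


def long_table(y, subjects=None, levels=None):
    n, k = y.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    levels = levels or [f"l{j}" for j in range(k)]
    rows = [
        {"subject": subjects[i], "level": levels[j], "value": y[i, j]}
        for i in range(n)
        for j in range(k)
    ]
    return pd.DataFrame(rows)


class TestTTests:
    def test_identical_samples_t0_p1(self):
        res = st.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0
        res = st.unpaired_t([1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_pooled_df_is_n1_plus_n2_minus_2(self, rng):
        x, y = rng.normal(size=11), rng.normal(size=11)
        res = st.unpaired_t(x, y)
        assert res.df1 == 20  # e.g. two groups of 11 cells

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=9), rng.normal(1.0, 1.0, size=12)
        ours = st.unpaired_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)
        xp, yp = rng.normal(size=8), rng.normal(size=8)
        ours = st.paired_t(xp, yp)
        ref = sps.ttest_rel(xp, yp)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_sign_convention_first_minus_second(self):
        res = st.unpaired_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert res.statistic > 0


def ols_rm_f_oracle(y):
    """Independent route to the within-subject F: OLS projections on
    subject and level factor spaces."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    tab = long_table(y)
    full = smf.ols("value ~ C(subject) + C(level)", data=tab).fit()
    reduced = smf.ols("value ~ C(subject)", data=tab).fit()
    n, k = y.shape
    ss_level = reduced.ssr - full.ssr
    ss_err = full.ssr
    return (ss_level / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_equal_level_values_give_f0_p1(self):
        y = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 3))
        res = st.rm_anova_gg(long_table(y), posthoc=False)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_k2_equals_paired_t_squared_and_eps_1(self, rng):
        y = rng.normal(size=(8, 2))
        res = st.rm_anova_gg(long_table(y), posthoc=False)
        t = st.paired_t(y[:, 0], y[:, 1])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.epsilon == 1.0
        assert res.p == pytest.approx(t.p, rel=1e-9)

    @pytest.mark.parametrize("n,k", [(4, 3), (6, 4), (5, 5)])
    def test_f_matches_ols_projection_oracle(self, rng, n, k):
        y = rng.normal(size=(n, k))
        res = st.rm_anova_gg(long_table(y), posthoc=False)
        assert res.statistic == pytest.approx(ols_rm_f_oracle(y), abs=1e-10)

    def test_matches_pingouin_including_epsilon(self, rng):
        y = rng.normal(size=(7, 3))
        tab = long_table(y)
        res = st.rm_anova_gg(tab, posthoc=False)
        ref = pg.rm_anova(data=tab, dv="value", within="level", subject="subject", correction=True)
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-9)

    def test_epsilon_bounds(self, rng):
        for _ in range(20):
            y = rng.normal(size=(6, 4))
            eps = st.gg_epsilon(y)
            assert 1.0 / 3 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_gg_dfs_are_epsilon_scaled(self, rng):
        y = rng.normal(size=(7, 3))
        res = st.rm_anova_gg(long_table(y), posthoc=False)
        assert res.df1 == pytest.approx(res.epsilon * 2)
        assert res.df2 == pytest.approx(res.epsilon * 12)

    def test_incomplete_design_names_missing_cells(self, rng):
        tab = long_table(rng.normal(size=(4, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="s3"):
            st.rm_anova_gg(tab)

    def test_posthoc_is_sidak_over_all_pairs(self, rng):
        y = rng.normal(size=(6, 3))
        res = st.rm_anova_gg(long_table(y))
        assert len(res.posthoc) == 3
        for ph in res.posthoc:
            assert ph.p_adj == pytest.approx(1 - (1 - ph.p_raw) ** 3)


class TestMixedAnova:
    def balanced_table(self, rng, n_per=6, k=3):
        rows = []
        for grp in ("control", "cohabitation"):
            for s in range(n_per):
                base = rng.normal()
                for j in range(k):
                    rows.append(
                        {
                            "subject": f"{grp}-{s}",
                            "group": grp,
                            "treatment": f"t{j}",
                            "value": base + rng.normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_all_f_statistics_match_pingouin(self, rng):
        tab = self.balanced_table(rng)
        res = st.mixed_anova(tab)
        ref = pg.mixed_anova(
            data=tab, dv="value", within="treatment", between="group", subject="subject"
        ).set_index("Source")
        assert res.statistic == pytest.approx(float(ref.loc["Interaction", "F"]), abs=1e-10)
        assert res.extras["group"].statistic == pytest.approx(
            float(ref.loc["group", "F"]), abs=1e-10
        )
        assert res.extras["within"].statistic == pytest.approx(
            float(ref.loc["treatment", "F"]), abs=1e-10
        )

    def test_duplicated_columns_have_zero_interaction(self, rng):
        # every subject shows the same treatment profile → no interaction
        profile = np.array([1.0, 2.0, 4.0])
        rows = []
        for grp, offset in (("a", 0.0), ("b", 3.0)):
            for s in range(4):
                for j in range(3):
                    rows.append(
                        {
                            "subject": f"{grp}{s}",
                            "group": grp,
                            "treatment": f"t{j}",
                            "value": offset + profile[j],
                        }
                    )
        res = st.mixed_anova(pd.DataFrame(rows))
        assert res.statistic == pytest.approx(0.0, abs=1e-18)

    def test_subject_in_two_groups_rejected(self, rng):
        tab = self.balanced_table(rng)
        tab.loc[tab["subject"] == "control-0", "group"] = "cohabitation"
        tab.loc[tab.index[0], "group"] = "control"
        with pytest.raises(ValueError, match="group"):
            st.mixed_anova(tab)


class TestTwoWayAnova:
    def test_matches_pingouin_type3(self, rng):
        rows = []
        for v in ("Gq", "Gi", "mCherry"):
            for d in ("CNO", "saline"):
                for _ in range(7):
                    rows.append({"virus": v, "drug": d, "value": rng.normal()})
        tab = pd.DataFrame(rows)
        ours = st.two_way_anova(tab, "virus", "drug")
        ref = pg.anova(data=tab, dv="value", between=["virus", "drug"], ss_type=3).set_index(
            "Source"
        )
        assert ours["virus"].statistic == pytest.approx(float(ref.loc["virus", "F"]), rel=1e-9)
        assert ours["drug"].statistic == pytest.approx(float(ref.loc["drug", "F"]), rel=1e-9)
        assert ours["interaction"].statistic == pytest.approx(
            float(ref.loc["virus * drug", "F"]), rel=1e-9
        )

    def test_balanced_2x2_interaction_contrast_oracle(self, rng):
        """In a balanced 2×2 the interaction F equals the squared t of the
        cell-mean contrast (m11 − m12 − m21 + m22)/2."""
        n = 8
        cells = {}
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                v = rng.normal(size=n)
                cells[(a, b)] = v
                rows += [{"f1": a, "f2": b, "value": x} for x in v]
        ours = st.two_way_anova(pd.DataFrame(rows), "f1", "f2")["interaction"]
        contrast = (
            cells[("a1", "b1")].mean()
            - cells[("a1", "b2")].mean()
            - cells[("a2", "b1")].mean()
            + cells[("a2", "b2")].mean()
        ) / 2.0
        mse = np.mean([np.var(v, ddof=1) for v in cells.values()])
        f_oracle = contrast**2 / (mse * (4 / (4 * n)))
        assert ours.statistic == pytest.approx(f_oracle, rel=1e-9)

    def test_empty_cell_rejected(self):
        tab = pd.DataFrame(
            {"f1": ["a", "a", "b"], "f2": ["x", "y", "x"], "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="empty"):
            st.two_way_anova(tab, "f1", "f2")


class TestSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.05, 1, 0.05), (0.01, 3, 0.029701), (0.0, 5, 0.0), (1.0, 2, 1.0)],
    )
    def test_closed_form(self, p, m, expected):
        assert st.sidak_adjust([p], m)[0] == pytest.approx(expected, abs=1e-12)

    def test_family_size_validation(self):
        with pytest.raises(ValueError):
            st.sidak_adjust([0.1], 0)


class TestKruskalWallis:
    def test_identical_groups_h0_p1(self):
        res = st.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]], posthoc=False)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_rank_oracle(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2,5,8 give
        H = 12/(N(N+1)) Σ n R̄² − 3(N+1) = 7.2."""
        res = st.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]], posthoc=False)
        h_oracle = 12.0 / (9 * 10) * (3 * 2**2 + 3 * 5**2 + 3 * 8**2) - 3 * 10
        assert res.statistic == pytest.approx(h_oracle, rel=1e-12)
        assert res.df1 == 2

    def test_tie_correction_reduces_h(self):
        untied = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]], posthoc=False)
        # replace distinct values by ties across groups; H must not increase
        tied = st.kruskal_wallis([[1, 2], [2, 4], [4, 6]], posthoc=False)
        assert tied.statistic < untied.statistic

    def test_dunn_posthoc_count_and_adjustment(self):
        res = st.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]], ["a", "b", "c"])
        assert len(res.posthoc) == 3
        for ph in res.posthoc:
            assert ph.p_adj == pytest.approx(1 - (1 - ph.p_raw) ** 3)


class TestAssumptionChecks:
    def test_equal_spread_groups_pass_levene(self, rng):
        g1, g2 = rng.normal(size=200), rng.normal(size=200)
        checks = st.assumption_checks([g1, g2])
        assert checks["levene_p"] > 0.01
        assert not checks["degenerate"]

    def test_constant_sample_degenerate(self):
        checks = st.assumption_checks([[1.0, 1.0, 1.0]])
        assert checks["degenerate"]

    def test_ks_estimated_params_is_conservative(self):
        """KS against a normal with sample-estimated mean/sd rejects at
        most at the nominal rate (the estimated-parameter KS is
        conservative, not uniform)."""
        rejections = 0
        for seed in range(300):
            x = np.random.default_rng(seed).normal(size=100)
            if st.assumption_checks([x])["ks_p"] < 0.05:
                rejections += 1
        assert rejections / 300 < 0.05
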