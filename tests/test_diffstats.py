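"""Per-gene tests, Dunnett adjustment, Storey q-values, covariate screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bloodsig.core import ValidationError
from bloodsig.diffstats import (
    de_table,
    gene_aucs,
    oneway_dunnett,
    spearman_age_screen,
    storey_qvalues,
    twoway_anova,
    welch_t,
    welch_t_matrix,
)
from .conftest import expr_from_log2, planted_config


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # closed-form Welch on [1,2,3,4] vs [3,4,5,6]: equal variances 5/3,
        # se = sqrt(2*(5/3)/4), t = -2/se, Satterthwaite df = 6 exactly
        t, df, p = welch_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-4)
        assert df == pytest.approx(6.0, abs=1e-9)

    def test_group_swap_flips_sign_only(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(3.5 * a - 2, 3.5 * b - 2)
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2)

    def test_p_matches_monte_carlo_null(self):
        """The analytic p agrees with a simulated null to Monte-Carlo error."""
        a = np.array([0.1, 1.2, -0.4, 0.9, 0.3])
        b = np.array([1.1, 1.9, 0.8, 2.1])
        t_obs, df, p = welch_t(a, b)
        rng = np.random.default_rng(42)
        n_mc = 200_000
        za = rng.standard_normal((n_mc, a.size))
        zb = rng.standard_normal((n_mc, b.size))
        va = za.var(axis=1, ddof=1) / a.size
        vb = zb.var(axis=1, ddof=1) / b.size
        t_null = (za.mean(axis=1) - zb.mean(axis=1)) / np.sqrt(va + vb)
        p_mc = (np.abs(t_null) >= abs(t_obs)).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(p - p_mc) < 3 * se + 1e-12

    def test_both_groups_constant_is_an_error(self):
        with pytest.raises(ValidationError, match="constant"):
            welch_t([2, 2, 2], [3, 3, 3])

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (5, 7))
        b = rng.normal(0.3, 1.5, (5, 9))
        t, df, p = welch_t_matrix(a, b)
        for i in range(5):
            ts, dfs, ps = welch_t(a[i], b[i])
            assert t[i] == pytest.approx(ts)
            assert df[i] == pytest.approx(dfs)
            assert p[i] == pytest.approx(ps)


class TestDunnett:
    def test_two_group_reduction_matches_pooled_t(self):
        rng = np.random.default_rng(3)
        g = {"A": rng.normal(0.4, 1, 18)}
        ctrl = rng.normal(0, 1, 20)
        res = oneway_dunnett(g, ctrl, n_draws=200_000, seed=1)
        # with one comparison the adjusted p equals the two-sided pooled t p
        t = res["t"].iloc[0]
        nu = 18 + 20 - 2
        p_pooled = 2 * stats.t.sf(abs(t), nu)
        assert res["p_adjusted"].iloc[0] == pytest.approx(p_pooled, abs=0.005)

    def test_agrees_with_scipy_dunnett(self):
        rng = np.random.default_rng(4)
        groups = {"AUT": rng.normal(0.5, 1, 15), "PDDNOS": rng.normal(0.2, 1, 12),
                  "ASP": rng.normal(0.0, 1, 9)}
        ctrl = rng.normal(0, 1, 20)
        mine = oneway_dunnett(groups, ctrl, n_draws=200_000, seed=2)
        ref = stats.dunnett(*groups.values(), control=ctrl)
        np.testing.assert_allclose(mine["p_adjusted"].to_numpy(),
                                   np.asarray(ref.pvalue), atol=0.01)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        for s in range(5):
            groups = {k: rng.normal(rng.normal(), 1, 10) for k in "abc"}
            res = oneway_dunnett(groups, rng.normal(0, 1, 10),
                                 n_draws=20_000, seed=s)
            assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()

    def test_null_adjusted_p_roughly_uniform(self):
        """Permuting labels of one null gene gives uniform adjusted p-values."""
        rng = np.random.default_rng(6)
        y = rng.standard_normal(45)
        ps = []
        for _ in range(300):
            idx = rng.permutation(45)
            groups = {"A": y[idx[:10]], "B": y[idx[10:20]]}
            res = oneway_dunnett(groups, y[idx[20:]], n_draws=4_000,
                                 seed=int(rng.integers(2 ** 31)))
            ps.append(res["p_adjusted"].min())
        # min over 2 comparisons of adjusted p is itself ~uniform under the null
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            oneway_dunnett({"A": [1.0]}, [0.0, 1.0, 2.0])


class TestTwowayAnova:
    def test_balanced_design_type_II_equals_sequential(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(40)
        dx = ["case"] * 20 + ["control"] * 20
        sex = (["male"] * 10 + ["female"] * 10) * 2
        p2 = twoway_anova(y, dx, sex)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = pd.DataFrame({"y": y, "dx": dx, "sex": sex})
        t1 = sm.stats.anova_lm(smf.ols("y ~ C(dx) * C(sex)", df).fit(), typ=1)
        assert p2[0] == pytest.approx(t1.loc["C(dx)", "PR(>F)"], abs=1e-9)
        assert p2[1] == pytest.approx(t1.loc["C(sex)", "PR(>F)"], abs=1e-9)

    def test_planted_diagnosis_main_effect(self):
        rng = np.random.default_rng(8)
        dx = np.array(["case"] * 30 + ["control"] * 30)
        sex = np.array((["male"] * 20 + ["female"] * 10) * 2)
        y = rng.standard_normal(60) + (dx == "case") * 1.5
        p_dx, p_sex, p_int = twoway_anova(y, dx, sex)
        assert p_dx < 0.001
        assert p_int > 0.01  # no planted interaction

    def test_sex_only_gene(self):
        rng = np.random.default_rng(9)
        dx = np.array(["case"] * 30 + ["control"] * 30)
        sex = np.array((["male"] * 20 + ["female"] * 10) * 2)
        y = rng.standard_normal(60) + (sex == "female") * 2.0
        p_dx, p_sex, _ = twoway_anova(y, dx, sex)
        assert p_sex < 1e-6
        assert p_dx > 0.01

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError, match="cell"):
            twoway_anova([1.0, 2.0, 3.0, 4.0],
                         ["case", "case", "control", "control"],
                         ["male", "male", "male", "male"])


class TestStorey:
    def test_uniform_pvalues_give_pi0_near_one(self):
        rng = np.random.default_rng(0)
        res = storey_qvalues(rng.random(10_000))
        assert 0.9 <= res.pi0 <= 1.0

    def test_pi0_one_reduces_to_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.random(500)
        q = storey_qvalues(p, pi0=1.0).qvalues
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    def test_qvalues_monotone_in_p_rank(self, p):
        res = storey_qvalues(np.array(p))
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(res.qvalues[order]) >= -1e-12).all()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            storey_qvalues([])


class TestSpearman:
    def _matrix(self, rows):
        return expr_from_log2(np.asarray(rows, dtype=float))

    def test_monotone_gene_rho_one(self):
        age = np.arange(1.0, 9.0)
        x = self._matrix([np.linspace(5, 8, 8), np.linspace(8, 5, 8)])
        res = spearman_age_screen(x, age)
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["rho"].iloc[1] == pytest.approx(-1.0)
        assert res["p_value"].iloc[0] < 1e-6

    def test_p_within_factor_two_of_permutation_oracle(self):
        rng = np.random.default_rng(10)
        age = rng.uniform(4, 13, 20)
        y = 6 + 0.04 * age + 0.3 * rng.standard_normal(20)
        x = self._matrix([y])
        res = spearman_age_screen(x, age)
        rho_obs = abs(res["rho"].iloc[0])
        n_perm = 100_000
        ry = stats.rankdata(y)
        ra = stats.rankdata(age)
        perms = np.array([rng.permutation(ra) for _ in range(n_perm)])
        ryc = ry - ry.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_null = (pc @ ryc) / np.sqrt((pc ** 2).sum(axis=1) * (ryc ** 2).sum())
        count = int((np.abs(r_null) >= rho_obs - 1e-12).sum())
        p_perm = max(count / n_perm, 1 / n_perm)
        assert 0.5 <= res["p_value"].iloc[0] / p_perm <= 2.0

    def test_constant_gene_flagged_excluded(self):
        age = np.arange(1.0, 7.0)
        x = self._matrix([np.full(6, 7.0), np.linspace(5, 8, 6)])
        res = spearman_age_screen(x, age)
        assert bool(res["excluded"].iloc[0])
        assert np.isnan(res["rho"].iloc[0])
        assert not res["excluded"].iloc[1]

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError, match="n >= 4"):
            spearman_age_screen(self._matrix([[5, 6, 7]]), [1, 2, 3])


class TestDeTable:
    def test_alpha_one_flags_everything(self):
        rng = np.random.default_rng(11)
        x = expr_from_log2(rng.uniform(5, 9, (20, 10)))
        labels = np.array([True] * 5 + [False] * 5)
        de = de_table(x, labels, alpha=1.0)
        assert de["significant"].all()

    def test_screen_type_I_error_in_band(self):
        """The p<0.001 screen's false-positive rate sits in [0.0005, 0.002]."""
        rng = np.random.default_rng(12)
        hits, total = 0, 0
        for _ in range(50):
            y = rng.uniform(5, 9, 400)[:, None] + 0.5 * rng.standard_normal((400, 60))
            labels = np.array([True] * 40 + [False] * 20)
            de = de_table(expr_from_log2(y), labels, alpha=0.001)
            hits += int(de["significant"].sum())
            total += 400
        assert 0.0005 <= hits / total <= 0.002

    def test_planted_signal_detected(self):
        """At delta=1.5 most of the 55 planted genes pass the p<0.001 screen."""
        from bloodsig.synthdata import simulate
        counts = []
        for s in range(10):
            cfg = planted_config(400 + s, effect_size=1.5)
            _, x2, samples, _, _, truth = simulate(cfg)
            p2 = [i for i in samples.sample_ids if i.startswith("p2")]
            de = de_table(x2, samples.is_case(p2))
            sig = set(de.index[de["significant"]])
            counts.append(len(sig & set(truth.signal_genes)))
        assert np.median(counts) >= 45

    def test_fold_change_on_linear_scale(self):
        x = expr_from_log2(np.array([[8.0, 8.0, 7.0, 7.0]]))
        de = de_table(x, np.array([True, True, False, False]), alpha=1.0)
        assert de["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_auc_columns_bounded(self):
        rng = np.random.default_rng(13)
        x = expr_from_log2(rng.uniform(5, 9, (30, 12)))
        de = de_table(x, np.array([True] * 6 + [False] * 6))
        assert ((de["auc"] >= 0) & (de["auc"] <= 1)).all()
        assert ((de["q_value"] >= 0) & (de["q_value"] <= 1)).all()


def test_gene_aucs_pairwise_example():
    # cases [3,5], control [4]: one concordant and one discordant pair
    vals = np.array([[3.0, 5.0, 4.0]])
    assert gene_aucs(vals, np.array([True, True, False]))[0] == pytest.approx(0.5)
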