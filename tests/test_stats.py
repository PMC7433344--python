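"""Statistics battery: p-value routines, Student t, split-plot ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special
from scipy import stats as sps

from startlekit.stats import (GroupSample, format_p, mixed_anova,
                              mixed_anova_sums_of_squares, p_from_f, p_from_t,
                              student_t_test)


def t_density(x, df):
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


class TestPFromT:
    def test_symmetric_and_one_at_zero(self):
        assert p_from_t(0.0, 5) == 1.0
        assert p_from_t(2.5, 12) == p_from_t(-2.5, 12)

    def test_agrees_with_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the t density upper tail
        for df in range(1, 61):
            for t in (0.25, 1.0, 2.5, 4.0, 7.0, 10.0):
                tail, _ = integrate.quad(t_density, t, np.inf, args=(df,))
                assert p_from_t(t, df) == pytest.approx(2 * tail, abs=1e-6)

    def test_incomplete_beta_identity(self):
        for t, df in ((1.3, 4), (3.3, 21), (0.4, 60)):
            ib = special.betainc(df / 2, 0.5, df / (df + t * t))
            assert p_from_t(t, df) == pytest.approx(ib, abs=1e-12)

    def test_invalid_df_raises(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)


class TestPFromF:
    def test_zero_statistic_is_one(self):
        assert p_from_f(0.0, 3, 27) == 1.0

    def test_agrees_with_scipy_distribution(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            F = rng.uniform(0, 6)
            df1, df2 = int(rng.integers(1, 10)), int(rng.integers(2, 60))
            assert p_from_f(F, df1, df2) == pytest.approx(sps.f.sf(F, df1, df2))

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            p_from_f(1.0, 0, 5)
        with pytest.raises(ValueError):
            p_from_f(-1.0, 3, 5)


class TestStudentTTest:
    def test_identical_samples(self):
        g = GroupSample("a", [1.0, 2.0, 3.0])
        r = student_t_test(g, GroupSample("b", [1.0, 2.0, 3.0]))
        assert r.t == 0.0 and r.p == 1.0
        assert r.f_ratio == 1.0

    def test_zero_variance_group_gives_infinite_variance_ratio(self):
        r = student_t_test(GroupSample("a", [0.0, 0.0, 0.0]),
                           GroupSample("b", [1.0, 2.0, 3.0]))
        assert math.isinf(r.f_ratio)

    def test_hand_computed_pooled_formula(self):
        r = student_t_test(GroupSample("a", [1, 2, 3, 4]), GroupSample("b", [3, 4, 5, 6]))
        assert r.t == pytest.approx(-2.19089, abs=1e-5)
        assert r.df == 6

    def test_df_is_n1_plus_n2_minus_2(self):
        r = student_t_test(GroupSample("a", np.arange(10.0)),
                           GroupSample("b", np.arange(9.0)))
        assert r.df == 17

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(2, 15)))
            b = rng.normal(0.3, 2, int(rng.integers(2, 15)))
            r = student_t_test(GroupSample("a", a), GroupSample("b", b))
            t, p = sps.ttest_ind(a, b, equal_var=True)
            assert r.t == pytest.approx(t, abs=1e-12)
            assert r.p == pytest.approx(p, abs=1e-12)

    def test_variance_ratio_is_larger_over_smaller(self):
        a = GroupSample("a", [0.0, 10.0, -10.0])  # big variance
        b = GroupSample("b", [1.0, 1.1, 0.9, 1.0])
        r = student_t_test(a, b)
        assert r.f_ratio >= 1.0
        assert r.f_df == (2, 3)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="n >= 2"):
            student_t_test(GroupSample("a", [1.0]), GroupSample("b", [1.0, 2.0]))


def random_table(rng, n1, n2, k=4):
    y = rng.normal(0, 1, (n1 + n2, k)) + rng.normal(0, 1, (n1 + n2, 1))
    table = pd.DataFrame(y, index=[f"a{i}" for i in range(n1 + n2)],
                         columns=[70, 80, 90, 100] if k == 4 else list(range(k)))
    geno = pd.Series(["g1"] * n1 + ["g2"] * n2, index=table.index)
    return table, geno


class TestMixedAnova:
    @pytest.mark.parametrize("n1,n2,df2", [(5, 6, 27), (8, 7, 39)])
    def test_interaction_dfs_for_cohort_sizes(self, n1, n2, df2):
        table, geno = random_table(np.random.default_rng(7), n1, n2)
        res = mixed_anova(table, geno)
        assert (res.df1, res.df2) == (3, df2)

    def test_additive_noiseless_data_has_zero_interaction(self):
        levels = np.array([0.0, 1.0, 2.0, 3.0])
        rows = [levels + g for g in [0, 0.5, 0.5, 2, 2, 2.5]]
        table = pd.DataFrame(rows, index=[f"a{i}" for i in range(6)],
                             columns=[70, 80, 90, 100])
        geno = pd.Series(["g1"] * 3 + ["g2"] * 3, index=table.index)
        res = mixed_anova(table, geno)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-12)

    def test_sums_of_squares_partition_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            k = int(rng.integers(2, 6))
            table, geno = random_table(rng, n1, n2, k)
            ss = mixed_anova_sums_of_squares(table, geno)
            # brute-force check of the split-plot partition
            parts = (ss["genotype"] + ss["error_between"] + ss["level"]
                     + ss["interaction"] + ss["error_within"])
            assert parts == pytest.approx(ss["total"], rel=1e-10)
            assert ss["between_subjects"] == pytest.approx(
                ss["genotype"] + ss["error_between"], rel=1e-10)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        table, geno = random_table(np.random.default_rng(9), 5, 6)
        res = mixed_anova(table, geno)
        long = table.reset_index().melt(id_vars="index", var_name="level",
                                        value_name="y")
        long["geno"] = long["index"].map(geno)
        ref = pg.mixed_anova(data=long, dv="y", within="level",
                             subject="index", between="geno")
        inter = ref[ref.Source == "Interaction"].iloc[0]
        assert res.F_interaction == pytest.approx(inter.F, rel=1e-9)
        assert (res.df1, res.df2) == (inter.DF1, inter.DF2)
        assert res.p_interaction == pytest.approx(inter.p_unc, rel=1e-9)

    def test_posthoc_bonferroni_adjustment(self):
        table, geno = random_table(np.random.default_rng(10), 5, 6)
        res = mixed_anova(table, geno)
        assert len(res.posthoc) == 4
        for c in res.posthoc:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 4))
            assert c.df == 9

    def test_missing_cell_error_names_animal_and_intensity(self):
        table, geno = random_table(np.random.default_rng(11), 5, 6)
        table.loc["a3", 90] = np.nan
        with pytest.raises(ValueError, match="a3.*90"):
            mixed_anova(table, geno)

    def test_requires_two_groups(self):
        table, geno = random_table(np.random.default_rng(12), 5, 6)
        with pytest.raises(ValueError, match="2 genotype groups"):
            mixed_anova(table, pd.Series("g1", index=table.index))


def test_null_rejection_rate_is_nominal():
    # Student t under H0, alpha = 0.05 (modest replication; the full
    # 10 000-rep battery runs in the acceptance suite)
    rng = np.random.default_rng(13)
    rej = sum(student_t_test(GroupSample("a", rng.normal(0, 1, 10)),
                             GroupSample("b", rng.normal(0, 1, 10))).p < 0.05
              for _ in range(2000))
    assert 0.035 <= rej / 2000 <= 0.065


def test_format_p_renders_report_style():
    assert format_p(0.01482) == "0.0148"
    assert format_p(3e-5) == "< 0.0001"
    assert format_p(0.9999) == "0.9999"
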