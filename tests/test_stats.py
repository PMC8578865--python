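"""Correlation, t-test and ANOVA machinery against brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neuroindex import (
    gg_epsilon,
    mixed_anova,
    paired_t,
    pearson,
    posthoc_vs_baseline,
    rm_anova_oneway,
    two_sample_t,
)


# ---------------------------------------------------------------- oracles

def brute_pearson(x, y):
    """Direct-summation Pearson r, t, p (python loops, no vector algebra)."""
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sxy = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    sxx = sum((a - xm) ** 2 for a in x)
    syy = sum((b - ym) ** 2 for b in y)
    r = sxy / (sxx * syy) ** 0.5
    t = r * ((n - 2) / (1 - r * r)) ** 0.5
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, t, p


def brute_rm_ss(data):
    """Two-way (subjects x conditions) SS decomposition by explicit loops."""
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    rowm = [sum(data[i]) / k for i in range(n)]
    colm = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_subj = k * sum((m - grand) ** 2 for m in rowm)
    ss_time = n * sum((m - grand) ** 2 for m in colm)
    ss_err = sum(
        (data[i][j] - rowm[i] - colm[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    return ss_subj, ss_time, ss_err


def brute_split_plot_ss(data, group):
    """Split-plot SS decomposition by explicit summation."""
    n, k = data.shape
    levels = sorted(set(group))
    grand = data.mean()
    subj = data.mean(axis=1)
    ss_group = k * sum(
        (group == g).sum() * (subj[group == g].mean() - grand) ** 2 for g in levels
    )
    ss_sw = k * sum(
        (subj[i] - subj[group == group[i]].mean()) ** 2 for i in range(n)
    )
    ss_time = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_cells = sum(
        (group == g).sum() * (data[group == g, j].mean() - grand) ** 2
        for g in levels for j in range(k)
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_ew = sum(
        (data[i, j] - data[group == group[i], j].mean()
         - subj[i] + subj[group == group[i]].mean()) ** 2
        for i in range(n) for j in range(k)
    )
    return ss_group, ss_sw, ss_time, ss_inter, ss_ew


# ---------------------------------------------------------------- pearson

class TestPearson:
    def test_identity_and_anticorrelation(self):
        res = pearson([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        res = pearson([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0)
        assert res.p_two_tailed == 0.0

    def test_hand_computed_half_correlation(self):
        res = pearson([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(0.25)
        assert res.df == 1

    def test_matches_scipy_on_random_fixtures(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = pearson(x, y)
            ref_r, ref_p = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref_r, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(ref_p, rel=1e-9)

    @given(a=st.floats(-100, 100, allow_nan=False),
           b=st.floats(0.01, 100, allow_nan=False))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_under_positive_affine_transform(self, a, b):
        x = np.array([0.3, -1.2, 2.4, 0.9, -0.5])
        y = np.array([1.0, 0.2, 1.7, -0.3, 0.8])
        assert pearson(x, a + b * y).r == pytest.approx(pearson(x, y).r, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


# ---------------------------------------------------------------- t tests

class TestTTests:
    def test_welch_hand_computed(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0)

    def test_identical_samples_give_p_one(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_two_tailed == 1.0

    def test_translation_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=12)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(a + 5.0, b + 5.0)
        assert r1.t_stat == pytest.approx(r2.t_stat, rel=1e-12)

    def test_welch_matches_scipy(self, rng):
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(3, 20)))
            b = rng.normal(1.0, 2.0, size=int(rng.integers(3, 20)))
            res = two_sample_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(size=9)
        b = a + rng.normal(0.4, 1.0, size=9)
        res = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------- epsilon

class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 2.0 * np.eye(4) + 0.7 * (np.ones((4, 4)) - np.eye(4))
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_two_conditions_forced_to_one(self, rng):
        x = rng.normal(size=(10, 2)) @ np.array([[1.0, 0.4], [0.0, 2.0]])
        assert gg_epsilon(np.cov(x, rowvar=False)) == pytest.approx(1.0)

    def test_dominant_eigenvalue_approaches_lower_bound(self):
        # one strong component after double centering -> epsilon ~ 1/(k-1)
        v = np.array([3.0, -1.0, -1.0, -1.0])
        S = np.outer(v, v) + 1e-6 * np.eye(4)
        eps = gg_epsilon(S)
        k = 4
        C = np.eye(k) - np.ones((k, k)) / k
        St = C @ S @ C
        direct = np.trace(St) ** 2 / ((k - 1) * np.sum(St * St))
        assert eps == pytest.approx(direct, rel=1e-9)
        assert eps == pytest.approx(1 / 3, abs=1e-3)

    def test_bounds_on_random_covariances(self, rng):
        for k in (3, 4, 5):
            for _ in range(20):
                a = rng.normal(size=(k + 3, k))
                S = np.cov(a, rowvar=False)
                eps = gg_epsilon(S)
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gg_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_epsilon_estimator_conservative_under_sphericity(self, rng):
        # sample epsilon under a truly spherical population approaches 1 from below
        eps = []
        for _ in range(200):
            x = rng.normal(size=(12, 4))  # iid => compound symmetric population
            eps.append(gg_epsilon(np.cov(x, rowvar=False)))
        m = np.mean(eps)
        assert 0.6 < m < 1.0


# ---------------------------------------------------------------- rm anova

class TestRmAnova:
    def test_identical_columns_null_effect(self, rng):
        col = rng.normal(size=8)
        data = np.tile(col[:, None], (1, 4))
        res = rm_anova_oneway(data)
        e = res.effect("time")
        assert e.ss == pytest.approx(0.0, abs=1e-18)
        assert e.f_stat == 0.0
        assert e.p == 1.0

    def test_brute_force_ss_decomposition(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 6))
            data = rng.integers(-5, 15, size=(n, k)).astype(float)
            res = rm_anova_oneway(data)
            ss_subj, ss_time, ss_err = brute_rm_ss(data)
            assert res.components["subjects"][0] == pytest.approx(ss_subj, abs=1e-8)
            assert res.effect("time").ss == pytest.approx(ss_time, abs=1e-8)
            assert res.components["error"][0] == pytest.approx(ss_err, abs=1e-8)
            assert res.ss_total == pytest.approx(ss_subj + ss_time + ss_err, abs=1e-8)

    def test_two_conditions_equal_squared_paired_t(self, rng):
        for _ in range(20):
            data = rng.normal(size=(int(rng.integers(3, 12)), 2))
            res = rm_anova_oneway(data)
            t = paired_t(data[:, 1], data[:, 0])
            assert res.effect("time").f_stat == pytest.approx(t.t_stat**2, rel=1e-9)
            assert res.effect("time").epsilon == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        data = rng.normal(size=(12, 4)) + np.array([0.0, 0.4, 0.9, 1.1])
        res = rm_anova_oneway(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "time": np.tile(np.arange(4), 12),
                "y": data.ravel(),
            }
        )
        ref = pg.rm_anova(long, dv="y", within="time", subject="subject",
                          correction=True)
        e = res.effect("time")
        assert e.f_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert e.p_uncorrected == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        assert e.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert e.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            rm_anova_oneway(data)


class TestPosthoc:
    def test_column_equal_to_baseline(self, rng):
        base = rng.normal(size=6)
        data = np.column_stack([base, base, base + 1.0])
        contrasts = posthoc_vs_baseline(data, 0)
        assert contrasts[0].t_stat == 0.0
        assert contrasts[0].p_raw == 1.0

    def test_constant_shift_degenerates_to_infinite_t(self):
        data = np.column_stack([[5.0, 6.0, 7.0], [2.0, 3.0, 4.0]])
        con = posthoc_vs_baseline(data, 0)[0]
        assert np.isinf(con.t_stat)
        assert con.p_raw == 0.0

    def test_hand_computed_paired_t(self, rng):
        data = rng.normal(size=(5, 3))
        con = posthoc_vs_baseline(data, 0)[1]
        d = data[:, 2] - data[:, 0]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert con.t_stat == pytest.approx(t, rel=1e-12)
        assert con.df == 4

    def test_bonferroni_scales_p(self, rng):
        data = rng.normal(size=(8, 4))
        raw = posthoc_vs_baseline(data, 0, "none")
        adj = posthoc_vs_baseline(data, 0, "bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))


# ---------------------------------------------------------------- mixed anova

class TestMixedAnova:
    def _fixture(self, rng, n_per=6, k=3, shift=0.0, interaction=0.0):
        g0 = rng.normal(size=(n_per, k))
        g1 = rng.normal(size=(n_per, k)) + shift
        g1 += interaction * np.arange(k)
        data = np.vstack([g0, g1])
        group = np.array(["a"] * n_per + ["b"] * n_per)
        return data, group

    def test_identical_groups_have_null_group_effects(self, rng):
        half = rng.normal(size=(5, 3))
        data = np.vstack([half, half])
        group = np.array(["a"] * 5 + ["b"] * 5)
        res = mixed_anova(data, group)
        assert res.effect("drug").f_stat == pytest.approx(0.0, abs=1e-20)
        assert res.effect("drug:time").ss == pytest.approx(0.0, abs=1e-18)

    def test_parallel_profiles_have_zero_interaction(self, rng):
        half = rng.normal(size=(5, 4))
        data = np.vstack([half, half + 2.5])
        group = np.array(["a"] * 5 + ["b"] * 5)
        res = mixed_anova(data, group)
        assert res.effect("drug:time").ss == pytest.approx(0.0, abs=1e-10)

    def test_brute_force_ss_decomposition(self, rng):
        for n_per in (2, 4, 5):
            data, group = self._fixture(rng, n_per=n_per, shift=0.8, interaction=0.3)
            res = mixed_anova(data, group)
            ssg, sssw, sst, ssi, ssew = brute_split_plot_ss(data, group)
            assert res.effect("drug").ss == pytest.approx(ssg, abs=1e-8)
            assert res.components["subjects_within_groups"][0] == pytest.approx(sssw, abs=1e-8)
            assert res.effect("time").ss == pytest.approx(sst, abs=1e-8)
            assert res.effect("drug:time").ss == pytest.approx(ssi, abs=1e-8)
            assert res.components["error_within"][0] == pytest.approx(ssew, abs=1e-8)

    def test_components_nonnegative_and_sum_to_total(self, rng):
        for _ in range(20):
            n_per = int(rng.integers(2, 7))
            k = int(rng.integers(2, 5))
            data, group = self._fixture(rng, n_per=n_per, k=k,
                                        shift=float(rng.normal()),
                                        interaction=float(rng.normal()))
            res = mixed_anova(data, group)
            parts = [res.effect("drug").ss, res.effect("time").ss,
                     res.effect("drug:time").ss,
                     res.components["subjects_within_groups"][0],
                     res.components["error_within"][0]]
            assert all(p >= 0 for p in parts)
            assert sum(parts) == pytest.approx(res.ss_total, rel=1e-9)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        data, group = self._fixture(rng, n_per=8, k=4, shift=0.6, interaction=0.4)
        res = mixed_anova(data, group)
        n, k = data.shape
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "time": np.tile(np.arange(k), n),
                "grp": np.repeat(group, k),
                "y": data.ravel(),
            }
        )
        ref = pg.mixed_anova(long, dv="y", within="time", subject="subject",
                             between="grp")
        ref = ref.set_index("Source")
        assert res.effect("drug").f_stat == pytest.approx(float(ref.loc["grp", "F"]), rel=1e-9)
        assert res.effect("time").f_stat == pytest.approx(float(ref.loc["time", "F"]), rel=1e-9)
        assert res.effect("drug:time").f_stat == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-9
        )

    def test_single_subject_group_rejected(self, rng):
        data = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            mixed_anova(data, np.array(["a", "a", "b"]))
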