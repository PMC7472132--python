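import numpy as np
import pytest
from scipy import stats as sstats

from ecgdenoise import ParameterError, independent_t_test, rm_anova_bonferroni


def brute_force_rm_f(groups: np.ndarray) -> float:
    """Repeated-measures F from explicit sums of squares, loop form."""
    n, k = groups.shape
    grand = groups.sum() / (n * k)
    ss_cond = 0.0
    for j in range(k):
        mean_j = sum(groups[i][j] for i in range(n)) / n
        ss_cond += n * (mean_j - grand) ** 2
    ss_subj = 0.0
    for i in range(n):
        mean_i = sum(groups[i][j] for j in range(k)) / k
        ss_subj += k * (mean_i - grand) ** 2
    ss_total = sum((groups[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def closed_form_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestRmAnova:
    def test_identical_groups_f_zero_p_one(self):
        groups = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        res = rm_anova_bonferroni(groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.pairwise_p.values())

    def test_large_offsets_all_pairwise_significant(self, rng):
        base = rng.normal(0, 0.01, size=8)
        groups = np.stack([base, base + 10.0, base + 20.0], axis=1)
        res = rm_anova_bonferroni(groups)
        assert res.p_value < 1e-10
        assert all(p < 0.05 for p in res.pairwise_p.values())

    def test_f_matches_brute_force_sums_of_squares(self, rng):
        groups = rng.normal(size=(7, 3)) + np.array([0.0, 0.5, 1.1])
        res = rm_anova_bonferroni(groups)
        assert res.f_statistic == pytest.approx(brute_force_rm_f(groups), rel=1e-9)
        assert res.df_conditions == 2 and res.df_error == 12

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        groups = rng.normal(size=(6, 3)) + np.array([0.0, 0.3, 0.9])
        res = rm_anova_bonferroni(groups)
        long = pd.DataFrame(
            {
                "y": groups.ravel(),
                "cond": list(range(3)) * 6,
                "subj": np.repeat(range(6), 3),
            }
        )
        pg = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert res.f_statistic == pytest.approx(float(pg["F"].iloc[0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(pg["p_unc"].iloc[0]), rel=1e-6)

    def test_textbook_paired_t_posthoc(self):
        groups = np.array([[1.0, 2.0, 3.5], [2.0, 3.0, 4.0], [0.5, 2.5, 3.0], [1.5, 2.0, 4.5]])
        res = rm_anova_bonferroni(groups)
        t, p = sstats.ttest_rel(groups[:, 0], groups[:, 1])
        assert res.pairwise_p[(0, 1)] == pytest.approx(min(1.0, 3 * p), rel=1e-9)

    def test_unbalanced_input_rejected(self):
        with pytest.raises(ParameterError):
            rm_anova_bonferroni(np.zeros((2, 3)))
        with pytest.raises(ParameterError):
            rm_anova_bonferroni(np.zeros(5))


class TestIndependentT:
    def test_equal_samples_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = independent_t_test(a, a)
        assert t == 0.0 and p == 1.0

    def test_tiny_variance_large_offset(self):
        a = np.zeros(4)
        b = np.array([10.0, 10.0, 10.0, 10.0001])
        _, p = independent_t_test(a, b)
        assert p < 1e-6

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        _, p1 = independent_t_test(a, b)
        _, p2 = independent_t_test(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy(self, rng, equal_var):
        a, b = rng.normal(size=9), rng.normal(0.8, 1.3, size=14)
        t, p = independent_t_test(a, b, equal_var=equal_var)
        ref = sstats.ttest_ind(a, b, equal_var=equal_var)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_closed_form_t_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        t, _ = independent_t_test(a, b)
        assert t == pytest.approx(closed_form_t(a, b), rel=1e-12)

    def test_degenerate_equal_means(self):
        t, p = independent_t_test(np.ones(3), np.ones(4))
        assert (t, p) == (0.0, 1.0)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ParameterError):
            independent_t_test(np.array([1.0]), np.array([1.0, 2.0]))
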