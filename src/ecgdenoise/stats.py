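"""Statistical tests used by the evaluation protocol.

One-way repeated-measures ANOVA with Bonferroni-corrected paired t-tests as
the post-hoc, and a two-sample (independent) t-test.  The F and t statistics
are computed from first-principles sums of squares so that they are directly
auditable against brute-force computation; only the distribution tail
probabilities come from scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import ParameterError


@dataclass(frozen=True)
class RMAnovaResult:
    f_statistic: float
    p_value: float
    df_conditions: int
    df_error: int
    pairwise_p: dict[tuple[int, int], float]  # Bonferroni-adjusted paired t


def rm_anova_bonferroni(groups: np.ndarray) -> RMAnovaResult:
    """Repeated-measures ANOVA over ``groups`` (n_subjects x n_conditions).

    Post-hoc: all pairwise paired t-tests, p-values multiplied by the number
    of pairs (capped at 1).  Requires a balanced layout with at least two
    conditions and three subjects.
    """
    groups = np.asarray(groups, dtype=float)
    if groups.ndim != 2:
        raise ParameterError("groups must be a (subjects x conditions) matrix")
    n, k = groups.shape
    if k < 2 or n < 3:
        raise ParameterError("need >= 2 conditions and >= 3 subjects")
    if not np.all(np.isfinite(groups)):
        raise ParameterError("groups contain non-finite values")

    grand = groups.mean()
    cond_means = groups.mean(axis=0)
    subj_means = groups.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((groups - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat = 0.0 if ms_cond == 0 else float("inf")
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f_stat = ms_cond / ms_err
        p = float(sstats.f.sf(f_stat, df_cond, df_err))

    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            d = groups[:, i] - groups[:, j]
            sd = d.std(ddof=1)
            if sd == 0:
                p_ij = 1.0 if np.allclose(d, 0) else 0.0
            else:
                t = d.mean() / (sd / np.sqrt(n))
                p_ij = 2.0 * float(sstats.t.sf(abs(t), n - 1))
            pairwise[(i, j)] = min(1.0, n_pairs * p_ij)
    return RMAnovaResult(
        f_statistic=f_stat,
        p_value=p,
        df_conditions=df_cond,
        df_error=df_err,
        pairwise_p=pairwise,
    )


def independent_t_test(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    Pooled-variance by default, Welch with ``equal_var=False``.  If both
    samples are constant with equal means the result is (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs at least two values")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        return (0.0, 1.0) if diff == 0 else (float("inf") * np.sign(diff), 0.0)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = diff / se
    p = 2.0 * float(sstats.t.sf(abs(t), df))
    return float(t), p
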