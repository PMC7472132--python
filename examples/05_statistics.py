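"""The evaluation statistics on constructed data.

Repeated-measures ANOVA with Bonferroni post-hoc compares the ratio of
power across the clean/noisy/denoised conditions within subjects; the
independent t-test compares cross-correlation distributions.
"""

import numpy as np

from ecgdenoise import independent_t_test, rm_anova_bonferroni

rng = np.random.default_rng(0)
subject_effect = rng.normal(0.0, 0.02, size=6)
clean = 0.74 + subject_effect
noisy = 0.26 + subject_effect + rng.normal(0, 0.01, size=6)
denoised = 0.63 + subject_effect + rng.normal(0, 0.01, size=6)

res = rm_anova_bonferroni(np.stack([clean, noisy, denoised], axis=1))
print(f"RM-ANOVA: F({res.df_conditions},{res.df_error}) = {res.f_statistic:.1f}, "
      f"p = {res.p_value:.2e}")
for (i, j), p in res.pairwise_p.items():
    labels = ["clean", "noisy", "denoised"]
    print(f"  {labels[i]:8s} vs {labels[j]:8s}: Bonferroni p = {p:.2e}")

xc_noisy = rng.normal(0.49, 0.01, size=6)
xc_denoised = rng.normal(0.71, 0.01, size=6)
t, p = independent_t_test(xc_noisy, xc_denoised)
print(f"independent t-test on cross-correlations: t = {t:.2f}, p = {p:.2e}")
# both tests should flag the separation between noisy and denoised as significant
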