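"""Significance letters for genotype comparisons, the way figure panels do it.

Generates triplicate relative-abundance values for four genotypes and assigns
compact-letter-display letters with one-way ANOVA + Tukey HSD, then with
Kruskal-Wallis + rank-based Fisher LSD (Bonferroni).
"""

import numpy as np

from prmkit import stats

rng = np.random.default_rng(0)
groups = {
    "WT": list(rng.normal(1.00, 0.08, 3)),
    "aco3": list(rng.normal(0.05, 0.03, 3)),
    "S91A": list(rng.normal(0.95, 0.08, 3)),
    "S91D": list(rng.normal(2.60, 0.20, 3)),
}

for name, fn in [("ANOVA + Tukey HSD", stats.anova_tukey_letters),
                 ("Kruskal-Wallis + LSD", stats.kruskal_lsd_letters)]:
    disp = fn(groups, alpha=0.05)
    print(name)
    print(stats.summarize_groups(groups, disp).to_string(index=False))
    print()
# Groups sharing a letter are not significantly different at alpha = 0.05;
# the phosphomimetic S91D group separates from the others in both tests.
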