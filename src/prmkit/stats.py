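"""Group testing with significance letters and qPCR NRQ normalization.

Implements the statistical toolbox used alongside the quantification results:
pooled-variance Student's t for two-group contrasts, one-way ANOVA with Tukey
HSD and compact letter displays, Kruskal-Wallis with a rank-based (Conover)
Fisher-LSD post hoc under Bonferroni correction, and normalized relative
quantities (NRQ) for RT-qPCR with multi-reference-gene geometric-mean
normalization and delta-method standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError


@dataclass
class TwoGroupResult:
    t: float
    p: float
    significant: bool
    warning: str | None = None


def two_group_test(a, b, alpha: float = 0.05) -> TwoGroupResult:
    """Two-sided Student's t test with pooled variance.

    Degenerate inputs follow fixed conventions: zero pooled variance with equal
    means gives p = 1; zero pooled variance with unequal means gives p = 0 with
    a warning recorded on the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TwoGroupResult(t=0.0, p=1.0, significant=False)
        return TwoGroupResult(
            t=math.copysign(math.inf, diff), p=0.0, significant=True,
            warning="zero pooled variance with unequal means",
        )
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * _st.t.sf(abs(t), na + nb - 2)
    return TwoGroupResult(t=float(t), p=float(p), significant=p < alpha)


@dataclass
class LetterDisplay:
    """Significance letters: two groups share a letter iff their adjusted p >= alpha."""

    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float]
    alpha: float

    def consistent(self) -> bool:
        for (g1, g2), p in self.pairwise_p.items():
            share = bool(set(self.letters[g1]) & set(self.letters[g2]))
            if share != (p >= self.alpha):
                return False
        return True


def _compact_letter_display(
    groups: list[str], pairwise_p: dict[tuple[str, str], float], alpha: float
) -> dict[str, str]:
    """Insert-and-absorb construction of a compact letter display.

    Starts from one column holding every group; each significant pair splits
    every column containing both members into two copies (one without each
    member); columns that become subsets of another are absorbed.  Letters are
    assigned to columns in order of their earliest group.
    """
    columns: list[set[str]] = [set(groups)]
    for (g1, g2), p in sorted(pairwise_p.items()):
        if p >= alpha:
            continue
        new_columns = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop empties, proper subsets of another column, and duplicates
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns):
                continue
            if col not in columns:
                columns.append(col)
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def _check_groups(groups: dict[str, np.ndarray]):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n < 2")


def anova_tukey_letters(groups: dict[str, list[float]], alpha: float = 0.05) -> LetterDisplay:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letter assignment."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _check_groups(groups)
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = list(res.groupsunique)
    pairwise = {}
    for (i, j), p in zip(combinations(range(len(uniq)), 2), res.pvalues):
        key = tuple(sorted((uniq[i], uniq[j])))
        pairwise[key] = float(p)
    pairwise = {
        tuple(sorted(pair)): pairwise[tuple(sorted(pair))]
        for pair in combinations(names, 2)
    }
    letters = _compact_letter_display(names, pairwise, alpha)
    return LetterDisplay(letters=letters, pairwise_p=pairwise, alpha=alpha)


def kruskal_lsd_letters(groups: dict[str, list[float]], alpha: float = 0.05) -> LetterDisplay:
    """Kruskal-Wallis omnibus with rank-based Fisher LSD (Conover) post hoc.

    Pairwise comparisons use Conover's t statistics on mean ranks with a
    ties-corrected variance, Bonferroni-adjusted over all group pairs.  The
    post hoc only runs when the omnibus p < alpha; otherwise every group shares
    one letter (Fisher-LSD protection).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _check_groups(groups)
    names = list(groups)
    n_pairs = len(names) * (len(names) - 1) // 2
    h_stat, h_p = _st.kruskal(*[groups[g] for g in names])
    pooled = np.concatenate([groups[g] for g in names])
    ranks = _st.rankdata(pooled)
    sizes = [len(groups[g]) for g in names]
    split = np.cumsum(sizes)[:-1]
    mean_ranks = {g: r.mean() for g, r in zip(names, np.split(ranks, split))}
    n_total = len(pooled)
    k = len(names)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    scale = s2 * (n_total - 1 - h_stat) / (n_total - k)
    df = n_total - k
    pairwise = {}
    for g1, g2 in combinations(names, 2):
        key = tuple(sorted((g1, g2)))
        if h_p >= alpha:
            pairwise[key] = 1.0
            continue
        se = math.sqrt(scale * (1.0 / len(groups[g1]) + 1.0 / len(groups[g2])))
        if se == 0:
            p = 1.0 if mean_ranks[g1] == mean_ranks[g2] else 0.0
        else:
            t = abs(mean_ranks[g1] - mean_ranks[g2]) / se
            p = 2.0 * _st.t.sf(t, df)
        pairwise[key] = min(1.0, p * n_pairs)
    letters = _compact_letter_display(names, pairwise, alpha)
    return LetterDisplay(letters=letters, pairwise_p=pairwise, alpha=alpha)


def summarize_groups(groups: dict[str, list[float]], display: LetterDisplay) -> pd.DataFrame:
    """Group mean, sd, n and letters, as written to ``stats.csv``."""
    rows = []
    for g, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {"group": g, "mean": v.mean(), "sd": v.std(ddof=1), "n": v.size,
             "letters": display.letters[g]}
        )
    return pd.DataFrame(rows)


def nrq(
    cq: pd.DataFrame,
    efficiencies: dict[str, float],
    reference_genes: list[str],
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Normalized relative quantities with delta-method standard errors.

    ``cq`` has columns ``gene, sample, cq`` (technical replicates as repeated
    rows).  For gene g and sample s,

        RQ_{g,s}  = E_g ** (mean_s' Cq_{g,s'} - Cq_{g,s})
        NF_s      = geometric mean over reference genes of RQ
        NRQ_{g,s} = RQ_{g,s} / NF_s

    The default centering is the across-sample mean Cq per gene; passing a
    ``calibrator`` sample centers on that sample instead.  Standard errors
    propagate the technical-replicate SD of each Cq mean to NRQ by a
    first-order delta method (including the reference-gene contribution).
    """
    if len(reference_genes) < 2:
        raise ConfigurationError("need at least two reference genes")
    for g, e in efficiencies.items():
        if not 1.0 < e <= 2.0:
            raise ConfigurationError(f"efficiency of {g} must be in (1, 2]")
    agg = cq.groupby(["gene", "sample"])["cq"].agg(["mean", "std", "count"])
    if (agg["mean"] <= 0).any():
        raise ConfigurationError("Cq values must be > 0")
    genes = agg.index.get_level_values("gene").unique()
    samples = agg.index.get_level_values("sample").unique()
    for ref in reference_genes:
        for s in samples:
            if (ref, s) not in agg.index:
                raise ConfigurationError(f"sample {s!r} lacks Cq for reference gene {ref!r}")

    mean_cq = agg["mean"].unstack("sample")
    var_cq = (agg["std"].fillna(0.0) ** 2 / agg["count"]).unstack("sample").fillna(0.0)
    if calibrator is None:
        center = mean_cq.mean(axis=1)
    else:
        center = mean_cq[calibrator]
    log_e = pd.Series({g: math.log(efficiencies[g]) for g in genes})
    ln_rq = mean_cq.rsub(center, axis=0).mul(log_e, axis=0)
    ln_nf = ln_rq.loc[reference_genes].mean(axis=0)
    ln_nrq = ln_rq.sub(ln_nf, axis=1)

    m = len(reference_genes)
    rows = []
    for g in genes:
        for s in samples:
            if (g, s) not in agg.index:
                continue
            var = 0.0
            for r in reference_genes:
                w = 1.0 / m
                if r == g:
                    continue
                var += (w * log_e[r]) ** 2 * var_cq.loc[r, s]
            own_w = (1.0 - 1.0 / m) if g in reference_genes else 1.0
            var += (own_w * log_e[g]) ** 2 * var_cq.loc[g, s]
            value = math.exp(ln_nrq.loc[g, s])
            rows.append(
                {"gene": g, "sample": s, "nrq": value, "se": value * math.sqrt(var)}
            )
    return pd.DataFrame(rows)
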