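"""Inferential toolbox: Spearman correlation, Benjamini-Hochberg FDR,
two-sample t, two-way ANOVA with interaction, Tukey HSD with compact
letter display.

Thin, contract-checked wrappers over scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import TelovitaError


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    fdr_adjusted_p: float = np.nan


def spearman(x, y):
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise TelovitaError("x and y must have equal length")
    if x.size < 4:
        raise TelovitaError("need n >= 4 for a Spearman correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise TelovitaError("Spearman rho undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), n=int(x.size), p_value=float(p))


def benjamini_hochberg(p_values):
    """Step-up FDR adjustment; preserves input order, clips at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise TelovitaError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(panel, by=("sex", "organ"), hormones=("e2", "t", "kt11"),
                      measures=("ta_rel", "trf_bp"), family="per_sex"):
    """Tidy hormone-vs-(TA, TRF) Spearman table with BH adjustment.

    ``family`` controls which rows form one multiple-testing family:
    ``per_sex`` (default: all hormone x measure x organ tests of one sex)
    or ``all``.  The choice is recorded in the output.
    """
    rows = []
    for keys, grp in panel.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for h in hormones:
            for m in measures:
                r = spearman(grp[h], grp[m])
                rows.append((*keys, h, m, r.rho, r.n, r.p_value))
    out = pd.DataFrame(rows, columns=[*by, "hormone", "measure", "rho", "n", "p"])
    if family == "per_sex":
        out["p_adj"] = out.groupby("sex")["p"].transform(
            lambda s: benjamini_hochberg(s.to_numpy()))
    elif family == "all":
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        raise TelovitaError(f"unknown FDR family {family!r}")
    out.attrs["fdr_family"] = family
    return out


@dataclass
class AnovaTable:
    table: pd.DataFrame  # terms x (sum_sq, df, F, PR(>F))

    def f_and_p(self, term):
        row = self.table.loc[term]
        return float(row["F"]), float(row["PR(>F)"])


def two_way_anova(values, factor_a, factor_b, names=("sex", "age")):
    """Two-way ANOVA with interaction, sequential (type I) sums of squares."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       names[0]: factor_a, names[1]: factor_b})
    cells = df.groupby([names[0], names[1]]).size()
    a_levels = df[names[0]].nunique()
    b_levels = df[names[1]].nunique()
    if a_levels < 2 or b_levels < 2:
        raise TelovitaError("need >= 2 levels per factor")
    if len(cells) < a_levels * b_levels:
        raise TelovitaError(
            "empty design cells: fit a cell-means parameterisation instead")
    if (cells < 2).any():
        raise TelovitaError("need >= 2 replicates per cell for the interaction")
    model = ols(f"value ~ C({names[0]}) * C({names[1]})", data=df).fit()
    return AnovaTable(table=anova_lm(model, typ=1))


@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float


def t_test(a, b):
    """Two-sample pooled-variance Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TelovitaError("need >= 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise TelovitaError("t undefined: zero variance and equal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(statistic=float(t), df=float(a.size + b.size - 2),
                       p_value=float(p))


@dataclass
class TukeyResult:
    table: pd.DataFrame  # pairwise comparisons
    letters: dict  # group -> letter string (shared letter = not sig. different)


def tukey_hsd(values, groups, alpha=0.05):
    """Tukey HSD with a compact letter display (presentation layer).

    Groups sharing any letter are not significantly different at ``alpha``.
    Letters come from a greedy clique cover of the non-significant-pair
    graph, visiting groups in descending mean order.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    sig = {}
    for (g1, g2, reject) in zip(table["group1"], table["group2"], table["reject"]):
        sig[frozenset((str(g1), str(g2)))] = bool(reject)

    means = pd.Series(values).groupby(pd.Series(groups).astype(str)).mean()
    ordered = list(means.sort_values(ascending=False).index)
    cliques = []  # each clique: set of mutually non-different groups
    for g in ordered:
        placed = False
        for clique in cliques:
            if all(not sig.get(frozenset((g, other)), False) for other in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in ordered}
    for letter, clique in zip(alphabet, cliques):
        for g in ordered:
            if g in clique:
                letters[g] += letter
    return TukeyResult(table=table, letters=letters)
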