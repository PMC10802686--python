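"""Group comparison statistics for bio-factors.

One-way ANOVA with Tukey post-hoc evaluations (HSD, or Tukey-Kramer for
unequal group sizes), Holm-Bonferroni family-wise error control across the
bio-factors, Glass delta effect sizes (healthy SD as denominator), and a
family-adjusted ANOVA for relative analyses in which the unique family is
the unit of analysis, so the error degrees of freedom equal the number of
unique families minus the number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "glass_delta",
    "anova_oneway",
    "tukey_posthoc",
    "equivalence_classes",
    "holm_bonferroni",
    "family_adjusted_anova",
    "compare_groups",
]


def glass_delta(mean_g: float, mean_h: float, sd_h: float) -> float:
    """Glass's delta: (group mean - healthy mean) / healthy SD."""
    if sd_h <= 0:
        raise ValueError("healthy SD must be positive")
    return (mean_g - mean_h) / sd_h


def _group_arrays(y, groups):
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    return y, groups, [y[groups == g] for g in levels], levels


def anova_oneway(y, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns (F, df_between, df_error, p)."""
    y, groups, parts, levels = _group_arrays(y, groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs n >= 2")
    n = len(y)
    grand = y.mean()
    ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    dfb, dfe = g - 1, n - g
    if ssw == 0:
        F = 0.0 if ssb == 0 else np.inf
    else:
        F = (ssb / dfb) / (ssw / dfe)
    p = float(stats.f.sf(F, dfb, dfe)) if np.isfinite(F) else 0.0
    return float(F), dfb, dfe, p


def tukey_posthoc(y, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons by the studentized range.

    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) — the Tukey-Kramer
    standard error, which reduces to Tukey's HSD for equal group sizes.
    p-values come from the studentized range distribution with the number
    of groups and the ANOVA error df.
    """
    y, groups, parts, levels = _group_arrays(y, groups)
    if any(len(p) < 2 for p in parts):
        raise ValueError("singleton group in Tukey post-hoc")
    g = len(levels)
    n = len(y)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    dfe = n - g
    msw = ssw / dfe
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = parts[i], parts[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
            q = np.abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, g, dfe)) if np.isfinite(q) else 0.0
            rows.append(
                dict(group_a=levels[i], group_b=levels[j], diff=diff, q=q,
                     p=p, significant=p < alpha)
            )
    return pd.DataFrame(rows)


def equivalence_classes(y, groups, pairwise: pd.DataFrame) -> str:
    """Ordered equivalence-class pattern such as ``"(A = B) < C"``.

    Groups are ordered by mean; classes are the connected components of the
    non-significant-pair graph (transitive closure), ordered by class mean.
    """
    y, groups, parts, levels = _group_arrays(y, groups)
    means = {g: p.mean() for g, p in zip(levels, parts)}
    parent = {g: g for g in levels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, row in pairwise.iterrows():
        if not row["significant"]:
            ra, rb = find(row["group_a"]), find(row["group_b"])
            if ra != rb:
                parent[ra] = rb
    classes: dict = {}
    for g in levels:
        classes.setdefault(find(g), []).append(g)
    ordered = sorted(
        classes.values(), key=lambda mem: np.mean([means[g] for g in mem])
    )
    pieces = []
    for mem in ordered:
        mem = sorted(mem, key=lambda g: means[g])
        if len(mem) == 1:
            pieces.append(str(mem[0]))
        else:
            pieces.append("(" + " = ".join(map(str, mem)) + ")")
    return " < ".join(pieces)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down decisions (boolean reject array, original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def family_adjusted_anova(y, groups, family_ids) -> tuple[float, int, int, float]:
    """One-way ANOVA with the unique family as the unit of analysis.

    Observations within a family are first averaged (families are nested in
    groups: relatives share their proband's biotype), then an ordinary
    one-way ANOVA is run on the family means.  The error degrees of freedom
    therefore equal (number of unique families) - (number of groups), the
    adjustment described for analyses in which some families contribute
    several members.  When every subject is its own family this reduces
    exactly to :func:`anova_oneway`.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    family_ids = np.asarray(family_ids)
    if not (len(y) == len(groups) == len(family_ids)):
        raise ValueError("y, groups and family_ids must align")
    df = pd.DataFrame(dict(y=y, g=groups, fam=family_ids))
    fam_groups = df.groupby("fam")["g"].nunique()
    if (fam_groups > 1).any():
        raise ValueError("a family spans multiple groups; families must be "
                         "nested in groups")
    fam = df.groupby("fam").agg(y=("y", "mean"), g=("g", "first"))
    g = fam["g"].nunique()
    if len(fam) < g + 1:
        raise ValueError("need more unique families than groups")
    return anova_oneway(fam["y"].to_numpy(), fam["g"].to_numpy())


@dataclass
class ComparisonTable:
    """Per-factor ANOVA + post-hoc + effect-size summary."""

    table: pd.DataFrame
    pairwise: dict[str, pd.DataFrame]
    alpha: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_groups(
    scores: pd.DataFrame,
    groups,
    healthy_label="HC",
    family_ids=None,
    alpha: float = 0.05,
) -> ComparisonTable:
    """Compare every bio-factor across groups.

    Runs one-way (or family-adjusted, when ``family_ids`` is given) ANOVA
    per factor, Holm-Bonferroni across factors, Tukey pairwise tests with an
    equivalence-class ordering, and Glass delta of each group against the
    healthy group.
    """
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    rows = []
    pairwise = {}
    for factor in scores.columns:
        y = scores[factor].to_numpy(dtype=float)
        if family_ids is not None:
            F, dfb, dfe, p = family_adjusted_anova(y, groups, family_ids)
        else:
            F, dfb, dfe, p = anova_oneway(y, groups)
        pw = tukey_posthoc(y, groups, alpha=alpha)
        pairwise[factor] = pw
        row = dict(factor=factor, F=F, df_between=dfb, df_error=dfe, p=p,
                   pattern=equivalence_classes(y, groups, pw))
        if healthy_label in levels:
            hy = y[groups == healthy_label]
            for g in levels:
                if g == healthy_label:
                    continue
                gy = y[groups == g]
                row[f"glass_delta_{g}"] = glass_delta(
                    gy.mean(), hy.mean(), hy.std(ddof=1)
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["holm_reject"] = holm_bonferroni(table["p"].to_numpy(), alpha=alpha)
    return ComparisonTable(table=table, pairwise=pairwise, alpha=alpha)
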