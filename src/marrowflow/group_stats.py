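"""Nonparametric comparison of per-sample statistics across groups.

The study design is K = 6 groups with n = 3 samples each, far too small for
normality assumptions, hence Kruskal-Wallis on ranks followed by Dunn's
pairwise z tests on the pooled ranks with Bonferroni adjustment.  With n = 3
per group the chi-square approximation is crude; results carry a small-sample
caveat and an exact permutation p-value is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTable",
    "kruskal_wallis",
    "kruskal_wallis_permutation",
    "posthoc_pairwise",
    "descriptives",
    "SMALL_SAMPLE_CAVEAT",
    "P_SIGNIFICANT",
]

P_SIGNIFICANT = 0.05
SMALL_SAMPLE_CAVEAT = (
    "chi-square approximation with <5 samples per group is approximate; "
    "consider the permutation p-value"
)


@dataclass
class GroupTable:
    """Long-format per-sample statistics: (group, sample_id, value) rows."""

    data: pd.DataFrame
    statistic: str = "mean_surface_fss_pa"

    def __post_init__(self) -> None:
        required = {"group", "sample_id", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if self.data["group"].nunique() < 2:
            raise ValueError("need at least 2 groups")

    @classmethod
    def from_rows(cls, rows, statistic: str = "mean_surface_fss_pa") -> "GroupTable":
        df = pd.DataFrame(rows, columns=["group", "sample_id", "value"])
        return cls(df, statistic)

    def groups(self) -> list:
        return list(dict.fromkeys(self.data["group"]))

    def values_by_group(self) -> dict:
        return {g: self.data.loc[self.data["group"] == g, "value"].to_numpy()
                for g in self.groups()}


def kruskal_wallis(table: GroupTable) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (K-1 df).

    Identical values across all samples give the degenerate H = 0, p = 1.
    """
    groups = list(table.values_by_group().values())
    if sum(len(g) for g in groups) < 5:
        raise ValueError("need a total of at least 5 samples")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_permutation(table: GroupTable, n_perm: int = 20000,
                               seed: int = 0) -> float:
    """Permutation p-value for the KW statistic (small-sample option)."""
    vals = table.data["value"].to_numpy()
    labels = table.data["group"].to_numpy()
    groups = table.groups()
    sizes = [int((labels == g).sum()) for g in groups]
    obs = _h_statistic(vals, labels, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        splits = np.split(perm, np.cumsum(sizes)[:-1])
        lab = np.repeat(np.arange(len(groups)), sizes)
        if _h_statistic(perm, lab, list(range(len(groups)))) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _h_statistic(vals, labels, groups) -> float:
    r = stats.rankdata(vals)
    n = len(vals)
    h = 12.0 / (n * (n + 1)) * sum(
        (r[labels == g].sum()) ** 2 / (labels == g).sum() for g in groups
    ) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def posthoc_pairwise(table: GroupTable, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, adjusted p-value matrix.

    Symmetric with unit diagonal; a group with fewer than 2 samples has its
    comparisons flagged as NaN (not computed).
    """
    by = table.values_by_group()
    groups = list(by)
    vals = np.concatenate(list(by.values()))
    n = len(vals)
    ranks = stats.rankdata(vals)
    offsets = np.cumsum([0] + [len(v) for v in by.values()])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(groups)}
    _, counts = np.unique(vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    k = len(groups)
    n_comp = k * (k - 1) // 2
    P = pd.DataFrame(np.eye(k), index=groups, columns=groups)
    for g1, g2 in itertools.combinations(groups, 2):
        n1, n2 = len(by[g1]), len(by[g2])
        if n1 < 2 or n2 < 2:
            P.loc[g1, g2] = P.loc[g2, g1] = np.nan
            continue
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            praw = 1.0
        else:
            z = (mean_rank[g1] - mean_rank[g2]) / se
            praw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            padj = min(1.0, praw * n_comp)
        elif adjust == "none":
            padj = praw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        P.loc[g1, g2] = P.loc[g2, g1] = padj
    return P


def descriptives(table: GroupTable) -> pd.DataFrame:
    """Per-group median and quartiles (linear-interpolation quantiles)."""
    rows = []
    for g, v in table.values_by_group().items():
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        rows.append({"group": g, "n": len(v), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows).set_index("group")
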