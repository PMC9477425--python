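"""Group comparisons of redundancy/synergy across interaction orders.

Per interaction order, the per-run grand averages of two groups are compared
with a two-sided Wilcoxon rank-sum test; p-values are corrected across the
orders of one measure with the Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hoi import OInfoTable

__all__ = ["GroupComparison", "wilcoxon_rank_sum", "bh_fdr", "compare_groups_by_order"]

#: pooled-size cutoff below which the exact permutation distribution is enumerated
_EXACT_POOLED = 12


@dataclass
class GroupComparison:
    """Per-order rank-sum results for one measure (redundancy or synergy)."""

    table: pd.DataFrame  # columns: order, rs, p, p_fdr, significant
    measure: str
    n_a: int
    n_b: int
    alpha: float

    def significant_orders(self) -> list[int]:
        return self.table.loc[self.table["significant"], "order"].tolist()


def wilcoxon_rank_sum(a, b) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum test; rs = sum of pooled ranks of sample ``a``.

    Ties receive average ranks. For pooled sizes <= 12 the p-value is exact,
    from full enumeration of the C(n_a + n_b, n_a) group assignments of the
    pooled values (valid under ties); otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    rs = float(ranks[: a.size].sum())
    n, N = a.size, a.size + b.size
    if N <= _EXACT_POOLED:
        obs_dev = abs(rs - n * (N + 1) / 2.0)
        count = 0
        total = 0
        for idx in itertools.combinations(range(N), n):
            total += 1
            stat = ranks[list(idx)].sum()
            if abs(stat - n * (N + 1) / 2.0) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return {"rs": rs, "p": min(p, 1.0)}


def bh_fdr(pvals, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {"p_adj": p_adj, "reject": p_adj < alpha}


def _grand_average_samples(tables: list[OInfoTable], measure: str) -> dict[int, np.ndarray]:
    col = {"redundancy": "R", "synergy": "S", "omega": "omega"}[measure]
    samples: dict[int, list[float]] = {}
    for t in tables:
        ga = t.grand_averages()
        if col not in ga.columns:
            raise ValueError(f"tables lack {col}; run redundancy_synergy first")
        for order, val in zip(ga["order"], ga[col]):
            samples.setdefault(int(order), []).append(float(val))
    return {n: np.asarray(v) for n, v in samples.items()}


def compare_groups_by_order(
    tables_a: list[OInfoTable],
    tables_b: list[OInfoTable],
    measure: str = "redundancy",
    alpha: float = 0.05,
) -> GroupComparison:
    """Rank-sum test per order on per-run grand averages, BH-FDR across orders.

    The sampling unit is one simulation run (its grand-average redundancy or
    synergy at each order); the FDR family is the set of orders of the chosen
    measure.
    """
    sa = _grand_average_samples(tables_a, measure)
    sb = _grand_average_samples(tables_b, measure)
    if set(sa) != set(sb):
        raise ValueError(f"order ranges differ: {sorted(sa)} vs {sorted(sb)}")
    orders = sorted(sa)
    rows = []
    for n in orders:
        res = wilcoxon_rank_sum(sa[n], sb[n])
        rows.append({"order": n, "rs": res["rs"], "p": res["p"]})
    df = pd.DataFrame(rows)
    fdr = bh_fdr(df["p"].to_numpy(), alpha=alpha)
    df["p_fdr"] = fdr["p_adj"]
    df["significant"] = fdr["reject"]
    return GroupComparison(
        table=df,
        measure=measure,
        n_a=len(sa[orders[0]]),
        n_b=len(sb[orders[0]]),
        alpha=alpha,
    )
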