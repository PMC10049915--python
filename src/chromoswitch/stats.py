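"""Shared statistical primitives: Wilcoxon rank-sum, hypergeometric
enrichment tails, Benjamini-Hochberg adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_rank_sum", "hypergeom_sf", "bh_adjust"]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the pooled sample has at most 20 values and
    no ties; otherwise the normal approximation with continuity and tie
    corrections.  Degenerate input (all pooled values identical) returns 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for overlap k with
    population N, K marked, n drawn."""
    if not (0 <= k <= min(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
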