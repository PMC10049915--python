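"""ICE matrix balancing, distance-decay expected values, log2 observed/expected
maps, per-chromosome correlation maps and the two-condition quantile
subtraction map.

Balancing follows the iterative-correction scheme: under an equal-visibility
assumption each bin i carries a multiplicative weight b_i, and the balanced
matrix W_ij = M_ij * b_i * b_j has equal row sums on unmasked bins.  Bins with
anomalously low raw coverage are masked by a median/MAD rule before iteration
and excluded from every downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import BinTable, ContactMatrix

__all__ = [
    "BalanceWeights",
    "BalancedMatrix",
    "ice_balance",
    "expected_cis",
    "oe_log2",
    "correlation_map",
    "subtraction_quantile",
]


@dataclass
class BalanceWeights:
    weights: np.ndarray          # multiplicative per-bin weight; NaN on masked bins
    mask: np.ndarray             # True where the bin is masked (excluded)
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        ok = ~self.mask
        if not np.all(self.weights[ok] > 0):
            raise ValueError("weights must be positive on unmasked bins")


@dataclass
class BalancedMatrix:
    """Raw counts plus balancing weights; the balanced values are derived."""

    raw: ContactMatrix
    balance: BalanceWeights

    @property
    def bins(self) -> BinTable:
        return self.raw.bins

    def balanced_upper(self) -> sp.csr_matrix:
        w = np.where(self.balance.mask, 0.0, self.balance.weights)
        d = sp.diags(w)
        return d @ self.raw.upper @ d

    def dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense symmetric balanced cis block; masked rows/cols are NaN."""
        sl = self.bins.chrom_slice(chrom)
        block = self.balanced_upper()[sl, sl].toarray()
        block = block + block.T - np.diag(np.diag(block))
        m = self.balance.mask[sl]
        block[m, :] = np.nan
        block[:, m] = np.nan
        return block


def _coverage_mask(marginal: np.ndarray, mad_max: float) -> np.ndarray:
    """Mask zero-coverage bins and nonzero marginals below median - mad_max*MAD."""
    mask = marginal == 0
    nz = marginal[~mask]
    if len(nz) and mad_max > 0:
        med = np.median(nz)
        mad = np.median(np.abs(nz - med))
        mask |= marginal < med - mad_max * mad
    return mask


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_max: float = 3.0,
) -> BalancedMatrix:
    """Iteratively correct a symmetric count matrix to equal bin coverage.

    Each iteration divides the current weights by the (normalized) balanced
    marginals; convergence is declared when the maximum relative deviation of
    unmasked row sums from their mean drops below ``tol``.  After convergence
    weights are rescaled so unmasked balanced rows sum to 1.  Non-convergence
    returns the last iterate with ``converged=False`` and a warning.
    """
    sym = m.symmetric().tocsr()
    n = m.bins.n_bins
    marginal = np.asarray(sym.sum(axis=1)).ravel()
    mask = _coverage_mask(marginal, mad_max)

    keep = ~mask
    weights = np.ones(n)
    weights[mask] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = np.asarray(sym.multiply(weights[:, None]).multiply(weights[None, :]).sum(axis=1)).ravel()
        s_un = s[keep]
        if len(s_un) == 0 or s_un.mean() == 0:
            break
        rel = s_un / s_un.mean()
        dev = float(np.abs(rel - 1).max())
        if dev < tol:
            converged = True
            break
        upd = np.ones(n)
        upd[keep] = rel
        weights = weights / np.where(upd == 0, 1.0, upd)
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations", RuntimeWarning
        )
    # scale so unmasked balanced rows sum to 1
    s = np.asarray(sym.multiply(weights[:, None]).multiply(weights[None, :]).sum(axis=1)).ravel()
    mean_s = s[keep].mean() if keep.any() else 1.0
    if mean_s > 0:
        weights = weights / np.sqrt(mean_s)
    w_out = weights.astype(float)
    w_out[mask] = np.nan
    return BalancedMatrix(m, BalanceWeights(w_out, mask, converged, it))


# ---------------------------------------------------------------------------
# Expected profile and O/E
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Per-distance (in bins) expected balanced contact value.

    ``values[chrom][s]`` is the expected value at separation s; pooled mode
    stores the same array under every chromosome.
    """

    values: dict[str, np.ndarray]
    span: float
    pooled: bool

    def at(self, chrom: str, s: np.ndarray | int) -> np.ndarray:
        return self.values[chrom][s]


def _stratum_means(dense: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean balanced value per distance over unmasked pairs (zeros included)."""
    n = dense.shape[0]
    sums = np.zeros(n)
    cnts = np.zeros(n)
    for s in range(1, n):
        diag = np.diagonal(dense, offset=s)
        ok = np.isfinite(diag)
        sums[s] = np.nansum(diag)
        cnts[s] = ok.sum()
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    means[0] = np.nan
    return means, cnts


def _interpolate_gaps(log_s: np.ndarray, log_v: np.ndarray) -> np.ndarray:
    """Fill non-finite strata by linear interpolation in log-log space."""
    ok = np.isfinite(log_v)
    if ok.sum() == 0:
        return log_v
    return np.interp(log_s, log_s[ok], log_v[ok])


def expected_cis(
    bal: BalancedMatrix, span: float = 0.3, pooled: bool = False
) -> ExpectedProfile:
    """Distance-decay expected: raw per-distance means, lowess-smoothed in
    log-log space with fraction ``span``; ``span=0`` disables smoothing.

    Empty or zero strata are interpolated from neighbouring distances so the
    profile is strictly positive wherever any pair exists.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    per_chrom_means = {}
    pooled_sums = None
    pooled_cnts = None
    for chrom in bal.bins.chroms:
        dense = bal.dense_chrom(chrom)
        means, cnts = _stratum_means(dense)
        per_chrom_means[chrom] = (means, cnts)
        if pooled:
            size = bal.bins.n_bins
            if pooled_sums is None:
                pooled_sums = np.zeros(size)
                pooled_cnts = np.zeros(size)
            s_len = len(means)
            pooled_sums[:s_len] += np.nan_to_num(means) * cnts
            pooled_cnts[:s_len] += cnts

    def smooth(means: np.ndarray) -> np.ndarray:
        n = len(means)
        s = np.arange(n, dtype=float)
        out = np.full(n, np.nan)
        valid = np.flatnonzero((s >= 1) & (means > 0))
        if len(valid) == 0:
            return out
        ls, lv = np.log(s[valid]), np.log(means[valid])
        if span > 0 and len(valid) >= 5:
            sm = lowess(lv, ls, frac=span, return_sorted=False)
        else:
            sm = lv
        all_s = np.arange(1, n)
        out[1:] = np.exp(np.interp(np.log(all_s), ls, sm))
        return out

    values = {}
    if pooled:
        with np.errstate(invalid="ignore"):
            pm = np.where(pooled_cnts > 0, pooled_sums / np.maximum(pooled_cnts, 1), np.nan)
        prof = smooth(pm)
        for chrom in bal.bins.chroms:
            values[chrom] = prof
    else:
        for chrom in bal.bins.chroms:
            means, _ = per_chrom_means[chrom]
            values[chrom] = smooth(means)
    return ExpectedProfile(values, span, pooled)


@dataclass
class OEMatrix:
    """Cis observed/expected scores.

    The serialized score is log2(balanced / expected); pixels with zero
    observed are omitted from the sparse log2 map (never set to -inf).  For
    correlation/PC1 the linear ratio is used instead, with zero-observed
    pixels included as ratio 0 — at moderate depth most of the
    compartment signal sits in which pixels are empty, and dropping them
    destroys it.
    """

    bins: BinTable
    chrom_maps: dict[str, sp.csr_matrix]   # upper triangle of log2 OE per chrom
    chrom_present: dict[str, sp.csr_matrix]  # 1 where an OE value is defined
    mask: np.ndarray                       # per-bin masked flag (from balancing)

    def dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense symmetric log2 OE with NaN where undefined."""
        vals = self.chrom_maps[chrom].toarray()
        pres = self.chrom_present[chrom].toarray().astype(bool)
        vals = vals + vals.T - np.diag(np.diag(vals))
        pres = pres | pres.T
        out = np.where(pres, vals, np.nan)
        return out

    def ratio_dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense symmetric linear O/E ratio; zero-observed pixels are 0,
        masked rows/columns and the diagonal are NaN."""
        sl = self.bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        log2 = self.dense_chrom(chrom)
        out = np.where(np.isfinite(log2), np.exp2(log2), 0.0)
        np.fill_diagonal(out, np.nan)
        m = self.mask[sl]
        out[m, :] = np.nan
        out[:, m] = np.nan
        return out


def oe_log2(bal: BalancedMatrix, expected: ExpectedProfile) -> OEMatrix:
    """log2(balanced / expected(distance)) per cis pixel with nonzero observed."""
    maps = {}
    present = {}
    for chrom in bal.bins.chroms:
        sl = bal.bins.chrom_slice(chrom)
        block = bal.balanced_upper()[sl, sl].tocoo()
        n = sl.stop - sl.start
        s = block.col - block.row
        exp = expected.values[chrom]
        keep = (block.data > 0) & (s >= 1)
        e = exp[s[keep]]
        if np.any(~np.isfinite(e)) or np.any(e <= 0):
            raise ValueError(f"expected undefined at a needed distance on {chrom}")
        vals = np.log2(block.data[keep] / e)
        r, c = block.row[keep], block.col[keep]
        maps[chrom] = sp.coo_matrix((vals, (r, c)), shape=(n, n)).tocsr()
        present[chrom] = sp.coo_matrix(
            (np.ones(len(r)), (r, c)), shape=(n, n)
        ).tocsr()
    return OEMatrix(bal.bins, maps, present, bal.balance.mask.copy())


def correlation_map(oe: OEMatrix, chrom: str, min_periods: int = 3) -> np.ndarray:
    """Per-chromosome Pearson correlation of O/E bin profiles.

    corr(i, j) is the pairwise-complete Pearson correlation of the linear
    O/E column vectors of bins i and j (zero-observed pixels included as 0;
    masked bins and the diagonal excluded).  Diagonal forced to 1; rows for
    masked or zero-variance bins are NaN.
    """
    dense = oe.ratio_dense_chrom(chrom)
    n = dense.shape[0]
    if n < 3:
        raise ValueError("need >= 3 bins for a correlation map")
    df = pd.DataFrame(dense)
    corr = df.corr(min_periods=min_periods).to_numpy()
    valid = ~np.all(np.isnan(dense), axis=0)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    idx = np.flatnonzero(valid)
    corr[idx, idx] = 1.0
    return corr


def subtraction_quantile(
    bal_a: BalancedMatrix, bal_b: BalancedMatrix
) -> dict[str, np.ndarray]:
    """Per-pixel quantile difference map (condition A minus condition B).

    Each balanced cis matrix is rank-transformed to quantiles within its
    distance stratum (removing decay), then differenced pixel-wise; values lie
    in [-1, 1] and swapping the arguments negates the map exactly.
    """
    from scipy.stats import rankdata

    if bal_a.bins != bal_b.bins:
        raise ValueError("matrices must share one bin table")

    def quantile_map(bal: BalancedMatrix, chrom: str) -> np.ndarray:
        dense = bal.dense_chrom(chrom)
        n = dense.shape[0]
        out = np.full((n, n), np.nan)
        for s in range(1, n):
            diag = np.diagonal(dense, offset=s)
            ok = np.isfinite(diag)
            if ok.sum() == 0:
                continue
            q = np.full(len(diag), np.nan)
            q[ok] = (rankdata(diag[ok], method="average") - 0.5) / ok.sum()
            i = np.arange(len(diag))
            out[i, i + s] = q
            out[i + s, i] = q
        return out

    diff = {}
    for chrom in bal_a.bins.chroms:
        diff[chrom] = quantile_map(bal_a, chrom) - quantile_map(bal_b, chrom)
    return diff
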