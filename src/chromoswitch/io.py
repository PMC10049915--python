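"""Binned contact-matrix containers, HiC-Pro triplet I/O and whole-genome
interaction summaries.

The on-disk dialect is the HiC-Pro pair: a ``.matrix`` file of tab-separated
triplets ``bin_i  bin_j  count`` (1-based bin indices by convention, 0-based
supported via a flag) and a companion ``.bed`` of uniform bins
``chrom  start  end  index``.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BinTable",
    "ContactMatrix",
    "read_hicpro",
    "write_hicpro",
    "write_bedgraph",
    "cis_trans_fractions",
    "interchrom_counts",
    "distance_decay",
    "coarsen",
]


class MatrixFormatError(ValueError):
    """Raised for malformed triplet/bed input; carries the offending line number."""


@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bins with consecutive global 0-based indices.

    Bins are sorted by (chrom, start); every chromosome is tiled completely,
    the last bin of a chromosome may be short.
    """

    chroms: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    bin_size: int

    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: dict[str, int], bin_size: int) -> "BinTable":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        return cls(tuple(chrom_sizes), tuple(chrom_sizes.values()), int(bin_size))

    @property
    def n_bins_per_chrom(self) -> np.ndarray:
        return np.array(
            [-(-size // self.bin_size) for size in self.chrom_sizes], dtype=int
        )

    @property
    def offsets(self) -> np.ndarray:
        """Global index of the first bin of each chromosome, plus total."""
        return np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.offsets[-1])

    def chrom_slice(self, chrom: str) -> slice:
        k = self.chroms.index(chrom)
        off = self.offsets
        return slice(int(off[k]), int(off[k + 1]))

    def chrom_of_bins(self) -> np.ndarray:
        """Per-bin chromosome ordinal (int codes into ``self.chroms``)."""
        return np.repeat(np.arange(len(self.chroms)), self.n_bins_per_chrom)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        idx = 0
        for chrom, size in zip(self.chroms, self.chrom_sizes):
            for start in range(0, size, self.bin_size):
                rows.append((chrom, start, min(start + self.bin_size, size), idx))
                idx += 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index containing base-pair position ``pos`` (0-based)."""
        k = self.chroms.index(chrom)
        if not 0 <= pos < self.chrom_sizes[k]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.offsets[k]) + pos // self.bin_size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BinTable":
        df = df.sort_values("index").reset_index(drop=True)
        if not (df["index"].to_numpy() == np.arange(len(df))).all():
            raise ValueError("bin indices must be consecutive from 0")
        widths = (df["end"] - df["start"]).to_numpy()
        bin_size = int(widths.max()) if len(df) else 0
        chroms, sizes = [], []
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            if not (np.diff(starts) == bin_size).all():
                raise ValueError(f"non-uniform bins on {chrom}")
            chroms.append(chrom)
            sizes.append(int(grp["end"].max()))
        return cls(tuple(chroms), tuple(sizes), bin_size)


@dataclass
class ContactMatrix:
    """Genome-wide symmetric contact matrix stored as upper-triangle sparse CSR.

    ``matrix[i, j]`` for ``i <= j`` holds the (i, j) count; symmetry is implied.
    """

    bins: BinTable
    upper: sp.csr_matrix
    condition: str = ""

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.upper.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")

    @classmethod
    def from_triplets(
        cls,
        bins: BinTable,
        i: np.ndarray,
        j: np.ndarray,
        counts: np.ndarray,
        condition: str = "",
    ) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        n = bins.n_bins
        if len(lo) and (lo.min() < 0 or hi.max() >= n):
            raise MatrixFormatError("bin index out of range")
        m = sp.coo_matrix((counts, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        return cls(bins, m, condition)

    @property
    def total(self) -> float:
        return float(self.upper.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric sparse matrix (diagonal not double-counted)."""
        u = self.upper
        return u + u.T - sp.diags(u.diagonal())

    def dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense symmetric cis block for one chromosome."""
        sl = self.bins.chrom_slice(chrom)
        block = self.upper[sl, sl].toarray()
        return block + block.T - np.diag(np.diag(block))


def read_hicpro(
    matrix_path: str | Path,
    bed_path: str | Path,
    one_based: bool = True,
    condition: str = "",
) -> ContactMatrix:
    """Read a HiC-Pro sparse triplet ``.matrix`` with its companion bins ``.bed``.

    HiC-Pro writes 1-based bin indices; pass ``one_based=False`` for 0-based
    triplet files.  Malformed lines are rejected with their line number.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "index"],
        dtype={"chrom": str},
        comment="#",
    )
    if one_based and bed["index"].min() == 1:
        bed["index"] -= 1
    bins = BinTable.from_dataframe(bed)

    ii, jj, cc = [], [], []
    seen: set[tuple[int, int]] = set()
    offset = 1 if one_based else 0
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixFormatError(f"line {lineno}: expected 3 fields")
            try:
                i = int(parts[0]) - offset
                j = int(parts[1]) - offset
                c = float(parts[2])
            except ValueError as exc:
                raise MatrixFormatError(f"line {lineno}: non-numeric field") from exc
            if c < 0:
                raise MatrixFormatError(f"line {lineno}: negative count")
            if not (0 <= i < bins.n_bins and 0 <= j < bins.n_bins):
                raise MatrixFormatError(
                    f"line {lineno}: bin index ({parts[0]}, {parts[1]}) "
                    f"outside the {bins.n_bins}-bin table"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MatrixFormatError(f"line {lineno}: duplicate entry {key}")
            seen.add(key)
            ii.append(i)
            jj.append(j)
            cc.append(c)
    return ContactMatrix.from_triplets(
        bins, np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64),
        np.array(cc), condition=condition,
    )


def write_hicpro(
    m: ContactMatrix,
    matrix_path: str | Path,
    bed_path: str | Path | None = None,
    one_based: bool = True,
    header: str | None = None,
) -> None:
    """Write upper-triangle triplets (and optionally the bins bed)."""
    from .util import atomic_write

    coo = m.upper.tocoo()
    order = np.lexsort((coo.col, coo.row))
    offset = 1 if one_based else 0
    with atomic_write(matrix_path) as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, j, c in zip(coo.row[order], coo.col[order], coo.data[order]):
            c = int(c) if float(c).is_integer() else c
            fh.write(f"{i + offset}\t{j + offset}\t{c}\n")
    if bed_path is not None:
        df = m.bins.to_dataframe()
        if one_based:
            df = df.assign(index=df["index"] + 1)
        with atomic_write(bed_path) as fh:
            df.to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(bins: BinTable, values: np.ndarray, path: str | Path) -> None:
    """Write any per-bin track as bedGraph; NaN bins are skipped."""
    from .util import atomic_write

    df = bins.to_dataframe()
    vals = np.asarray(values, dtype=float)
    keep = np.isfinite(vals)
    with atomic_write(path) as fh:
        for (_, row), v in zip(df[keep].iterrows(), vals[keep]):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Whole-genome interaction summaries
# ---------------------------------------------------------------------------

def _cis_trans_masks(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coo = m.upper.tocoo()
    chrom_codes = m.bins.chrom_of_bins()
    return coo.row, coo.col, chrom_codes[coo.row] == chrom_codes[coo.col]


def cis_trans_fractions(m: ContactMatrix) -> dict:
    """Genome-wide and per-chromosome cis fraction of total contacts.

    A trans contact is attributed to both of its chromosomes, so each
    chromosome's denominator counts every contact touching it.
    """
    row, col, is_cis = _cis_trans_masks(m)
    data = m.upper.tocoo().data
    cis_sum = float(data[is_cis].sum())
    trans_sum = float(data[~is_cis].sum())
    total = cis_sum + trans_sum
    if total == 0:
        raise ValueError("all-zero matrix: cis fraction undefined")

    chrom_codes = m.bins.chrom_of_bins()
    per_chrom = {}
    for k, chrom in enumerate(m.bins.chroms):
        touches = (chrom_codes[row] == k) | (chrom_codes[col] == k)
        c = float(data[touches & is_cis].sum())
        t = float(data[touches & ~is_cis].sum())
        per_chrom[chrom] = c / (c + t) if c + t > 0 else float("nan")
    return {
        "cis_sum": cis_sum,
        "trans_sum": trans_sum,
        "cis_fraction": cis_sum / total,
        "per_chrom_cis_fraction": per_chrom,
    }


def interchrom_counts(m: ContactMatrix, normalized: bool = False) -> pd.DataFrame:
    """Symmetric chromosome-pair table of trans contact sums.

    With ``normalized=True`` each entry is divided by n_bins_A * n_bins_B.
    """
    if len(m.bins.chroms) < 2:
        raise ValueError("need at least 2 chromosomes for trans counts")
    row, col, is_cis = _cis_trans_masks(m)
    data = m.upper.tocoo().data
    chrom_codes = m.bins.chrom_of_bins()
    k = len(m.bins.chroms)
    table = np.zeros((k, k))
    a = chrom_codes[row[~is_cis]]
    b = chrom_codes[col[~is_cis]]
    np.add.at(table, (a, b), data[~is_cis])
    np.add.at(table, (b, a), data[~is_cis])
    if normalized:
        nb = m.bins.n_bins_per_chrom.astype(float)
        table = table / np.outer(nb, nb)
    return pd.DataFrame(table, index=m.bins.chroms, columns=m.bins.chroms)


def distance_decay(
    m: ContactMatrix,
    fit_min_bins: int = 2,
    fit_max_bp: int = 2_000_000,
) -> dict:
    """Contact-frequency decay P(s) and its log-log power-law exponent.

    P(s) is the mean count per bin pair at separation s (in bins), pooled over
    chromosomes with zero pairs included in the denominator.  The exponent is
    the least-squares slope of log10 P(s) on log10 s over
    ``fit_min_bins <= s <= fit_max_bp / bin_size``; empty (all-zero) strata
    are excluded from the fit.
    """
    nb = m.bins.n_bins_per_chrom
    max_s = int(nb.max()) - 1
    if max_s < 1:
        raise ValueError("no cis distance strata")
    sums = np.zeros(max_s + 1)
    npairs = np.zeros(max_s + 1)
    for chrom in m.bins.chroms:
        sl = m.bins.chrom_slice(chrom)
        block = m.upper[sl, sl].tocoo()
        s = block.col - block.row
        np.add.at(sums, s, block.data)
        n = sl.stop - sl.start
        d = np.arange(n)
        npairs[: n] += n - d
    with np.errstate(invalid="ignore"):
        ps = sums / npairs
    s_vals = np.arange(1, max_s + 1)
    ps = ps[1:]

    fit_max_bins = max(fit_min_bins, fit_max_bp // m.bins.bin_size)
    in_range = (s_vals >= fit_min_bins) & (s_vals <= fit_max_bins) & (ps > 0)
    if in_range.sum() < 3:
        raise ValueError("fewer than 3 nonzero strata in the fit range")
    slope, intercept = np.polyfit(np.log10(s_vals[in_range]), np.log10(ps[in_range]), 1)
    return {
        "s_bins": s_vals,
        "p_s": ps,
        "exponent": float(slope),
        "intercept": float(intercept),
        "fit_range_bins": (int(fit_min_bins), int(fit_max_bins)),
    }


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate a matrix to ``factor``-fold coarser bins (counts summed)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return m
    coarse = BinTable(
        m.bins.chroms, m.bins.chrom_sizes, m.bins.bin_size * factor
    )
    fine_chrom = m.bins.chrom_of_bins()
    fine_local = np.arange(m.bins.n_bins) - m.bins.offsets[fine_chrom]
    mapping = coarse.offsets[fine_chrom] + fine_local // factor
    coo = m.upper.tocoo()
    return ContactMatrix.from_triplets(
        coarse, mapping[coo.row], mapping[coo.col], coo.data, condition=m.condition
    )
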