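"""Bin tables, sparse contact matrices, balancing and O/E transforms.

Contact data are held as a uniform bin table (chrom, start, end, bin_id;
0-based half-open) plus upper-triangle triplets ``(bin_i, bin_j, value)``,
the plain-text dialect produced by HiC-Pro's ``abs.bed`` / ``.matrix``
pair.  All downstream modules consume only :class:`ContactMatrix`,
:class:`BinTable` and :class:`ExpectedProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "BinTable",
    "ContactMatrix",
    "ExpectedProfile",
    "BalanceError",
    "read_contacts",
    "write_contacts",
    "write_bedgraph",
    "balance",
    "observed_expected",
    "coarsen",
]


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BalanceError(RuntimeError):
    """Raised when iterative correction fails to converge.

    Carries the last maximum relative marginal deviation in
    ``last_deviation`` for diagnostics.
    """

    def __init__(self, message: str, last_deviation: float):
        super().__init__(message)
        self.last_deviation = last_deviation


@dataclass
class BinTable:
    """Uniform genome binning.

    ``table`` holds one row per bin with columns ``chrom``, ``start``,
    ``end`` (0-based half-open) and ``bin_id`` (dense ``0..N-1`` over the
    whole genome, in genome order).  Every bin has length ``resolution``
    except possibly the last bin of each chromosome.
    """

    table: pd.DataFrame
    resolution: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "bin_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"bin table needs columns {sorted(required)}")
        t = self.table.reset_index(drop=True)
        if not np.array_equal(t["bin_id"].to_numpy(), np.arange(len(t))):
            raise ValueError("bin_id must be dense 0..N-1 in table order")
        for _, sub in t.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError("bins within a chromosome must be contiguous")
            lengths = ends - starts
            if np.any(lengths[:-1] != self.resolution):
                raise ValueError("all bins but the last must span one resolution")
            if lengths[-1] > self.resolution or lengths[-1] <= 0:
                raise ValueError("trailing bin has invalid length")
        object.__setattr__(self, "table", t)

    @classmethod
    def from_chrom_sizes(
        cls, chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]], resolution: int
    ) -> "BinTable":
        items = chrom_sizes.items() if isinstance(chrom_sizes, Mapping) else chrom_sizes
        rows = []
        for chrom, size in items:
            starts = np.arange(0, size, resolution)
            ends = np.minimum(starts + resolution, size)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["bin_id"] = np.arange(len(table))
        return cls(table, resolution)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.table.groupby("chrom", sort=False)["end"].max())

    def bins_in(self, region: Region) -> np.ndarray:
        """bin_ids of bins overlapping ``region``, in genome order."""
        t = self.table
        hit = (
            (t["chrom"] == region.chrom)
            & (t["start"] < region.end)
            & (t["end"] > region.start)
        )
        return t.loc[hit, "bin_id"].to_numpy()

    def same_table(self, other: "BinTable") -> bool:
        return self.resolution == other.resolution and self.table[
            ["chrom", "start", "end"]
        ].equals(other.table[["chrom", "start", "end"]])


@dataclass
class ContactMatrix:
    """Symmetric contact matrix stored as upper-triangle triplets.

    ``bin1 <= bin2`` for every triplet; values are non-negative.  After
    balancing, ``weights`` records the per-bin correction factor (NaN for
    masked bins) and masked bins carry no triplets.
    """

    bins: BinTable
    bin1: np.ndarray
    bin2: np.ndarray
    value: np.ndarray
    normalization: str = "raw"  # {"raw", "balanced"}
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if not (len(self.bin1) == len(self.bin2) == len(self.value)):
            raise ValueError("triplet arrays must have equal length")
        n = self.bins.n_bins
        if len(self.bin1) and (
            self.bin1.min() < 0 or self.bin2.max() >= n or self.bin1.max() >= n
        ):
            raise ValueError("triplet bin id outside bin table")
        if np.any(self.bin1 > self.bin2):
            raise ValueError("triplets must satisfy bin1 <= bin2")
        if np.any(self.value < 0):
            raise ValueError("contact values must be non-negative")
        if self.normalization not in ("raw", "balanced"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean vector of bins that carry balancing weights (or all, if raw)."""
        if self.weights is None:
            return np.ones(self.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def total(self) -> float:
        """Genome-wide total signal (each off-diagonal pair counted once)."""
        return float(self.value.sum())

    def marginals(self) -> np.ndarray:
        """Per-bin row sums of the full symmetric matrix."""
        m = np.zeros(self.n_bins)
        np.add.at(m, self.bin1, self.value)
        off = self.bin1 != self.bin2
        np.add.at(m, self.bin2[off], self.value[off])
        return m

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (use on small instances only)."""
        n = self.n_bins
        d = np.zeros((n, n))
        d[self.bin1, self.bin2] = self.value
        d[self.bin2, self.bin1] = self.value
        return d

    def submatrix(self, bin_ids: np.ndarray) -> np.ndarray:
        """Dense symmetric submatrix over the given (sorted) bin ids."""
        pos = {b: k for k, b in enumerate(bin_ids)}
        keep = np.isin(self.bin1, bin_ids) & np.isin(self.bin2, bin_ids)
        i = np.array([pos[b] for b in self.bin1[keep]], dtype=np.int64)
        j = np.array([pos[b] for b in self.bin2[keep]], dtype=np.int64)
        m = np.zeros((len(bin_ids), len(bin_ids)))
        m[i, j] = self.value[keep]
        m[j, i] = self.value[keep]
        return m

    def cis_mask(self) -> np.ndarray:
        c = self.bins.chroms
        return c[self.bin1] == c[self.bin2]

    def with_values(self, value: np.ndarray, **kwargs) -> "ContactMatrix":
        out = replace(self, value=np.asarray(value, dtype=np.float64), **kwargs)
        return out


@dataclass
class ExpectedProfile:
    """Mean contact per genomic separation within one chromosome arm.

    One entry per diagonal; ``values`` is NaN where a separation has no
    valid (unmasked) pairs — missing shells are flagged, never zero-filled.
    """

    arm: Region
    separations: np.ndarray  # bp, strictly increasing
    values: np.ndarray  # mean contact, NaN = missing
    n_pairs: np.ndarray  # valid pairs per separation

    def __post_init__(self) -> None:
        if np.any(np.diff(self.separations) <= 0):
            raise ValueError("separations must be strictly increasing")


# ---------------------------------------------------------------------------
# I/O


def read_contacts(bins_path: str | Path, triplets_path: str | Path) -> ContactMatrix:
    """Read a HiC-Pro style bin table (BED3+bin_id) and triplet matrix.

    Lower-triangle entries are folded onto the upper triangle; duplicate
    pairs are summed.  Unknown bin ids and negative values raise
    ``ValueError``.
    """
    bins_df = pd.read_csv(
        bins_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "bin_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "bin_id": np.int64},
        comment="#",
    )
    lengths = bins_df["end"] - bins_df["start"]
    resolution = int(lengths.max())
    bins = BinTable(bins_df, resolution)

    trip = pd.read_csv(
        triplets_path,
        sep=r"\s+",
        header=None,
        names=["bin1", "bin2", "value"],
        comment="#",
    )
    i = trip["bin1"].to_numpy(dtype=np.int64)
    j = trip["bin2"].to_numpy(dtype=np.int64)
    v = trip["value"].to_numpy(dtype=np.float64)
    n = bins.n_bins
    if len(i) and (min(i.min(), j.min()) < 0 or max(i.max(), j.max()) >= n):
        raise ValueError("triplet references a bin id outside the bin table")
    if np.any(v < 0):
        raise ValueError("negative contact value in triplet file")
    # fold to upper triangle and sum duplicates
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    key = lo * n + hi
    order = np.argsort(key, kind="stable")
    key, lo, hi, v = key[order], lo[order], hi[order], v[order]
    uniq, inverse = np.unique(key, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, v)
    ui = (uniq // n).astype(np.int64)
    uj = (uniq % n).astype(np.int64)
    return ContactMatrix(bins, ui, uj, summed, normalization="raw")


def write_contacts(
    matrix: ContactMatrix, bins_path: str | Path, triplets_path: str | Path
) -> None:
    """Write the bin table and upper-triangle triplets as tab-separated text."""
    matrix.bins.table[["chrom", "start", "end", "bin_id"]].to_csv(
        bins_path, sep="\t", header=False, index=False
    )
    out = pd.DataFrame(
        {"bin1": matrix.bin1, "bin2": matrix.bin2, "value": matrix.value}
    )
    out.to_csv(triplets_path, sep="\t", header=False, index=False, float_format="%.17g")


def write_bedgraph(
    bins: BinTable, values: np.ndarray, path: str | Path, *, name: str | None = None
) -> None:
    """Write a per-bin track as bedGraph, skipping NaN bins."""
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    df = bins.table.loc[keep, ["chrom", "start", "end"]].copy()
    df["value"] = values[keep]
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Balancing (iterative correction)


def balance(
    matrix: ContactMatrix,
    tol: float = 1e-7,
    max_iter: int = 3000,
    sparsity_floor: float = 0.02,
) -> ContactMatrix:
    """Iterative-correction balancing to equal per-bin marginals.

    Bins whose nonzero-pair count is below ``sparsity_floor`` times the
    densest bin's count (or whose raw marginal is zero) are masked before
    correction and carry no triplets afterwards.  After convergence every
    unmasked bin's genome-wide marginal equals the common mean within
    ``tol`` (relative).  ``weights`` records per-bin factors such that
    ``balanced = raw * w_i * w_j``.

    Raises
    ------
    BalanceError
        if the maximum relative marginal deviation is still above ``tol``
        after ``max_iter`` sweeps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = matrix.n_bins
    nnz = np.zeros(n)
    np.add.at(nnz, matrix.bin1, (matrix.value > 0).astype(float))
    off = matrix.bin1 != matrix.bin2
    np.add.at(nnz, matrix.bin2[off], (matrix.value[off] > 0).astype(float))
    marg = matrix.marginals()
    mask = (marg <= 0) | (nnz < sparsity_floor * nnz.max() if nnz.max() > 0 else True)

    keep = ~mask[matrix.bin1] & ~mask[matrix.bin2]
    i, j, v = matrix.bin1[keep], matrix.bin2[keep], matrix.value[keep].copy()
    weights = np.ones(n)

    deviation = np.inf
    off_diag = i != j
    for _ in range(max_iter):
        m = np.bincount(i, weights=v, minlength=n)
        m += np.bincount(j[off_diag], weights=v[off_diag], minlength=n)
        live = ~mask & (m > 0)
        if not live.any():
            break
        target = m[live].mean()
        deviation = float(np.abs(m[live] / target - 1).max())
        if deviation < tol:
            break
        b = np.ones(n)
        b[live] = m[live] / target
        v = v / (b[i] * b[j])
        weights = weights / b
    else:
        raise BalanceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(last max marginal deviation {deviation:.3g})",
            deviation,
        )

    weights_out = weights.copy()
    weights_out[mask] = np.nan
    nonzero = v > 0
    return ContactMatrix(
        matrix.bins,
        i[nonzero],
        j[nonzero],
        v[nonzero],
        normalization="balanced",
        weights=weights_out,
    )


# ---------------------------------------------------------------------------
# Observed / expected


def observed_expected(
    matrix: ContactMatrix, arm: Region
) -> tuple[ContactMatrix, ExpectedProfile]:
    """Divide cis entries within ``arm`` by their per-diagonal mean.

    The expected value of a diagonal is the mean over all unmasked bin
    pairs at that separation (zeros included); diagonals with no valid
    pairs or no signal are flagged missing (NaN), never zero-filled.
    Returns the O/E matrix restricted to the arm plus the expected
    profile.
    """
    arm_bins = matrix.bins.bins_in(arm)
    if len(arm_bins) == 0:
        raise ValueError(f"arm {arm} outside bin table")
    unmasked = matrix.unmasked
    in_arm = np.zeros(matrix.n_bins, dtype=bool)
    in_arm[arm_bins] = True
    lo, hi = arm_bins.min(), arm_bins.max()
    n_arm = hi - lo + 1
    res = matrix.bins.resolution

    # valid pair count per diagonal, zeros included
    good = unmasked[arm_bins].astype(np.int64)
    offsets = arm_bins - lo
    indicator = np.zeros(n_arm, dtype=np.int64)
    indicator[offsets] = good
    # pairs at diagonal d with both ends unmasked: correlate indicator with itself
    n_valid = np.array(
        [int(np.dot(indicator[: n_arm - d], indicator[d:])) for d in range(n_arm)]
    )

    keep = in_arm[matrix.bin1] & in_arm[matrix.bin2]
    i, j, v = matrix.bin1[keep], matrix.bin2[keep], matrix.value[keep]
    d = j - i
    sums = np.zeros(n_arm)
    np.add.at(sums, d, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    expected[(n_valid > 0) & (sums == 0)] = np.nan  # empty diagonal: missing

    oe_vals = v / expected[d]
    finite = np.isfinite(oe_vals)
    oe = ContactMatrix(
        matrix.bins,
        i[finite],
        j[finite],
        oe_vals[finite],
        normalization=matrix.normalization,
        weights=matrix.weights,
    )
    profile = ExpectedProfile(
        arm=arm,
        separations=np.arange(n_arm, dtype=np.int64) * res,
        values=expected,
        n_pairs=n_valid,
    )
    return oe, profile


# ---------------------------------------------------------------------------
# Coarsening


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate to ``resolution * factor`` by summing values.

    Total genome-wide signal is conserved exactly for raw matrices.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(matrix)
    bins = matrix.bins
    new_res = bins.resolution * factor
    new_bins = BinTable.from_chrom_sizes(bins.chrom_sizes(), new_res)
    # map old bin -> new bin by chromosome-local coordinate
    lookup: dict[tuple[str, int], int] = {
        (row.chrom, row.start): row.bin_id for row in new_bins.table.itertuples()
    }
    old = bins.table
    mapping = np.array(
        [
            lookup[(c, (s // new_res) * new_res)]
            for c, s in zip(old["chrom"], old["start"])
        ],
        dtype=np.int64,
    )
    i = mapping[matrix.bin1]
    j = mapping[matrix.bin2]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    n = new_bins.n_bins
    key = lo * n + hi
    uniq, inverse = np.unique(key, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, matrix.value)
    return ContactMatrix(
        new_bins,
        (uniq // n).astype(np.int64),
        (uniq % n).astype(np.int64),
        summed,
        normalization=matrix.normalization,
    )
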