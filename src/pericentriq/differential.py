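"""Differential maps, insulation TAD boundaries, and virtual 4C.

The boundary-change taxonomy (Same / Shift / Lost / Gained / Split /
Merge) classifies how TAD boundaries move between a control and a
knockdown condition; virtual 4C profiles quantify interactions from a
multi-bin anchor (e.g. a pericentric compartment) to every bin, with
randomly placed size-matched control anchors for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from pericentriq.hic_io import BinTable, ContactMatrix, Region

__all__ = [
    "DifferentialMap",
    "TadBoundarySet",
    "BoundaryComparison",
    "Virtual4CProfile",
    "differential_map",
    "insulation_boundaries",
    "classify_boundaries",
    "virtual_4c",
    "size_matched_controls",
    "v4c_difference",
]


@dataclass
class DifferentialMap:
    """Per-pair log2(kd/control) of depth-matched values.

    Swapping the two conditions flips the sign of every entry.
    """

    bins: BinTable
    bin1: np.ndarray
    bin2: np.ndarray
    value: np.ndarray  # log2 ratios, may be negative
    pseudocount: float


@dataclass
class TadBoundarySet:
    """Insulation-minimum boundaries and the domains they delimit.

    ``boundaries``: columns chrom, pos (bp, bin-edge aligned), depth
    (insulation-dip prominence in log2 units).
    ``domains``: columns chrom, start, end, size — the partition of each
    chromosome induced by its boundaries (terminal segments included).
    """

    boundaries: pd.DataFrame
    domains: pd.DataFrame
    window: int

    def __len__(self) -> int:
        return len(self.boundaries)


@dataclass
class BoundaryComparison:
    """Classified control-to-KD boundary matching.

    ``matches`` has one row per matched (ctrl, kd) boundary pair with its
    shift distance and category; ``counts`` covers Same, Shift,
    Unclassified (shift in the 10-15kb gap), Far (matched beyond the
    shift window -> counted Lost+Gained), Lost, Gained, Split, Merge.
    Every control and KD boundary lands in exactly one category.
    """

    matches: pd.DataFrame
    counts: dict[str, int]
    same_tol: int
    shift_min: int
    shift_max: int


@dataclass
class Virtual4CProfile:
    """Mean anchor-to-bin interaction score per target bin."""

    bins: BinTable
    target_bin_ids: np.ndarray
    values: np.ndarray  # NaN for masked bins
    anchor_flag: np.ndarray  # True where the target bin lies in the anchor
    condition: str = ""


# ---------------------------------------------------------------------------
# differential map


def differential_map(
    kd: ContactMatrix, ctrl: ContactMatrix, pseudocount: float | None = None
) -> DifferentialMap:
    """log2((kd + p) / (ctrl + p)) over the union of stored pairs.

    Both inputs are first scaled to equal total signal so the map
    reflects redistribution, not depth.  The default pseudocount is
    1e-3 times the scaled control mean.
    """
    if not kd.bins.same_table(ctrl.bins):
        raise ValueError("matrices must share a bin table")
    n = kd.n_bins
    scale = ctrl.total() / kd.total()
    key_kd = kd.bin1 * n + kd.bin2
    key_ct = ctrl.bin1 * n + ctrl.bin2
    keys = np.union1d(key_kd, key_ct)
    vk = np.zeros(len(keys))
    vc = np.zeros(len(keys))
    vk[np.searchsorted(keys, key_kd)] = kd.value * scale
    vc[np.searchsorted(keys, key_ct)] = ctrl.value
    if pseudocount is None:
        pseudocount = 1e-3 * vc.mean()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    value = np.log2((vk + pseudocount) / (vc + pseudocount))
    return DifferentialMap(
        bins=kd.bins,
        bin1=(keys // n).astype(np.int64),
        bin2=(keys % n).astype(np.int64),
        value=value,
        pseudocount=float(pseudocount),
    )


# ---------------------------------------------------------------------------
# insulation boundaries


def insulation_boundaries(
    matrix: ContactMatrix, window: int = 100_000, prominence: float = 0.1
) -> TadBoundarySet:
    """Diamond insulation-score minima as TAD boundaries.

    For each bin the insulation score is the mean contact in the
    ``w x w`` diamond just up/downstream (w = window in bins); local
    minima of the log2 normalized score with at least ``prominence``
    depth become boundaries. Domains are the induced partition of each
    chromosome, terminal segments included.
    """
    res = matrix.bins.resolution
    w = int(window // res)
    if w < 3:
        raise ValueError("window must span at least 3 bins")
    brows = []
    drows = []
    sizes = matrix.bins.chrom_sizes()
    for chrom, size in sizes.items():
        ids = matrix.bins.bins_in(Region(chrom, 0, int(size)))
        dense = matrix.submatrix(ids)
        n = len(ids)
        if n < 2 * w + 1:
            continue
        score = np.full(n, np.nan)
        for i in range(w, n - w):
            score[i] = dense[i - w : i, i + 1 : i + w + 1].mean()
        ok = np.isfinite(score) & (score > 0)
        if ok.sum() < 3:
            continue
        log_score = np.full(n, np.nan)
        log_score[ok] = np.log2(score[ok] / score[ok].mean())
        starts = matrix.bins.starts[ids]
        positions = []
        # find minima within each contiguous stretch of defined scores
        finite = np.isfinite(log_score)
        edges_idx = np.flatnonzero(np.diff(finite.astype(int)))
        segs = np.split(np.arange(n), edges_idx + 1)
        for seg in segs:
            if len(seg) < 3 or not finite[seg[0]]:
                continue
            peaks, props = find_peaks(-log_score[seg], prominence=prominence)
            for p, prom in zip(peaks, props["prominences"]):
                pos = int(starts[seg[p]])
                positions.append(pos)
                brows.append((chrom, pos, float(prom)))
        edges = [0] + positions + [int(size)]
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                drows.append((chrom, a, b, b - a))
    boundaries = pd.DataFrame(brows, columns=["chrom", "pos", "depth"])
    domains = pd.DataFrame(drows, columns=["chrom", "start", "end", "size"])
    return TadBoundarySet(boundaries=boundaries, domains=domains, window=window)


def classify_boundaries(
    ctrl: TadBoundarySet,
    kd: TadBoundarySet,
    same_tol: int = 10_000,
    shift_min: int = 15_000,
    shift_max: int = 70_000,
) -> BoundaryComparison:
    """Greedy one-to-one nearest matching of control to KD boundaries.

    Matched at <= ``same_tol`` -> Same; within [shift_min, shift_max] ->
    Shift; in the open gap between -> Unclassified; beyond shift_max a
    pair is not matched, so those boundaries count as Lost / Gained.
    Split: a control domain wholly containing >= 2 KD domains; Merge:
    >= 2 whole control domains inside one KD domain.
    """
    match_rows = []
    counts = {k: 0 for k in ("Same", "Shift", "Unclassified", "Lost", "Gained")}
    chroms = set(ctrl.boundaries["chrom"]) | set(kd.boundaries["chrom"])
    for chrom in sorted(chroms):
        c_pos = ctrl.boundaries.loc[ctrl.boundaries["chrom"] == chrom, "pos"].to_numpy()
        k_pos = kd.boundaries.loc[kd.boundaries["chrom"] == chrom, "pos"].to_numpy()
        if len(c_pos) and len(k_pos):
            dist = np.abs(c_pos[:, None] - k_pos[None, :])
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
            used_c = np.zeros(len(c_pos), dtype=bool)
            used_k = np.zeros(len(k_pos), dtype=bool)
            for ci, ki in order:
                d = dist[ci, ki]
                if d > shift_max:
                    break
                if used_c[ci] or used_k[ki]:
                    continue
                used_c[ci] = used_k[ki] = True
                if d <= same_tol:
                    cat = "Same"
                elif d >= shift_min:
                    cat = "Shift"
                else:
                    cat = "Unclassified"
                counts[cat] += 1
                match_rows.append((chrom, int(c_pos[ci]), int(k_pos[ki]), int(d), cat))
        else:
            used_c = np.zeros(len(c_pos), dtype=bool)
            used_k = np.zeros(len(k_pos), dtype=bool)
        counts["Lost"] += int((~used_c).sum())
        counts["Gained"] += int((~used_k).sum())

    counts["Split"] = _count_containments(ctrl.domains, kd.domains)
    counts["Merge"] = _count_containments(kd.domains, ctrl.domains)
    matches = pd.DataFrame(
        match_rows, columns=["chrom", "ctrl_pos", "kd_pos", "shift", "category"]
    )
    return BoundaryComparison(
        matches=matches,
        counts=counts,
        same_tol=same_tol,
        shift_min=shift_min,
        shift_max=shift_max,
    )


def _count_containments(outer: pd.DataFrame, inner: pd.DataFrame) -> int:
    """Number of outer domains wholly containing >= 2 inner domains."""
    count = 0
    for row in outer.itertuples():
        sub = inner[
            (inner["chrom"] == row.chrom)
            & (inner["start"] >= row.start)
            & (inner["end"] <= row.end)
        ]
        if len(sub) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# virtual 4C


def virtual_4c(
    matrix: ContactMatrix,
    anchor: Region | list[Region],
    target: Region,
    condition: str = "",
) -> Virtual4CProfile:
    """Mean interaction from the anchor bin set to every target bin.

    Per target bin: mean of values between that bin and all unmasked
    anchor bins (zeros included).  Bins inside the anchor are flagged;
    masked target bins are NaN.
    """
    anchors = [anchor] if isinstance(anchor, Region) else list(anchor)
    anchor_ids = np.unique(np.concatenate([matrix.bins.bins_in(a) for a in anchors]))
    anchor_ids = anchor_ids[matrix.unmasked[anchor_ids]]
    if len(anchor_ids) == 0:
        raise ValueError("anchor is empty or fully masked")
    target_ids = matrix.bins.bins_in(target)
    if len(target_ids) == 0:
        raise ValueError(f"target {target} outside bin table")

    n = matrix.n_bins
    in_anchor = np.zeros(n, dtype=bool)
    in_anchor[anchor_ids] = True
    sums = np.zeros(n)
    i, j, v = matrix.bin1, matrix.bin2, matrix.value
    a1 = in_anchor[i]
    a2 = in_anchor[j]
    np.add.at(sums, j[a1], v[a1])
    off = i != j
    np.add.at(sums, i[a2 & off], v[a2 & off])
    profile = sums[target_ids] / len(anchor_ids)
    profile[~matrix.unmasked[target_ids]] = np.nan
    return Virtual4CProfile(
        bins=matrix.bins,
        target_bin_ids=target_ids,
        values=profile,
        anchor_flag=in_anchor[target_ids],
        condition=condition,
    )


def size_matched_controls(
    anchor: Region,
    arm: Region,
    n_controls: int,
    exclusions: list[Region] | None = None,
    seed: int = 0,
    grid: int | None = None,
    max_tries: int = 10_000,
    disjoint: bool = False,
) -> list[Region]:
    """Randomly placed control intervals of exactly the anchor's length.

    Placements are uniform on the arm, overlap neither the anchor nor
    any exclusion interval, and are reproducible for a given seed.
    ``grid`` snaps starts to a bin grid so controls align with matrix
    bins; ``disjoint`` additionally forbids controls overlapping each
    other (infeasible when the free arm span barely exceeds
    ``n_controls`` anchor lengths).
    """
    exclusions = list(exclusions or [])
    length = anchor.length
    if arm.length < length:
        raise ValueError("arm shorter than the anchor")
    rng = np.random.default_rng(seed)
    avoid = [anchor] + exclusions
    out: list[Region] = []
    tries = 0
    while len(out) < n_controls:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"no feasible placement after {max_tries} tries "
                f"({len(out)}/{n_controls} placed)"
            )
        start = int(rng.integers(arm.start, arm.end - length + 1))
        if grid:
            start = (start // grid) * grid
            if start + length > arm.end:
                continue
        cand = Region(arm.chrom, start, start + length)
        if any(cand.overlaps(r) for r in avoid):
            continue
        if disjoint and any(cand.overlaps(r) for r in out):
            continue
        out.append(cand)
    return out


def v4c_difference(
    a: Virtual4CProfile, b: Virtual4CProfile
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of per-bin (a - b) over unmasked, non-anchor bins."""
    if not np.array_equal(a.target_bin_ids, b.target_bin_ids):
        raise ValueError("profiles must cover the same bins")
    keep = (
        np.isfinite(a.values)
        & np.isfinite(b.values)
        & ~a.anchor_flag
        & ~b.anchor_flag
    )
    if not keep.any():
        raise ValueError("no overlapping unmasked non-anchor bins")
    diff = a.values[keep] - b.values[keep]
    return float(diff.mean()), float(diff.std()), diff
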