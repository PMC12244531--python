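"""Eigenvector A/B compartment calling and k-means P-compartment definition.

Per chromosome arm, the observed/expected map is converted to a Pearson
correlation matrix whose leading eigenvectors define compartment
structure: the sign of PC1 (oriented so active chromatin is positive)
gives A/B, and k-means over the first three components separates the
pericentric P compartment as a third cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from pericentriq.hic_io import BinTable, ContactMatrix, Region, observed_expected

__all__ = [
    "EigenResult",
    "Compartment",
    "CompartmentSegmentation",
    "PCompartmentCall",
    "compute_eigenvectors",
    "call_compartments",
    "kmeans_p_compartments",
    "annotate_bins_with_states",
]


@dataclass
class EigenResult:
    """First ``n`` principal components of an arm's O/E correlation matrix.

    ``components`` has one row per arm bin (NaN rows for masked or
    degenerate bins); ``bin_ids`` index into the genome-wide bin table.
    """

    bins: BinTable
    arm: Region
    bin_ids: np.ndarray
    components: np.ndarray  # (n_arm_bins, n), NaN where masked
    explained: np.ndarray  # explained-variance fractions
    oriented: bool
    centromeric_end: str | None = None  # 'left' / 'right' if known

    @property
    def pc1(self) -> np.ndarray:
        return self.components[:, 0]


@dataclass(frozen=True)
class Compartment:
    number: int  # per-type consecutive index along the genome (A1, A2, ...)
    ctype: str  # {'A', 'B', 'P'}
    chrom: str
    start: int
    end: int
    bin_ids: tuple[int, ...]

    @property
    def name(self) -> str:
        return f"{self.ctype}{self.number}"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class CompartmentSegmentation:
    """Ordered, non-overlapping compartments numbered along the genome."""

    compartments: list[Compartment]
    min_len: int

    def __post_init__(self) -> None:
        prev: Compartment | None = None
        for c in self.compartments:
            if prev is not None and prev.chrom == c.chrom and c.start < prev.end:
                raise ValueError("compartments must be sorted and non-overlapping")
            prev = c

    def __len__(self) -> int:
        return len(self.compartments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.chrom, c.start, c.end, c.name, c.ctype, c.number)
                for c in self.compartments
            ],
            columns=["chrom", "start", "end", "name", "type", "number"],
        )


@dataclass
class PCompartmentCall:
    """k-means cluster labels and the derived per-arm pericentric interval."""

    bin_ids: np.ndarray
    labels: np.ndarray  # cluster index per bin (rows of bin_ids)
    p_cluster: int | None
    p_regions: dict[str, Region | None]
    cluster_types: dict[int, str]
    scree: pd.DataFrame  # columns k, inertia
    seed: int
    restarts: int


def annotate_bins_with_states(
    bins: BinTable, state_track: pd.DataFrame
) -> np.ndarray:
    """Per-bin state by majority base overlap ('' where uncovered)."""
    states = np.full(bins.n_bins, "", dtype=object)
    cover = np.zeros(bins.n_bins)
    best = {}
    for row in state_track.itertuples():
        ids = bins.bins_in(Region(row.chrom, row.start, row.end))
        if len(ids) == 0:
            continue
        ov = np.minimum(bins.ends[ids], row.end) - np.maximum(bins.starts[ids], row.start)
        for b, o in zip(ids, ov):
            key = (b, row.state)
            best[key] = best.get(key, 0) + o
    for (b, state), o in best.items():
        if o > cover[b]:
            cover[b] = o
            states[b] = state
    return states.astype(str)


def compute_eigenvectors(
    matrix: ContactMatrix,
    arm: Region,
    n: int = 3,
    state_track: pd.DataFrame | None = None,
    centromeric_end: str | None = None,
    min_unmasked: int = 20,
    smooth_bins: int = 1,
) -> EigenResult:
    """PC1..PCn of the arm's O/E Pearson correlation matrix.

    ``smooth_bins`` applies a 2D running mean of half-window that many
    bins to the O/E map before the correlation step (the analogue of
    computing at a coarser "super-resolution" to stabilise higher
    components on sparse maps; 0 disables it).

    Bins that are masked, empty, or degenerate (constant O/E rows) carry
    NaN components. When a ``state_track`` is supplied, PC1 is oriented
    so bins overlapping 'active' intervals have positive mean PC1;
    otherwise the orientation is the raw eigensolver sign and
    ``oriented`` is False.
    """
    oe, _ = observed_expected(matrix, arm)
    arm_bins = matrix.bins.bins_in(arm)
    if matrix.unmasked[arm_bins].sum() < min_unmasked:
        raise ValueError(f"arm {arm} has fewer than {min_unmasked} unmasked bins")
    sub = oe.submatrix(arm_bins)
    if smooth_bins > 0:
        from scipy.ndimage import uniform_filter

        sub = uniform_filter(sub, size=2 * smooth_bins + 1, mode="nearest")
    valid = matrix.unmasked[arm_bins] & (sub.sum(axis=1) > 0)
    # degenerate rows (zero variance) cannot enter the correlation matrix
    with np.errstate(invalid="ignore"):
        row_sd = sub[valid].std(axis=1)
    valid_idx = np.flatnonzero(valid)
    valid_idx = valid_idx[row_sd > 0]
    if len(valid_idx) < max(n + 1, min_unmasked):
        raise ValueError("fewer informative bins than requested components")

    corr = np.corrcoef(sub[np.ix_(valid_idx, valid_idx)])
    corr = np.nan_to_num(corr, nan=0.0)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals[:n] <= 0).any():
        raise ValueError("fewer than n informative dimensions in correlation matrix")
    pos = evals[evals > 0]
    explained = evals[:n] / pos.sum()

    components = np.full((len(arm_bins), n), np.nan)
    components[valid_idx, :] = evecs[:, :n]

    oriented = False
    if state_track is not None:
        states = annotate_bins_with_states(matrix.bins, state_track)
        active = states[arm_bins] == "active"
        ref = active & np.isfinite(components[:, 0])
        if ref.any():
            if np.nanmean(components[ref, 0]) < 0:
                components[:, 0] = -components[:, 0]
            oriented = True
    if centromeric_end is not None and n > 1:
        # eigenvector signs are arbitrary per arm; anchor PC2.. to the
        # centromere-proximal tenth of the arm so pericentric signatures
        # align across arms (needed when clustering arms jointly)
        n_ref = max(len(arm_bins) // 10, 1)
        ref_rows = (
            np.arange(n_ref)
            if centromeric_end == "left"
            else np.arange(len(arm_bins) - n_ref, len(arm_bins))
        )
        for k in range(1, n):
            vals = components[ref_rows, k]
            if np.isfinite(vals).any() and np.nanmean(vals) < 0:
                components[:, k] = -components[:, k]
    return EigenResult(
        bins=matrix.bins,
        arm=arm,
        bin_ids=arm_bins,
        components=components,
        explained=explained,
        oriented=oriented,
        centromeric_end=centromeric_end,
    )


def _runs_from_signs(signs: np.ndarray) -> list[list[int]]:
    """Group consecutive indices of equal nonzero sign."""
    runs: list[list[int]] = []
    for k, s in enumerate(signs):
        if s == 0:
            continue
        if runs and signs[runs[-1][-1]] == s:
            runs[-1].append(k)
        else:
            runs.append([k])
    return runs


def call_compartments(
    eigs: EigenResult | list[EigenResult], min_len: int = 20_000
) -> CompartmentSegmentation:
    """Maximal same-sign PC1 runs of at least ``min_len`` become compartments.

    Runs shorter than ``min_len`` are absorbed into the larger flanking
    run (ties broken upstream), preserving the partition property.
    Compartments are numbered consecutively along the genome, per type
    (A1, A2, ... and B1, B2, ...).
    """
    if isinstance(eigs, EigenResult):
        eigs = [eigs]
    all_comps: list[tuple[str, int, int, str, tuple[int, ...]]] = []
    for eig in eigs:
        pc1 = eig.pc1
        finite = np.isfinite(pc1)
        signs = np.zeros(len(pc1), dtype=int)
        signs[finite] = np.sign(pc1[finite]).astype(int)
        runs = _runs_from_signs(signs)
        if not runs:
            continue

        bins = eig.bins
        ids = eig.bin_ids

        def extent(run: list[int]) -> int:
            return int(bins.ends[ids[run[-1]]] - bins.starts[ids[run[0]]])

        # absorb short runs into the larger flank until all pass min_len
        while len(runs) > 1:
            lengths = [extent(r) for r in runs]
            shortest = min(lengths)
            if shortest >= min_len:
                break
            k = lengths.index(shortest)
            left_len = lengths[k - 1] if k > 0 else -1
            right_len = lengths[k + 1] if k < len(runs) - 1 else -1
            target = k - 1 if left_len >= right_len else k + 1
            signs_target = signs[runs[target][0]]
            for idx in runs[k]:
                signs[idx] = signs_target
            merged = sorted(runs[k] + runs[target])
            lo, hi = min(k, target), max(k, target)
            runs[lo:hi + 1] = [merged]
            # coalesce neighbours that now share a sign
            merged_any = True
            while merged_any:
                merged_any = False
                for q in range(len(runs) - 1):
                    if signs[runs[q][0]] == signs[runs[q + 1][0]]:
                        runs[q:q + 2] = [runs[q] + runs[q + 1]]
                        merged_any = True
                        break
        runs = [r for r in runs if extent(r) >= min_len]
        for r in runs:
            ctype = "A" if signs[r[0]] > 0 else "B"
            all_comps.append(
                (
                    eig.arm.chrom,
                    int(bins.starts[ids[r[0]]]),
                    int(bins.ends[ids[r[-1]]]),
                    ctype,
                    tuple(int(ids[q]) for q in r),
                )
            )

    all_comps.sort(key=lambda c: (c[4][0],))  # genome order via first bin id
    counters = {"A": 0, "B": 0, "P": 0}
    comps = []
    for chrom, start, end, ctype, bin_ids in all_comps:
        counters[ctype] += 1
        comps.append(Compartment(counters[ctype], ctype, chrom, start, end, bin_ids))
    return CompartmentSegmentation(comps, min_len)


def kmeans_p_compartments(
    eigs: EigenResult | list[EigenResult],
    k: int = 3,
    seed: int = 0,
    restarts: int = 20,
    scree_max_k: int = 6,
) -> PCompartmentCall:
    """k-means over the first three components; designate the P cluster.

    Among the k clusters, P is the one whose bins sit closest, on
    average, to the centromeric end of their arm (the pericentric
    signature); each arm's P interval is the largest contiguous run of
    P-cluster bins. An inertia-vs-k table is emitted for scree
    inspection.
    """
    if isinstance(eigs, EigenResult):
        eigs = [eigs]
    rows = []
    proximity = []
    arm_of_row = []
    bin_ids = []
    for eig in eigs:
        comp = eig.components
        ok = np.all(np.isfinite(comp), axis=1)
        ids = eig.bin_ids[ok]
        rows.append(comp[ok])
        bin_ids.append(ids)
        mids = eig.bins.midpoints[ids]
        if eig.centromeric_end == "left":
            d = mids - eig.arm.start
        else:  # default to 'right' if unspecified
            d = eig.arm.end - mids
        proximity.append(1.0 - d / eig.arm.length)
        arm_of_row.extend([eig.arm.chrom] * len(ids))
    X = np.vstack(rows)
    bin_ids = np.concatenate(bin_ids)
    proximity = np.concatenate(proximity)
    arm_of_row = np.array(arm_of_row)
    if k > len(X):
        raise ValueError("k exceeds number of informative bins")

    scree_rows = []
    for kk in range(1, max(scree_max_k, k) + 1):
        if kk > len(X):
            break
        km = KMeans(n_clusters=kk, n_init=restarts, random_state=seed)
        km.fit(X)
        scree_rows.append((kk, float(km.inertia_)))
        if kk == k:
            labels = km.labels_
    scree = pd.DataFrame(scree_rows, columns=["k", "inertia"])

    if k == 1:
        warnings.warn("k=1 yields a single cluster; no P compartment called")
        return PCompartmentCall(
            bin_ids, labels, None, {a: None for a in np.unique(arm_of_row)},
            {0: "AB"}, scree, seed, restarts,
        )

    mean_prox = np.array([proximity[labels == c].mean() for c in range(k)])
    p_cluster = int(np.argmax(mean_prox))

    cluster_types = {p_cluster: "P"}
    others = [c for c in range(k) if c != p_cluster]
    # of the non-P clusters, higher mean PC1 is the A-like cluster
    mean_pc1 = {c: float(X[labels == c, 0].mean()) for c in others}
    if others:
        a_cluster = max(others, key=lambda c: mean_pc1[c])
        for c in others:
            cluster_types[c] = "A" if c == a_cluster else "B"

    p_regions: dict[str, Region | None] = {}
    for eig in eigs:
        arm_rows = np.flatnonzero(arm_of_row == eig.arm.chrom)
        is_p = labels[arm_rows] == p_cluster
        best_run: list[int] | None = None
        current: list[int] = []
        for r, flag in zip(arm_rows, is_p):
            if flag:
                current.append(r)
            else:
                if best_run is None or len(current) > len(best_run):
                    best_run = current
                current = []
        if best_run is None or len(current) > len(best_run):
            best_run = current
        if best_run:
            first, last = bin_ids[best_run[0]], bin_ids[best_run[-1]]
            p_regions[eig.arm.chrom] = Region(
                eig.arm.chrom,
                int(eig.bins.starts[first]),
                int(eig.bins.ends[last]),
            )
        else:
            p_regions[eig.arm.chrom] = None
    return PCompartmentCall(
        bin_ids, labels, p_cluster, p_regions, cluster_types, scree, seed, restarts
    )
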