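"""Distance- and compartment-stratified contact statistics.

P(s) decay curves and their crossovers, short/long contact ratios, trans
proportions, chromatin-state-stratified interaction strengths, numbered
compartment-pair scores with fold change against control, and the
stratum-adjusted correlation coefficient (SCC) for map reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.stats import rankdata

from pericentriq.hic_io import ContactMatrix, Region
from pericentriq.compartments import CompartmentSegmentation, annotate_bins_with_states

__all__ = [
    "PsCurve",
    "CrossoverResult",
    "CompartmentPairScore",
    "SccResult",
    "ps_curve",
    "fit_ps_slope",
    "curve_crossover",
    "short_long_ratio",
    "trans_proportion",
    "trans_proportion_matrix",
    "state_interaction_strength",
    "compartment_pair_scores",
    "fold_change",
    "scc",
]


@dataclass
class PsCurve:
    """Mean contact per log-spaced separation shell, normalized to sum 1."""

    arm: Region
    shell_edges: np.ndarray  # bp, strictly increasing, len = n_shells + 1
    separations: np.ndarray  # geometric shell midpoints (bp)
    values: np.ndarray  # normalized mean contact (NaN = missing shell)
    raw_means: np.ndarray  # unnormalized per-shell means
    n_pairs: np.ndarray
    norm_factor: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.shell_edges) <= 0):
            raise ValueError("shell edges must be strictly increasing")


@dataclass
class CrossoverResult:
    first: float  # smallest crossing separation (bp)
    all_crossings: list[float]


@dataclass(frozen=True)
class CompartmentPairScore:
    comp_i: str  # e.g. "A1"
    comp_j: str
    type_i: str
    type_j: str
    separation: float  # midpoint-to-midpoint (bp)
    mean: float
    n_pairs: int
    fold_change: float | None = None
    percent_change: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.comp_i, self.comp_j)

    @property
    def pair_class(self) -> str:
        return "-".join(sorted((self.type_i, self.type_j)))


@dataclass
class SccResult:
    per_chrom: dict[str, float]
    aggregate: float
    h: int
    max_sep: float


# ---------------------------------------------------------------------------
# P(s)


def _diagonal_sums(matrix: ContactMatrix, arm: Region):
    """Per-diagonal (sum, valid-pair count) within the arm, self excluded."""
    arm_bins = matrix.bins.bins_in(arm)
    if len(arm_bins) == 0:
        raise ValueError(f"empty arm {arm}")
    lo = arm_bins.min()
    n_arm = arm_bins.max() - lo + 1
    good = np.zeros(n_arm)
    good[arm_bins - lo] = matrix.unmasked[arm_bins]
    n_valid = np.array(
        [int(np.dot(good[: n_arm - d], good[d:])) for d in range(1, n_arm)]
    )
    in_arm = np.zeros(matrix.n_bins, dtype=bool)
    in_arm[arm_bins] = True
    keep = in_arm[matrix.bin1] & in_arm[matrix.bin2] & (matrix.bin1 != matrix.bin2)
    d = matrix.bin2[keep] - matrix.bin1[keep]
    sums = np.zeros(n_arm - 1)
    np.add.at(sums, d - 1, matrix.value[keep])
    seps = np.arange(1, n_arm) * matrix.bins.resolution
    return seps, sums, n_valid


def ps_curve(
    matrix: ContactMatrix, arm: Region, shells_per_decade: int = 8
) -> PsCurve:
    """Contact-frequency-vs-distance curve in log-spaced shells.

    Shell means are computed over all valid (unmasked) cis bin pairs at
    each separation (zeros included) and normalized so the reported
    curve sums to 1; the normalization factor is recorded.
    """
    seps, sums, n_valid = _diagonal_sums(matrix, arm)
    res = matrix.bins.resolution
    max_sep = seps[-1]
    n_shell = int(np.ceil(np.log10(max_sep / res) * shells_per_decade)) + 1
    edges = res * 10 ** (np.arange(n_shell + 1) / shells_per_decade)
    edges[0] = res * (1 - 1e-9)

    idx = np.searchsorted(edges, seps, side="right") - 1
    shell_sum = np.zeros(n_shell)
    shell_n = np.zeros(n_shell)
    np.add.at(shell_sum, idx, sums)
    np.add.at(shell_n, idx, n_valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(shell_n > 0, shell_sum / np.maximum(shell_n, 1), np.nan)
    total = np.nansum(raw)
    values = raw / total if total > 0 else raw
    mids = np.sqrt(edges[:-1] * edges[1:])
    return PsCurve(
        arm=arm,
        shell_edges=edges,
        separations=mids,
        values=values,
        raw_means=raw,
        n_pairs=shell_n,
        norm_factor=float(total),
    )


def fit_ps_slope(
    curve: PsCurve, min_sep: float | None = None, max_sep: float | None = None
) -> float:
    """Log-log slope of the P(s) curve (the decay exponent, negated)."""
    x = curve.separations
    y = curve.raw_means
    keep = np.isfinite(y) & (y > 0)
    if min_sep is not None:
        keep &= x >= min_sep
    if max_sep is not None:
        keep &= x <= max_sep
    if keep.sum() < 2:
        raise ValueError("too few shells for a slope fit")
    slope = np.polyfit(np.log(x[keep]), np.log(y[keep]), 1)[0]
    return float(slope)


def curve_crossover(a: PsCurve, b: PsCurve) -> CrossoverResult | None:
    """Separation where two P(s) curves cross, interpolated in log-log space.

    Uses the normalized curves (as plotted); returns None when the
    log-difference never changes sign (identical curves, or curves
    differing only by the recorded normalization).
    """
    if not np.allclose(a.shell_edges, b.shell_edges):
        raise ValueError("curves must share shells")
    ok = (
        np.isfinite(a.values)
        & np.isfinite(b.values)
        & (a.values > 0)
        & (b.values > 0)
    )
    x = np.log(a.separations[ok])
    ld = np.log(a.values[ok]) - np.log(b.values[ok])
    crossings = []
    for k in range(len(ld) - 1):
        if ld[k] == 0 and ld[k + 1] != 0:
            crossings.append(float(np.exp(x[k])))
        elif ld[k] * ld[k + 1] < 0:
            t = ld[k] / (ld[k] - ld[k + 1])
            crossings.append(float(np.exp(x[k] + t * (x[k + 1] - x[k]))))
    if not crossings:
        return None
    return CrossoverResult(first=min(crossings), all_crossings=sorted(crossings))


# ---------------------------------------------------------------------------
# ratios and proportions


def short_long_ratio(
    matrix: ContactMatrix, arm: Region, cutoff: float = 1_000_000
) -> float:
    """Ratio of short-range (< cutoff) to long-range (>= cutoff) cis signal.

    Self-pairs are excluded; a pair at exactly the cutoff counts as
    long-range.
    """
    arm_bins = matrix.bins.bins_in(arm)
    if len(arm_bins) == 0:
        raise ValueError(f"empty arm {arm}")
    in_arm = np.zeros(matrix.n_bins, dtype=bool)
    in_arm[arm_bins] = True
    keep = in_arm[matrix.bin1] & in_arm[matrix.bin2] & (matrix.bin1 != matrix.bin2)
    sep = (matrix.bin2[keep] - matrix.bin1[keep]) * matrix.bins.resolution
    v = matrix.value[keep]
    short = v[sep < cutoff].sum()
    long_ = v[sep >= cutoff].sum()
    if long_ == 0:
        raise ValueError(
            f"no long-range signal at or beyond {cutoff:g} bp on {arm.chrom}"
        )
    return float(short / long_)


def trans_proportion_matrix(matrix: ContactMatrix) -> pd.DataFrame:
    """Per source chromosome, the proportion of its total signal reaching
    each target chromosome (itself included); rows sum to 1.

    Computed on raw (non-balanced) matrices.
    """
    if matrix.normalization != "raw":
        raise ValueError("trans proportions are defined on raw matrices")
    chroms = list(dict.fromkeys(matrix.bins.chroms))
    if len(chroms) < 2:
        raise ValueError("trans proportions need at least two chromosomes")
    cidx = {c: k for k, c in enumerate(chroms)}
    ci = np.array([cidx[c] for c in matrix.bins.chroms])
    a = ci[matrix.bin1]
    b = ci[matrix.bin2]
    totals = np.zeros((len(chroms), len(chroms)))
    np.add.at(totals, (a, b), matrix.value)
    totals = totals + totals.T - np.diag(np.diag(totals))
    props = totals / totals.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=chroms, columns=chroms)


def trans_proportion(matrix: ContactMatrix, chrom_a: str, chrom_b: str) -> float:
    """(total signal chrom_a -> chrom_b) / (total signal chrom_a -> all)."""
    props = trans_proportion_matrix(matrix)
    return float(props.loc[chrom_a, chrom_b])


# ---------------------------------------------------------------------------
# chromatin-state stratified strength


def state_interaction_strength(
    matrix: ContactMatrix, state_track: pd.DataFrame, separation: int
) -> dict[str, np.ndarray]:
    """Per-state contact values at exactly the given genomic separation.

    A pair qualifies when both bins carry the same state (majority base
    overlap) and are unmasked; zero entries are included as zeros.
    Mixed-state pairs are excluded.
    """
    res = matrix.bins.resolution
    if separation % res != 0 or separation <= 0:
        raise ValueError("separation must be a positive multiple of the resolution")
    d = separation // res
    states = annotate_bins_with_states(matrix.bins, state_track)
    n = matrix.n_bins
    chroms = matrix.bins.chroms
    # value vector of pairs (i, i+d), default 0
    vals = np.zeros(n)
    hit = matrix.bin2 - matrix.bin1 == d
    vals[matrix.bin1[hit]] = matrix.value[hit]
    i = np.arange(n - d)
    j = i + d
    eligible = (chroms[i] == chroms[j]) & matrix.unmasked[i] & matrix.unmasked[j]
    out: dict[str, np.ndarray] = {}
    for state in pd.unique(state_track["state"]):
        pick = eligible & (states[i] == state) & (states[j] == state)
        out[state] = vals[i[pick]]
    return out


# ---------------------------------------------------------------------------
# compartment-pair scores


def compartment_pair_scores(
    matrix: ContactMatrix,
    seg: CompartmentSegmentation,
    min_sep: float = 500_000,
    max_sep: float = 5_000_000,
) -> list[CompartmentPairScore]:
    """Mean contact between every eligible pair of control compartments.

    The pair separation is measured midpoint-to-midpoint; pairs outside
    [min_sep, max_sep] or on different chromosomes are skipped.  The
    score is the mean of values over all unmasked bin pairs (zeros
    included). Empty (fully masked) compartments are skipped.
    """
    if min_sep >= max_sep:
        raise ValueError("min_sep must be below max_sep")
    unmasked = matrix.unmasked
    comp_bins = {}
    for c in seg.compartments:
        ids = np.array([b for b in c.bin_ids if unmasked[b]])
        if len(ids):
            comp_bins[c.name] = ids
    dense = matrix.to_dense()
    scores = []
    comps = seg.compartments
    for x in range(len(comps)):
        for y in range(x + 1, len(comps)):
            ci, cj = comps[x], comps[y]
            if ci.chrom != cj.chrom:
                continue
            sep = abs(cj.midpoint - ci.midpoint)
            if not (min_sep <= sep <= max_sep):
                continue
            if ci.name not in comp_bins or cj.name not in comp_bins:
                continue
            block = dense[np.ix_(comp_bins[ci.name], comp_bins[cj.name])]
            scores.append(
                CompartmentPairScore(
                    comp_i=ci.name,
                    comp_j=cj.name,
                    type_i=ci.ctype,
                    type_j=cj.ctype,
                    separation=float(sep),
                    mean=float(block.mean()),
                    n_pairs=int(block.size),
                )
            )
    return scores


def fold_change(
    scores_kd: list[CompartmentPairScore], scores_ctrl: list[CompartmentPairScore]
) -> list[CompartmentPairScore]:
    """Per-pair KD/control fold change; percent change = (fold - 1) * 100.

    Pairs whose control mean is zero are flagged undefined (fold NaN).
    """
    ctrl = {s.key: s for s in scores_ctrl}
    out = []
    for s in scores_kd:
        if s.key not in ctrl:
            continue
        c = ctrl[s.key]
        if c.mean > 0:
            fc = s.mean / c.mean
            pct = (fc - 1.0) * 100.0
        else:
            fc = float("nan")
            pct = float("nan")
        out.append(
            CompartmentPairScore(
                comp_i=s.comp_i,
                comp_j=s.comp_j,
                type_i=s.type_i,
                type_j=s.type_j,
                separation=s.separation,
                mean=s.mean,
                n_pairs=s.n_pairs,
                fold_change=fc,
                percent_change=pct,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stratum-adjusted correlation (HiCRep-style SCC)


def _scc_one(
    a: np.ndarray, b: np.ndarray, h: int, max_d: int
) -> float | None:
    if h > 0:
        size = 2 * h + 1
        a = uniform_filter(a, size=size, mode="constant")
        b = uniform_filter(b, size=size, mode="constant")
    num = 0.0
    den = 0.0
    n = len(a)
    for d in range(1, min(max_d, n - 1) + 1):
        x = np.diagonal(a, d)
        y = np.diagonal(b, d)
        if len(x) < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rho = float(np.corrcoef(x, y)[0, 1])
        w = len(x) * np.sqrt(np.var(rankdata(x)) * np.var(rankdata(y)))
        num += w * rho
        den += w
    if den == 0:
        return None
    return num / den


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    h: int = 20,
    max_sep: float = 20_000_000,
) -> SccResult:
    """Stratum-adjusted correlation between two maps on the same bins.

    Each cis map is 2D mean-filtered with half-window ``h`` bins, then
    per-separation-stratum Pearson correlations are combined with
    variance-stabilized (rank) weights up to ``max_sep``. ``h=0`` is the
    unsmoothed per-diagonal correlation.
    """
    if not a.bins.same_table(b.bins):
        raise ValueError("matrices must share a bin table")
    res = a.bins.resolution
    max_d = int(max_sep // res)
    per_chrom: dict[str, float] = {}
    for chrom in dict.fromkeys(a.bins.chroms):
        ids = a.bins.bins_in(Region(chrom, 0, int(a.bins.chrom_sizes()[chrom])))
        val = _scc_one(a.submatrix(ids), b.submatrix(ids), h, max_d)
        if val is not None:
            per_chrom[chrom] = val
    if not per_chrom:
        raise ValueError("no stratum had enough data for a correlation")
    return SccResult(
        per_chrom=per_chrom,
        aggregate=float(np.mean(list(per_chrom.values()))),
        h=h,
        max_sep=max_sep,
    )
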