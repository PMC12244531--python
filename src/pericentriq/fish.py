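"""Quantification of 3D FISH observations.

Label-volume statistics (domain counts, surface area, intermixing) and
probe-pair spot statistics (contact frequency, minimum distance,
power-law distance scaling).  The pipeline starts from segmented label
masks and centroid tables; raw-image processing is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

__all__ = [
    "NucleusLabelVolume",
    "ProbePairObservation",
    "PowerLawFit",
    "count_domains",
    "surface_area",
    "overlap_fraction",
    "pair_contact",
    "contact_frequency",
    "min_distance",
    "power_law_fit",
    "observations_to_frame",
]


@dataclass
class NucleusLabelVolume:
    """Multi-channel 3D label masks for one nucleus.

    ``channels`` maps channel name to a 3D non-negative integer array
    (0 = background); all channels share one shape.  ``voxel_size`` is
    the (x, y, z) voxel edge length in micrometres, matching array axes
    0, 1, 2.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share one array shape")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not a 3D array")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative labels")


@dataclass
class ProbePairObservation:
    """One probe pair in one nucleus: centroids and optional voxel overlap."""

    nucleus_id: int
    pair_id: int
    separation_bp: int
    centroid_a: tuple[float, float, float]
    centroid_b: tuple[float, float, float]
    overlap_voxels: int | None = None

    def __post_init__(self) -> None:
        if self.separation_bp <= 0:
            raise ValueError("genomic separation must be positive")
        coords = np.concatenate([self.centroid_a, self.centroid_b])
        if not np.all(np.isfinite(coords)):
            raise ValueError("centroids must be finite")

    @property
    def distance(self) -> float:
        return float(
            np.linalg.norm(np.subtract(self.centroid_a, self.centroid_b))
        )


@dataclass
class PowerLawFit:
    """Least-squares log-log fit d = amplitude * s**exponent."""

    amplitude: float
    exponent: float
    se_log_amplitude: float
    se_exponent: float
    n: int
    residual_sd: float
    aggregation: str  # 'median' per separation or 'none'

    def exponent_ci(self, level: float = 0.95) -> tuple[float, float]:
        q = t_dist.ppf(0.5 + level / 2, df=max(self.n - 2, 1))
        return (
            self.exponent - q * self.se_exponent,
            self.exponent + q * self.se_exponent,
        )


# ---------------------------------------------------------------------------
# label-volume metrics


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def count_domains(
    volume: NucleusLabelVolume, channel: str, connectivity: int = 26
) -> int:
    """Number of 3D connected components in the channel mask.

    Under the default 26-connectivity, voxels touching even only at a
    corner join one domain.  An empty mask counts zero domains.
    """
    mask = volume.channels[channel] > 0
    if not mask.any():
        return 0
    _, n = ndimage.label(mask, structure=_structure(connectivity))
    return int(n)


def surface_area(volume: NucleusLabelVolume, channel: str) -> float:
    """Total exposed voxel-face area of the channel mask, in µm².

    Each voxel face not shared with another foreground voxel contributes
    the face's physical area; anisotropic voxels are respected.
    """
    mask = (volume.channels[channel] > 0).astype(np.int8)
    sx, sy, sz = volume.voxel_size
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for axis, area in face.items():
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        total += float(np.abs(np.diff(padded, axis=axis)).sum()) * area
    return total


def overlap_fraction(
    volume: NucleusLabelVolume, channel_a: str, channel_b: str
) -> float:
    """Fraction of channel_a's voxels overlapping channel_b.

    Directional: overlap_fraction(v, a, b) != overlap_fraction(v, b, a)
    in general; compute both directions when both are of interest.
    Returns NaN (undefined) when channel_a is empty.
    """
    a = volume.channels[channel_a] > 0
    b = volume.channels[channel_b] > 0
    denom = int(a.sum())
    if denom == 0:
        return float("nan")
    return float((a & b).sum() / denom)


# ---------------------------------------------------------------------------
# probe-pair metrics


def pair_contact(
    obs: ProbePairObservation,
    mode: str = "overlap",
    threshold: float | None = None,
) -> bool:
    """Whether a probe pair is in contact.

    'overlap' mode (default): contact means the two probe signals share
    at least one voxel.  'distance' mode: centroid distance at most
    ``threshold`` (µm).
    """
    if mode == "overlap":
        if obs.overlap_voxels is None:
            raise ValueError("overlap mode requires a voxel-overlap count")
        return obs.overlap_voxels >= 1
    if mode == "distance":
        if threshold is None:
            raise ValueError("distance mode requires a threshold")
        return obs.distance <= threshold
    raise ValueError("mode must be 'overlap' or 'distance'")


def contact_frequency(
    observations: list[ProbePairObservation],
    mode: str = "overlap",
    threshold: float | None = None,
) -> float:
    """Percent of observations in contact."""
    if not observations:
        raise ValueError("no observations")
    hits = sum(pair_contact(o, mode, threshold) for o in observations)
    return 100.0 * hits / len(observations)


def min_distance(foci_a: np.ndarray, foci_b: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between two focus sets (µm).

    Each argument is an (n, 3) array of focus centroids; multiple foci
    per probe (diploid homologs) are allowed and the global minimum over
    all combinations is taken.
    """
    a = np.atleast_2d(np.asarray(foci_a, dtype=float))
    b = np.atleast_2d(np.asarray(foci_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("each probe needs at least one focus")
    return float(cdist(a, b).min())


def power_law_fit(
    observations: list[tuple[float, float]] | np.ndarray,
    aggregate: str = "median",
) -> PowerLawFit:
    """Fit d = A * s**beta by least squares in log-log space.

    ``observations`` are (genomic separation, 3D distance) records.
    Non-positive entries are excluded with a warning.  With
    ``aggregate='median'`` (default) the per-separation median distance
    is fitted, one point per distinct separation; 'none' fits every
    record.
    """
    arr = np.asarray(observations, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("observations must be (separation, distance) records")
    good = (arr[:, 0] > 0) & (arr[:, 1] > 0) & np.all(np.isfinite(arr), axis=1)
    if good.sum() < len(arr):
        warnings.warn(
            f"excluded {len(arr) - int(good.sum())} non-positive/non-finite records"
        )
    arr = arr[good]
    if aggregate == "median":
        df = pd.DataFrame(arr, columns=["s", "d"])
        agg = df.groupby("s", sort=True)["d"].median().reset_index()
        s, d = agg["s"].to_numpy(), agg["d"].to_numpy()
    elif aggregate == "none":
        s, d = arr[:, 0], arr[:, 1]
    else:
        raise ValueError("aggregate must be 'median' or 'none'")
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct separations")

    x = np.log(s)
    y = np.log(d)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return PowerLawFit(
        amplitude=float(np.exp(coef[0])),
        exponent=float(coef[1]),
        se_log_amplitude=float(np.sqrt(cov[0, 0])),
        se_exponent=float(np.sqrt(cov[1, 1])),
        n=n,
        residual_sd=float(np.sqrt(s2)),
        aggregation=aggregate,
    )


def observations_to_frame(observations: list[ProbePairObservation]) -> pd.DataFrame:
    """Tabulate observations as TSV-ready records."""
    rows = []
    for o in observations:
        rows.append(
            (
                o.nucleus_id,
                o.pair_id,
                o.separation_bp,
                *o.centroid_a,
                *o.centroid_b,
                o.overlap_voxels if o.overlap_voxels is not None else -1,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus",
            "pair",
            "sep_bp",
            "ax",
            "ay",
            "az",
            "bx",
            "by",
            "bz",
            "overlap_voxels",
        ],
    )
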