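"""Forward model of a genome with planted compartments and condensin activity.

The generator plants: (a) power-law cis distance decay whose exponent
responds to a condensin-activity parameter lambda (1 = control, >1 =
elevated condensin II, <1 = depleted); (b) A/B checkerboarding via a
compartment affinity matrix; (c) a strongly self-interacting pericentric
P domain at the centromeric end of each arm, with condensin-dependent
stripes from the P domain to everything else; (d) a trans background
that decreases with condensin activity; (e) FISH probe-pair 3D distances
scaling as a power law of genomic separation, compacting as lambda grows.

Every downstream module is validated against the labels and parameters
planted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pericentriq.hic_io import BinTable, ContactMatrix, Region

__all__ = [
    "ArmSpec",
    "SyntheticGenomeSpec",
    "GeneratorModel",
    "GroundTruth",
    "expected_map",
    "sample_contacts",
    "simulate_fish_pairs",
    "ground_truth",
]

_LABELS = ("A", "B", "P")
_LABEL_INDEX = {lab: k for k, lab in enumerate(_LABELS)}


@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm: A/B blocks plus a terminal pericentric P domain.

    ``blocks`` tile the non-pericentric portion of the arm in genomic
    order; the P domain of length ``p_length`` sits at the
    ``centromeric_end`` ('left' or 'right').
    """

    name: str
    length: int
    blocks: tuple[tuple[str, int], ...]
    p_length: int
    centromeric_end: str = "right"

    def __post_init__(self) -> None:
        if self.centromeric_end not in ("left", "right"):
            raise ValueError("centromeric_end must be 'left' or 'right'")
        if self.p_length < 0 or self.p_length >= self.length:
            raise ValueError("p_length must be in [0, arm length)")
        if any(lab not in ("A", "B") for lab, _ in self.blocks):
            raise ValueError("blocks must be labeled A or B")
        if sum(ln for _, ln in self.blocks) + self.p_length != self.length:
            raise ValueError("blocks plus P domain must tile the arm exactly")

    def p_region(self) -> Region | None:
        if self.p_length == 0:
            return None
        if self.centromeric_end == "right":
            return Region(self.name, self.length - self.p_length, self.length)
        return Region(self.name, 0, self.p_length)

    def intervals(self) -> list[tuple[str, int, int]]:
        """(label, start, end) tiles covering the arm, including P."""
        out = []
        pos = self.p_length if self.centromeric_end == "left" else 0
        if self.centromeric_end == "left" and self.p_length:
            out.append(("P", 0, self.p_length))
        for lab, ln in self.blocks:
            out.append((lab, pos, pos + ln))
            pos += ln
        if self.centromeric_end == "right" and self.p_length:
            out.append(("P", pos, self.length))
        return out


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Arm layout plus resolution; the source of all planted ground truth."""

    arms: tuple[ArmSpec, ...]
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")

    @classmethod
    def default(cls, resolution: int = 5000) -> "SyntheticGenomeSpec":
        """Two 5Mb arms flanking a centromere (2,000 bins at 5kb).

        Each arm carries a 1Mb terminal P domain and ten alternating
        400kb A/B blocks, sized so control maps show clear megabase-scale
        checkerboarding at 5kb resolution.
        """
        block = 400_000
        blocks_l = tuple(("A" if k % 2 == 0 else "B", block) for k in range(10))
        blocks_r = tuple(("B" if k % 2 == 0 else "A", block) for k in range(10))
        return cls(
            arms=(
                ArmSpec("armL", 5_000_000, blocks_l, 1_000_000, "right"),
                ArmSpec("armR", 5_000_000, blocks_r, 1_000_000, "left"),
            ),
            resolution=resolution,
        )

    def bin_table(self) -> BinTable:
        return BinTable.from_chrom_sizes(
            [(a.name, a.length) for a in self.arms], self.resolution
        )

    def state_track(self) -> pd.DataFrame:
        """Chromatin-state intervals aligned to the compartment layout.

        A blocks map to 'active'; B blocks alternate 'repressed' and
        'null' along each arm; P domains are 'null' (heterochromatic,
        non-polycomb).
        """
        rows = []
        for arm in self.arms:
            b_count = 0
            for lab, start, end in arm.intervals():
                if lab == "A":
                    state = "active"
                elif lab == "B":
                    state = "repressed" if b_count % 2 == 0 else "null"
                    b_count += 1
                else:
                    state = "null"
                rows.append((arm.name, start, end, state))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels for recovery scoring."""

    bins: BinTable
    labels: np.ndarray  # per-bin {'A','B','P'}
    p_regions: dict[str, Region | None]
    state_track: pd.DataFrame


def ground_truth(spec: SyntheticGenomeSpec) -> GroundTruth:
    """Per-bin compartment labels and per-arm P intervals.

    A bin takes the label of the tile containing its midpoint.
    """
    bins = spec.bin_table()
    labels = np.empty(bins.n_bins, dtype="<U1")
    for arm in spec.arms:
        ids = bins.bins_in(Region(arm.name, 0, arm.length))
        mids = bins.midpoints[ids]
        for lab, start, end in arm.intervals():
            hit = (mids >= start) & (mids < end)
            labels[ids[hit]] = lab
    return GroundTruth(
        bins=bins,
        labels=labels,
        p_regions={a.name: a.p_region() for a in spec.arms},
        state_track=spec.state_track(),
    )


@dataclass(frozen=True)
class GeneratorModel:
    """Parameters of the contact-generating process.

    * ``alpha0``: control cis decay exponent; effective exponent is
      ``alpha(lam) = alpha0 - kappa * log2(lam)`` (more condensin ->
      shallower decay -> relatively more long-range contact).
    * ``affinity``: 3x3 symmetric compartment-affinity matrix over
      (A, B, P); like-with-like A/B affinities above cross affinities
      give checkerboarding, a large P-P term gives a self-interacting
      pericentric domain.
    * ``sigma``: pericentric stripe amplitude; every pair with at least
      one end in P is multiplied by ``1 + sigma * (lam - 1)`` (cis and
      trans alike), planting the condensin-dependent stripe phenotype:
      contacts emanating from the pericentric domain rise and fall with
      condensin activity even when the global trans trend goes the other
      way.
    * ``tau0``: trans background level (defaults to 5% of the control cis
      level at 1Mb); scaled by ``lam ** -gamma`` so trans contact falls
      as condensin rises.
    * ``fish_*``: power law ``d = A_f * (s/1Mb) ** beta(lam) * exp(eps)``
      for probe-pair 3D distances, ``beta(lam) = fish_beta0 -
      fish_beta_kappa * log2(lam)``.
    """

    alpha0: float = 1.0
    kappa: float = 0.3
    sigma: float = 1.0
    tau0: float | None = None
    gamma: float = 0.5
    affinity: tuple[tuple[float, float, float], ...] = (
        (1.5, 0.7, 1.0),
        (0.7, 1.5, 1.0),
        (1.0, 1.0, 3.0),
    )
    depth: int = 1_000_000
    seed: int = 0
    fish_amplitude: float = 0.4
    fish_beta0: float = 0.33
    fish_beta_kappa: float = 0.05
    fish_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        aff = np.asarray(self.affinity, dtype=float)
        if aff.shape != (3, 3) or not np.allclose(aff, aff.T):
            raise ValueError("affinity must be a symmetric 3x3 matrix over (A,B,P)")
        if np.any(aff <= 0):
            raise ValueError("all affinities must be positive")

    def alpha(self, lam: float) -> float:
        if lam <= 0:
            raise ValueError("condensin parameter lambda must be positive")
        a = self.alpha0 - self.kappa * np.log2(lam)
        if not (0.2 < a < 2.5):
            raise ValueError(f"decay exponent {a:.3g} outside admissible (0.2, 2.5)")
        return float(a)

    def beta(self, lam: float) -> float:
        return float(self.fish_beta0 - self.fish_beta_kappa * np.log2(lam))

    def stripe_factor(self, lam: float) -> float:
        f = 1.0 + self.sigma * (lam - 1.0)
        if f <= 0:
            raise ValueError(
                f"stripe factor {f:.3g} <= 0: inadmissible sigma={self.sigma}, "
                f"lambda={lam}"
            )
        return f

    def trans_level(self, lam: float, resolution: int) -> float:
        tau0 = self.tau0
        if tau0 is None:
            # 5% of the control cis level at 1Mb separation
            tau0 = 0.05 * (1_000_000 / resolution) ** (-self.alpha0)
        return float(tau0 * lam ** (-self.gamma))


def _row_scale_to_constant_coverage(
    dense: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """Symmetric scaling so every row sum equals the common mean."""
    m = dense.copy()
    for _ in range(max_iter):
        rs = m.sum(axis=1)
        b = rs / rs.mean()
        if np.abs(b - 1).max() < tol:
            break
        s = np.sqrt(b)
        m = m / s[:, None] / s[None, :]
    return m


def expected_map(
    spec: SyntheticGenomeSpec,
    model: GeneratorModel,
    lam: float,
    row_scale: bool = True,
) -> ContactMatrix:
    """Deterministic expected contact map for condensin activity ``lam``.

    Cis pair (i, j) at separation s (bins) gets
    ``affinity[c_i, c_j] * s^-alpha(lam) * stripe`` where the stripe
    factor ``1 + sigma*(lam-1)`` applies when either end is in P; trans
    pairs get ``tau0 * lam^-gamma * affinity[c_i, c_j]``, with the same
    stripe factor. Rows are then symmetrically scaled so expected
    coverage per bin is constant; self-pairs are excluded.
    """
    gt = ground_truth(spec)
    bins = gt.bins
    n = bins.n_bins
    c = np.array([_LABEL_INDEX[lab] for lab in gt.labels])
    aff = np.asarray(model.affinity, dtype=float)
    alpha = model.alpha(lam)
    stripe = model.stripe_factor(lam)
    tau = model.trans_level(lam, spec.resolution)

    chrom_idx = pd.factorize(bins.chroms)[0]
    pos = np.arange(n)

    dense = aff[np.ix_(c, c)].copy()
    cis = chrom_idx[:, None] == chrom_idx[None, :]
    sep = np.abs(pos[:, None] - pos[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(sep > 0, sep, 1.0) ** (-alpha)
    dense = np.where(cis, dense * decay, dense * tau)

    in_p = gt.labels == "P"
    one_in_p = in_p[:, None] ^ in_p[None, :]
    dense = np.where(one_in_p, dense * stripe, dense)
    np.fill_diagonal(dense, 0.0)

    if row_scale:
        # equalize per-bin coverage while conserving the total intensity,
        # so maps at different lambda stay on the model's absolute scale
        total = dense.sum()
        dense = _row_scale_to_constant_coverage(dense)
        dense *= total / dense.sum()

    iu, ju = np.triu_indices(n, k=1)
    v = dense[iu, ju]
    nz = v > 0
    return ContactMatrix(
        bins, iu[nz], ju[nz], v[nz], normalization="raw", weights=None
    )


def sample_contacts(
    expected: ContactMatrix, depth: int, seed: int
) -> ContactMatrix:
    """Poisson-sample integer contact counts from an expected map.

    Per-pair counts are independent Poisson draws with mean proportional
    to the expected value, scaled so the total expectation equals
    ``depth``. Identical seeds give identical output.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    mu = expected.value * (depth / expected.total())
    counts = rng.poisson(mu).astype(float)
    nz = counts > 0
    return ContactMatrix(
        expected.bins,
        expected.bin1[nz],
        expected.bin2[nz],
        counts[nz],
        normalization="raw",
    )


def simulate_fish_pairs(
    spec: SyntheticGenomeSpec,
    model: GeneratorModel,
    lam: float,
    separations: list[int],
    n_nuclei: int,
    seed: int,
):
    """Simulate 3D probe-pair distances for the given genomic separations.

    For separation s the distance is ``d = A_f * (s/1Mb)^beta(lam) *
    exp(eps)`` with ``eps ~ N(0, fish_noise_sd)``; beta decreases with
    lambda (more condensin -> more compact at long range). Returns the
    observations and the planted (amplitude, beta) ground truth.
    """
    from pericentriq.fish import ProbePairObservation

    max_arm = max(a.length for a in spec.arms)
    if any(s <= 0 or s > max_arm for s in separations):
        raise ValueError("separations must be positive and within arm length")
    rng = np.random.default_rng(seed)
    beta = model.beta(lam)
    obs = []
    for pair_id, s in enumerate(separations):
        base = model.fish_amplitude * (s / 1e6) ** beta
        eps = rng.normal(0.0, model.fish_noise_sd, size=n_nuclei)
        dists = base * np.exp(eps)
        directions = rng.normal(size=(n_nuclei, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        for nuc in range(n_nuclei):
            a = np.zeros(3)
            b = directions[nuc] * dists[nuc]
            obs.append(
                ProbePairObservation(
                    nucleus_id=nuc,
                    pair_id=pair_id,
                    separation_bp=int(s),
                    centroid_a=tuple(a),
                    centroid_b=tuple(b),
                )
            )
    planted = {"amplitude": model.fish_amplitude, "beta": beta}
    return obs, planted
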