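"""End-to-end orchestration: simulate -> balance -> compartments ->
metrics -> differential / virtual 4C -> FISH, from a single YAML config
with deterministic per-stage seeds and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pericentriq import hic_io
from pericentriq.hic_io import Region, write_bedgraph, write_contacts
from pericentriq import synthetic
from pericentriq.synthetic import GeneratorModel, SyntheticGenomeSpec
from pericentriq import compartments as comp_mod
from pericentriq import metrics as metrics_mod
from pericentriq import differential as diff_mod
from pericentriq import fish as fish_mod

logger = logging.getLogger("pericentriq")

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "resolution",
    "lambdas",
    "depth",
    "model",
    "fish",
    "metrics",
    "tads",
    "v4c",
    "compartments",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "pericentriq_run"
    resolution: int = 5000
    lambdas: tuple[float, ...] = (0.5, 1.0, 2.0)
    depth: int = 1_000_000
    model: dict = field(default_factory=dict)
    fish: dict = field(default_factory=lambda: {"n_nuclei": 100})
    metrics: dict = field(default_factory=dict)
    tads: dict = field(default_factory=dict)
    v4c: dict = field(default_factory=lambda: {"n_controls": 3})
    compartments: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.lambdas, list):
            cfg.lambdas = tuple(cfg.lambdas)
        return cfg


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def add(self, name: str, outputs: dict[str, str], params: dict, t0: float) -> None:
        digests = {k: _digest(v) for k, v in outputs.items()}
        self.stages.append(
            {
                "stage": name,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "digests": digests,
                "params": params,
                "seconds": round(time.time() - t0, 3),
            }
        )

    def write(self, path: str | Path) -> None:
        payload = {"config": self.config, "stages": self.stages}
        # wall-clock varies run to run; digests are what determinism checks use
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global seed and stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _cond_name(lam: float) -> str:
    return f"lambda_{lam:g}".replace(".", "p")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on a synthetic genome; write outputs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))

    spec = SyntheticGenomeSpec.default(resolution=config.resolution)
    model = GeneratorModel(**config.model)
    gt = synthetic.ground_truth(spec)
    arms = {a.name: Region(a.name, 0, a.length) for a in spec.arms}
    cen_ends = {a.name: a.centromeric_end for a in spec.arms}

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    sampled = {}
    balanced = {}
    sim_outputs = {}
    for lam in config.lambdas:
        exp = synthetic.expected_map(spec, model, lam)
        seed = stage_seed(config.seed, f"simulate:{lam}")
        raw = synthetic.sample_contacts(exp, config.depth, seed)
        name = _cond_name(lam)
        bins_path = outdir / f"{name}_abs.bed"
        trip_path = outdir / f"{name}.matrix"
        write_contacts(raw, bins_path, trip_path)
        sim_outputs[f"{name}_bins"] = bins_path
        sim_outputs[f"{name}_matrix"] = trip_path
        sampled[lam] = raw
        logger.info("simulated %s: %d contacts", name, int(raw.total()))
    state_path = outdir / "state_track.bed"
    gt.state_track.to_csv(state_path, sep="\t", header=False, index=False)
    truth_path = outdir / "compartment_truth.bed"
    truth = gt.bins.table[["chrom", "start", "end"]].copy()
    truth["label"] = gt.labels
    truth.to_csv(truth_path, sep="\t", header=False, index=False)
    sim_outputs["state_track"] = state_path
    sim_outputs["compartment_truth"] = truth_path
    manifest.add(
        "simulate",
        sim_outputs,
        {"lambdas": list(config.lambdas), "depth": config.depth},
        t0,
    )

    # --- balance ------------------------------------------------------
    t0 = time.time()
    bal_outputs = {}
    for lam, raw in sampled.items():
        bal = hic_io.balance(raw)
        balanced[lam] = bal
        name = _cond_name(lam)
        wpath = outdir / f"{name}_weights.bedgraph"
        write_bedgraph(bal.bins, bal.weights, wpath)
        bal_outputs[f"{name}_weights"] = wpath
    manifest.add("balance", bal_outputs, {}, t0)

    # --- compartments (on the control condition) ----------------------
    t0 = time.time()
    control_lam = min(config.lambdas, key=lambda x: abs(x - 1.0))
    ctrl_bal = balanced[control_lam]
    eigs = [
        comp_mod.compute_eigenvectors(
            ctrl_bal,
            arms[name],
            state_track=gt.state_track,
            centromeric_end=cen_ends[name],
        )
        for name in arms
    ]
    min_len = config.compartments.get("min_len", 20_000)
    seg = comp_mod.call_compartments(eigs, min_len=min_len)
    pcall = comp_mod.kmeans_p_compartments(
        eigs,
        k=config.compartments.get("k", 3),
        seed=stage_seed(config.seed, "kmeans"),
        restarts=config.compartments.get("restarts", 20),
    )
    comp_outputs = {}
    seg_path = outdir / "compartments.bed"
    seg.to_frame().to_csv(seg_path, sep="\t", header=False, index=False)
    comp_outputs["compartments"] = seg_path
    for eig in eigs:
        pc_path = outdir / f"pc1_{eig.arm.chrom}.bedgraph"
        full = np.full(eig.bins.n_bins, np.nan)
        full[eig.bin_ids] = eig.pc1
        write_bedgraph(eig.bins, full, pc_path)
        comp_outputs[f"pc1_{eig.arm.chrom}"] = pc_path
    scree_path = outdir / "kmeans_scree.tsv"
    pcall.scree.to_csv(scree_path, sep="\t", index=False)
    comp_outputs["scree"] = scree_path
    manifest.add(
        "compartments",
        comp_outputs,
        {"min_len": min_len, "k": config.compartments.get("k", 3)},
        t0,
    )

    # --- metrics ------------------------------------------------------
    t0 = time.time()
    cutoff = config.metrics.get("cutoff", 1_000_000)
    min_sep = config.metrics.get("min_sep", 500_000)
    max_sep = config.metrics.get("max_sep", 5_000_000)
    rows = []
    for lam in config.lambdas:
        for name, arm in arms.items():
            slr = metrics_mod.short_long_ratio(balanced[lam], arm, cutoff=cutoff)
            rows.append((lam, name, "short_long_ratio", slr))
        tp = metrics_mod.trans_proportion_matrix(sampled[lam])
        chroms = list(tp.index)
        rows.append(
            (lam, f"{chroms[0]}-{chroms[1]}", "trans_proportion",
             float(tp.iloc[0, 1]))
        )
    metrics_df = pd.DataFrame(rows, columns=["lambda", "region", "metric", "value"])
    metrics_path = outdir / "metrics.tsv"
    metrics_df.to_csv(metrics_path, sep="\t", index=False)

    ctrl_scores = metrics_mod.compartment_pair_scores(
        ctrl_bal, seg, min_sep=min_sep, max_sep=max_sep
    )
    fc_rows = []
    for lam in config.lambdas:
        if lam == control_lam:
            continue
        kd_scores = metrics_mod.compartment_pair_scores(
            balanced[lam], seg, min_sep=min_sep, max_sep=max_sep
        )
        for s in metrics_mod.fold_change(kd_scores, ctrl_scores):
            fc_rows.append(
                (lam, s.comp_i, s.comp_j, s.pair_class, s.separation,
                 s.mean, s.fold_change, s.percent_change)
            )
    fc_df = pd.DataFrame(
        fc_rows,
        columns=["lambda", "comp_i", "comp_j", "class", "separation",
                 "mean", "fold_change", "percent_change"],
    )
    fc_path = outdir / "compartment_pair_fold_changes.tsv"
    fc_df.to_csv(fc_path, sep="\t", index=False)
    manifest.add(
        "metrics",
        {"metrics": metrics_path, "fold_changes": fc_path},
        {"cutoff": cutoff, "min_sep": min_sep, "max_sep": max_sep},
        t0,
    )

    # --- TADs ---------------------------------------------------------
    t0 = time.time()
    window = config.tads.get("window", 100_000)
    prominence = config.tads.get("prominence", 0.1)
    tad_sets = {
        lam: diff_mod.insulation_boundaries(balanced[lam], window, prominence)
        for lam in config.lambdas
    }
    tad_outputs = {}
    for lam, ts in tad_sets.items():
        path = outdir / f"{_cond_name(lam)}_domains.bed"
        ts.domains.to_csv(path, sep="\t", header=False, index=False)
        tad_outputs[f"{_cond_name(lam)}_domains"] = path
    cls_rows = []
    for lam in config.lambdas:
        if lam == control_lam:
            continue
        cmp_res = diff_mod.classify_boundaries(tad_sets[control_lam], tad_sets[lam])
        for cat, n in cmp_res.counts.items():
            cls_rows.append((lam, cat, n))
    cls_path = outdir / "boundary_classes.tsv"
    pd.DataFrame(cls_rows, columns=["lambda", "category", "count"]).to_csv(
        cls_path, sep="\t", index=False
    )
    tad_outputs["boundary_classes"] = cls_path
    manifest.add(
        "tads", tad_outputs, {"window": window, "prominence": prominence}, t0
    )

    # --- virtual 4C ---------------------------------------------------
    t0 = time.time()
    first_arm = spec.arms[0]
    anchor = first_arm.p_region()
    arm_region = arms[first_arm.name]
    n_controls = config.v4c.get("n_controls", 3)
    controls = diff_mod.size_matched_controls(
        anchor,
        arm_region,
        n_controls,
        exclusions=[anchor],
        seed=stage_seed(config.seed, "v4c"),
        grid=config.resolution,
    )
    v4c_rows = []
    profiles = {}
    for lam in config.lambdas:
        prof = diff_mod.virtual_4c(
            balanced[lam], anchor, arm_region, condition=_cond_name(lam)
        )
        profiles[lam] = prof
        path = outdir / f"v4c_p_{_cond_name(lam)}.bedgraph"
        full = np.full(prof.bins.n_bins, np.nan)
        full[prof.target_bin_ids] = prof.values
        write_bedgraph(prof.bins, full, path)
    high = max(config.lambdas)
    if high != control_lam:
        mean_p, sd_p, _ = diff_mod.v4c_difference(profiles[high], profiles[control_lam])
        v4c_rows.append(("P", mean_p, sd_p))
        for ci, ctrl_region in enumerate(controls):
            prof_hi = diff_mod.virtual_4c(balanced[high], ctrl_region, arm_region)
            prof_lo = diff_mod.virtual_4c(balanced[control_lam], ctrl_region, arm_region)
            m, s, _ = diff_mod.v4c_difference(prof_hi, prof_lo)
            v4c_rows.append((f"control_{ci + 1}", m, s))
    v4c_path = outdir / "v4c_differences.tsv"
    pd.DataFrame(v4c_rows, columns=["anchor", "mean_diff", "sd_diff"]).to_csv(
        v4c_path, sep="\t", index=False
    )
    manifest.add("v4c", {"differences": v4c_path}, {"n_controls": n_controls}, t0)

    # --- FISH ---------------------------------------------------------
    t0 = time.time()
    seps = config.fish.get(
        "separations", [int(s) for s in np.geomspace(2e5, 4.5e6, 12)]
    )
    n_nuclei = config.fish.get("n_nuclei", 100)
    fish_rows = []
    for lam in config.lambdas:
        obs, planted = synthetic.simulate_fish_pairs(
            spec, model, lam, seps, n_nuclei,
            seed=stage_seed(config.seed, f"fish:{lam}"),
        )
        fit = fish_mod.power_law_fit([(o.separation_bp, o.distance) for o in obs])
        fish_rows.append(
            (lam, planted["beta"], fit.exponent, fit.se_exponent, fit.amplitude)
        )
    fish_path = outdir / "fish_power_law.tsv"
    pd.DataFrame(
        fish_rows,
        columns=["lambda", "planted_beta", "fitted_beta", "se_beta", "amplitude"],
    ).to_csv(fish_path, sep="\t", index=False)
    manifest.add("fish", {"power_law": fish_path}, {"n_nuclei": n_nuclei}, t0)

    manifest.write(outdir / "manifest.json")
    return manifest
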