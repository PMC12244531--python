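# pericentriq

Quantification of how condensin II activity reshapes long-range chromatin
architecture, from Hi-C contact matrices and 3D FISH observations.

Interphase condensin II compacts chromosomes at large length scales: raising
its level (e.g. by depleting SLMB, the adaptor that degrades its Cap-H2
subunit) shifts contacts toward longer genomic ranges, strengthens
interactions between distant A/B compartments, and sends stripes of
interaction out of the pericentric heterochromatin ("P") compartment across
the whole chromosome; lowering it (Cap-H2 depletion) does the opposite while
*increasing* inter-chromosomal background contact. `pericentriq` implements
the full analysis stack needed to measure these phenotypes — and a forward
model with a planted condensin-activity parameter λ so that every stage can
be validated against known ground truth. It is intended for chromatin
biologists analysing uniform-bin Hi-C data (HiC-Pro-style bin/triplet text
matrices) together with Oligopaint FISH label volumes and spot tables.

## What it computes

| Stage | Module | Core quantities |
|---|---|---|
| I/O & normalization | `pericentriq.hic_io` | bin tables, sparse upper-triangle contacts, iterative-correction balancing, observed/expected, coarsening |
| Forward model | `pericentriq.synthetic` | expected maps with planted compartments, P domain, stripe amplitude and decay exponent α(λ); Poisson sampling; FISH distance simulation |
| Compartments | `pericentriq.compartments` | arm-wise O/E correlation eigenvectors, A/B calls from the PC1 sign (≥20 kb runs), k-means P-compartment from the first three components |
| Contact statistics | `pericentriq.metrics` | P(s) curves and crossovers, short/long (<1 Mb / ≥1 Mb) ratios, trans proportions, chromatin-state-stratified strengths, numbered compartment-pair scores and fold changes, HiCRep-style SCC (h=20, ≤20 Mb) |
| Differential structure | `pericentriq.differential` | log2 differential maps, insulation TAD boundaries, boundary-change classes (Same ≤10 kb, Shift 15–70 kb, Lost/Gained, Split/Merge), virtual 4C with size-matched control anchors |
| FISH | `pericentriq.fish` | 3D domain counts, voxel-face surface areas, intermixing fractions, probe-pair contact frequency and minimum distances, power-law distance scaling d = A·s^β |
| Orchestration | `pericentriq.pipeline`, `pericentriq.cli` | YAML-configured end-to-end runs with deterministic per-stage seeds and a digest manifest |

The model at the core of the synthetic calibration: a cis pair at separation
*s* bins has expected contact `B[c_i,c_j] · s^(−α(λ))`, with
`α(λ) = α₀ − κ·log₂λ` (more condensin → shallower decay), a stripe factor
`1 + σ(λ−1)` on pairs with exactly one end in the P compartment, and a trans
background `τ₀·λ^(−γ)`; rows are scaled to constant coverage. FISH distances
follow `d = A_f·(s/1 Mb)^β(λ)·e^ε` with β decreasing in λ.

## Worked example

```python
import numpy as np
from pericentriq import synthetic, metrics, compartments
from pericentriq.hic_io import Region, balance

spec = synthetic.SyntheticGenomeSpec.default()      # 2 arms x 5 Mb, 5 kb bins
model = synthetic.GeneratorModel()                  # alpha0=1.0, kappa=0.3
arm = Region("armL", 0, 5_000_000)

for lam in (0.5, 1.0, 2.0):
    emap = synthetic.expected_map(spec, model, lam)
    ratio = metrics.short_long_ratio(emap, arm)
    trans = metrics.trans_proportion(emap, "armL", "armR")
    print(f"lambda={lam:3g}  short/long={ratio:6.2f}  trans fraction={trans:.4f}")

raw = synthetic.sample_contacts(synthetic.expected_map(spec, model, 1.0),
                                depth=1_000_000, seed=1)
bal = balance(raw)
curve = metrics.ps_curve(bal, arm)
slope = metrics.fit_ps_slope(curve, 10_000, 100_000)
print(f"fitted P(s) slope: {slope:.3f}  (planted alpha = {model.alpha(1.0):.2f})")

truth = synthetic.ground_truth(spec)
eig = compartments.compute_eigenvectors(
    bal, arm, state_track=truth.state_track, centromeric_end="right")
seg = compartments.call_compartments(eig, min_len=20_000)
print(f"{len(seg)} compartments on armL:",
      " ".join(c.name for c in seg.compartments))
```

prints

```
lambda=0.5  short/long= 39.76  trans fraction=0.0638
lambda=  1  short/long= 10.00  trans fraction=0.0291
lambda=  2  short/long=  2.85  trans fraction=0.0096
fitted P(s) slope: -1.010  (planted alpha = 1.00)
26 compartments on armL: A1 B1 A2 B2 A3 B3 A4 B4 A5 B5 A6 B6 A7 B7 A8 B8 A9 B9 A10 B10 A11 B11 A12 B12 A13 B13
```

Reading the output: as the condensin-activity parameter λ rises from 0.5 to
2, the short-to-long contact ratio falls (contacts redistribute to ≥1 Mb
ranges) and the fraction of a chromosome arm's signal that is
inter-chromosomal falls — the two signature directions of condensin II gain.
The P(s) log-log slope fitted from a million sampled contacts recovers the
planted control decay exponent (−1.0), and eigenvector compartment calling
on the same sampled matrix recovers the planted alternation of A/B blocks
(A1, B1, A2, …, numbered per type along the arm).

The same stages are exposed on the command line:

```bash
pericentriq simulate --lam 0.5 --lam 1 --lam 2 --depth 1000000 --seed 1 -o sim
pericentriq balance sim/lambda_1_abs.bed sim/lambda_1.matrix -o bal
pericentriq compartments sim/lambda_1_abs.bed sim/lambda_1.matrix \
    --arm armL:0-5000000 --state-track sim/state_track.bed -o cc
pericentriq run config.yaml        # full pipeline from a YAML config
```

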