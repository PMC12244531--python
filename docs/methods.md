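# Methods

This note documents the models, defaults, numerical choices and known
limitations of `pericentriq`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Contact-matrix representation and balancing

Contact data live as a uniform bin table (0-based, half-open; dense
`bin_id` 0..N−1 in genome order) plus upper-triangle triplets
`(bin_i ≤ bin_j, value ≥ 0)`, the HiC-Pro matrix/abs-bed text dialect.
Lower-triangle input is folded upward on read and duplicate pairs are
summed, tolerating dialect differences. Coordinates are 0-based half-open
everywhere internally.

Balancing uses iterative correction (symmetric proportional fitting): each
sweep divides every pair by the geometric mean of its two bins' relative
marginals until the maximum relative marginal deviation falls below `tol`
(default 1e−7, cap 3000 sweeps; non-convergence raises an error carrying the
last deviation). Iterative correction was chosen over KR because the
analyses depend only on the balanced-marginal property, and the
post-condition (equal marginals) is directly assertable. Bins with zero raw
marginal, or whose nonzero-pair count is below 2% of the densest bin's
(configurable), are masked before correction and carry no triplets
afterwards. Strongly striped maps converge more slowly than typical
matrices, hence the generous sweep cap.

Observed/expected divides each cis pair by its diagonal's mean over all
unmasked pairs at that separation (zeros included). Diagonals with no valid
pairs or no signal are flagged missing (NaN), never zero-filled, so an O/E
of an O/E is the identity on the defined entries.

## The synthetic forward model

The generator plants every quantity the pipeline is later asked to recover.
The default genome is two 5 Mb arms ("armL", "armR") at 5 kb resolution
(2,000 bins) flanking a centromere: each arm carries a 1 Mb terminal P
(pericentric heterochromatin) domain at its centromeric end and ten
alternating 400 kb A/B blocks. The chromatin-state track maps A→active and
alternates B blocks between repressed and null, with P null — giving the
eigenvector orientation an independent reference, as state annotations do
for real data.

Expected contact for a cis pair at separation *s* bins:

    E[i,j] = B[c_i, c_j] · s^(−α(λ)) · stripe(λ)        (cis)
    E[i,j] = B[c_i, c_j] · τ₀ · λ^(−γ) · stripe(λ)      (trans)

with `α(λ) = α₀ − κ·log₂λ` and `stripe(λ) = 1 + σ(λ−1)` applied when
exactly one end lies in P (cis *and* trans; a stripe emanating from the
pericentric domain crosses the centromere, so trans pairs touching one P
carry it, while P-to-opposing-P pairs follow the trans background).
Self-pairs are excluded. Rows are then symmetrically scaled to constant
per-bin coverage — so the short-range/long-range trade-off emerges from the
single exponent α — while conserving the map's total intensity. Maps at
different λ therefore stay on the model's absolute propensity scale rather
than being forced to a common depth; sequencing depth is modelled separately
by Poisson sampling (`sample_contacts`), which scales the expectation to a
target total count.

Defaults: α₀ = 1.0, κ = 0.3 (so α ∈ {1.3, 1.0, 0.7} over λ ∈ {0.5, 1, 2},
all inside the admissible (0.2, 2.5) band), σ = 1.0,
τ₀ = 5% of the control cis level at 1 Mb, γ = 0.5, affinities
A-A = B-B = 1.5, A-B = 0.7, P-P = 3.0, P-A = P-B = 1.0. These produce clear
checkerboarding and a strongly self-interacting, insulated P domain in the
control condition. γ = 0.5 rather than 1: with γ = 1 and σ = 1 the trans
stripe factor at λ = 0.5 exactly cancels the trans background gain
(0.5 × 2 = 1), leaving P-emanating trans contacts flat instead of
directional; γ = 0.5 keeps the global trans trend (decreasing in λ) while
letting the stripe dominate contacts that touch one P domain.

Count noise is Poisson per pair — the standard shot-noise assumption for
uniquely mapped read pairs; overdispersion from library complexity is not
modelled.

FISH distances for a probe pair at genomic separation *s* are drawn as
`d = A_f · (s/1 Mb)^β(λ) · exp(ε)`, `ε ~ N(0, 0.25)`,
`β(λ) = 0.33 − 0.05·log₂λ`, `A_f = 0.4 µm` — scaling amplitude and exponent
in the range reported for ~0.1–5 Mb chromatin in diploid insect nuclei, with
log-normal nucleus-to-nucleus variability. Note that because the power laws
for different λ cross near s = 1 Mb, the compaction ordering is a
*long-range* statement, matching the biology (short-range distances respond
oppositely).

### What the generator does and does not emulate

It emulates: power-law cis decay with compartment-dependent affinity, a
terminal self-interacting P domain with condensin-dependent stripes, a trans
background falling with condensin activity, and power-law FISH distances.
It does **not** emulate polymer/loop-extrusion dynamics, homolog pairing
(single-copy genome), TAD-scale insulation structure (TAD callers are tested
on separately constructed block toys), translocations, or mappability
artifacts. Passing recovery tests therefore demonstrates estimator
correctness under the planted model, not robustness to every real-data
pathology.

## Compartment calling

Per arm, the balanced O/E map is smoothed with a 2D running mean of
half-window 1 bin (a 15 kb window at 5 kb resolution — the analogue of
computing the PCA at a coarser "super-resolution", which stabilises the
second and third components on sparse maps; configurable, 0 disables), then
converted to a Pearson correlation matrix over informative bins and
eigendecomposed. PC1 is oriented so active-state bins have positive mean;
bins masked, empty, or with degenerate (constant) O/E rows carry NaN.

Because eigenvector signs are arbitrary per arm, PC2 and PC3 are
additionally sign-anchored so the centromere-proximal tenth of each arm is
positive. Without this, jointly clustering several arms can split clusters
by arm rather than by compartment type whenever two arms' pericentric
signatures land with opposite signs (observed in roughly one in eight
sampled datasets before anchoring; recovery is stable across seeds after).

A/B calls are maximal same-sign PC1 runs of at least 20 kb; shorter runs
are absorbed into the larger flanking run (ties upstream), which keeps the
calls a partition. Compartments are numbered per type consecutively along
the genome (A1, A2, …, B1, …), the numbering used by compartment-pair
scoring.

The P compartment is defined by k-means (k = 3 by default, k-means++
initialisation, 20 restarts, seed recorded) on the first three components
stacked across arms. The P cluster is the one whose bins lie closest on
average to their arm's declared centromeric end; each arm's P interval is
its largest contiguous run of P-cluster bins. An inertia-versus-k table is
emitted for scree inspection. k = 1 warns and calls no P.

## Contact statistics

* **P(s)**: per-diagonal means (zeros over unmasked pairs included)
  aggregated into log-spaced shells, 8 per decade; the reported curve is
  normalised to sum to 1 with the factor recorded. Decay-exponent fits use
  the 10–100 kb window: at larger separations the alternating-block
  affinity structure modulates the per-shell mean affinity (the same-type
  pair fraction falls from ~1 within a block toward ~0.5 and oscillates
  with the block period), biasing a wide-window slope by ~0.1; below a
  quarter block length the composition is nearly constant and the planted
  exponent is recovered to better than ±0.02 on expected maps and ±0.05
  after sampling at depth 10⁶.
* **Crossover** of two P(s) curves: smallest sign change of the
  log-difference, linearly interpolated in log-log space; equal or
  proportional normalised curves yield a none-result.
* **Short/long ratio**: cis signal below versus at-or-above the cutoff
  (default 1 Mb; a pair exactly at the cutoff is long-range), self-pairs
  excluded.
* **Trans proportions**: on raw matrices, S(A→B)/ΣS(A→·) per source
  chromosome, cis included in the denominator; rows sum to 1 exactly.
* **State-stratified strength**: bins take the state covering the majority
  of their bases; pairs at exactly the requested separation where both bins
  share a state contribute their balanced value (zeros included);
  mixed-state pairs are excluded.
* **Compartment-pair scores**: for each control-segmentation pair on one
  chromosome with midpoint separation inside [500 kb, 5 Mb] (both bounds
  configurable; a wider ≥300 kb window is one setting away), the mean
  balanced value over all unmasked bin pairs. Fold change is per pair,
  KD/control, with percent change (fold − 1)·100; zero-control pairs are
  flagged undefined. Both per-pair and aggregate summaries can be formed
  from the returned records.
* **SCC**: per chromosome, both cis maps are mean-filtered with half-window
  h (default 20 bins), then per-separation-stratum Pearson correlations up
  to 20 Mb are combined with the variance-stabilised weights
  `N_d·sqrt(var(rank x)·var(rank y))`. h = 0 reduces to the unsmoothed
  stratum correlation; scc(X, X) = 1 identically.

## Differential structure

Differential maps are `log2((kd+p)/(ctrl+p))` over the union of stored
pairs after scaling both conditions to equal totals; the default
pseudocount is 1e−3 × the scaled control mean, chosen small enough to
leave well-covered pairs untouched while keeping empty pairs finite;
antisymmetry under condition swap is exact.

TAD boundaries are minima of the diamond insulation score (window 100 kb
default, ≥3 bins) in log2-relative units, detected with prominence ≥ 0.1
within each contiguous stretch of defined scores (edge bins, where the
diamond does not fit, are undefined — not zero). Domains are the induced
partition of the chromosome including terminal segments, so a two-block toy
with one junction yields two domains of the planted sizes.

Boundary classification matches control to KD boundaries greedily by
distance, one-to-one, up to 70 kb: ≤10 kb → Same, 15–70 kb → Shift. The
10–15 kb gap is unreachable on a 5 kb grid but is reported as an explicit
"Unclassified" bucket rather than silently binned; matches beyond 70 kb do
not form and the boundaries count as Lost + Gained. Split = a control
domain wholly containing ≥2 KD domains; Merge symmetric — one reasonable
reading of category names that are otherwise undefined. Counts conserve
boundaries: |ctrl| = Same + Shift + Unclassified + Lost, analogously for KD.

Virtual 4C averages balanced values from all unmasked anchor bins to each
target bin (zeros included); anchor-internal bins are flagged and excluded
from profile differences. Size-matched control anchors are placed uniformly
at random (seeded, bin-grid aligned), overlapping neither the true anchor
nor exclusion intervals such as the P compartment; controls may overlap
*each other* unless `disjoint=True`, since rejection sampling cannot pack
three disjoint 1 Mb controls into the 4 Mb non-P span of the default arm.

One representation subtlety, documented because it affects how the
P-anchor comparison should be run: on this compact genome the P domain is
20% of all bins, so coverage equalisation reallocates much of the planted
stripe amplitude into the per-bin scale factors. The absolute per-bin
virtual-4C difference (λ = 2 − control) then ranks the P anchor above
size-matched controls on the *propensity* maps
(`expected_map(..., row_scale=False)`), while on coverage-equalised maps
the same ranking holds in per-bin log2-fold terms (≈3.5 versus ≈2.4–2.6
mean log2-fold in the default conditions). Both comparisons are asserted;
differences are always measured over the non-pericentric targets that all
anchors share. On real genomes, where the pericentric domain is a far
smaller fraction of the map, balancing perturbs the stripe much less.

## FISH quantification

Domain counting uses 3D connected components at 26-connectivity by default
(6 available). Surface areas sum exposed voxel faces with per-axis face
areas, respecting anisotropy, so closed forms are exact (a single 1 µm
voxel is 6 µm²) and areas scale quadratically with voxel edge. The
intermixing fraction |a∩b|/|a| is deliberately directional; compute both
directions when both matter. Contact defaults to the overlap criterion
(≥1 shared voxel), with a centroid-distance mode for spot-only data.
Minimum distances take the global minimum over all focus combinations, so
diploid homolog pairs are handled. The power-law fit is ordinary least
squares in log-log space — exact on noiseless input and unbiased (mean
exponent bias < 0.02 at n = 500 over 200 replicates) — aggregating
per-separation medians by default (`aggregate="none"` fits every nucleus;
the choice between the two is exposed because either convention is
defensible for per-nucleus data).

## Pipeline determinism

`run_pipeline` derives each stage's seed from the single global seed by
hashing the stage name, so adding a stage cannot shift another stage's
randomness; the manifest records per-output SHA-256 digests, and identical
config + seed reproduce identical digests. Unknown config keys are rejected
before any stage runs.

## Problem sizes

The validation study runs at 2,000 bins (two 5 Mb arms at 5 kb) and 10⁶
sampled contacts — small enough that every stage, including balancing the
strongly striped λ = 2 condition, completes in seconds, while leaving the
planted compartment and P-domain signals comfortably above the sampling
noise floor (A/B sign agreement ≥99%, P-cluster purity 95–99% across
seeds). FISH recovery uses 20 separations × 25 nuclei (n = 500) per
condition and 100 replicate pairs for the β-ordering rate.

## Known limitations

* The balancing mask is a sparsity heuristic, not a mappability track.
* Insulation boundaries use a single window; no multi-scale consensus or
  FDR, since the boundary-change taxonomy, not the caller, is the reusable
  analysis.
* The eigenvector orientation requires a state track (or falls back to
  unoriented signs); GC-content orientation is not implemented.
* k-means P designation assumes the centromeric end of each arm is
  declared; it will mislabel acrocentric arms described with the wrong
  polarity.
* The FISH simulator emits single foci per probe; multi-focus (homolog)
  observations are handled by the metrics but not generated.
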