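# Methods

`nmdp` implements a per-drug response classifier for multi-omics cell-line
cohorts.  The model's core idea is that each drug is predicted by its own
small, pathway-coherent probe panel, selected per omics with a
semi-supervised sparse principal component, and that samples are then
represented not by raw probe values but by their rank-correlation
similarity to the training cohort, with the per-omics similarity networks
fused by data-driven weights before a compact convolution + KAN classifier.

## IC50 binarization (waterfall rule)

Per drug, finite IC50 values are sorted ascending and regressed on their
ranks 1..n.  If the Pearson correlation of that fit exceeds 0.95 the curve
has no usable elbow and the median splits the cohort; otherwise the cutoff
is the sorted value with the largest perpendicular distance to the chord
joining the curve's endpoints (vertical distance is available behind a
flag).  Responsive means IC50 ≤ cutoff: a lower inhibitory concentration
indicates a more sensitive line.  If fewer than 25% of samples come out
responsive, the cutoff is raised to the 25th percentile rather than
dropping samples — this keeps every cohort usable and is deterministic; a
strict mode that skips the drug instead is available.  Drugs with fewer
than `min_samples` (default 200, overridable for small cohorts) finite
measurements are skipped.

## Semi-supervised weighted edge sparse PCA

For one omics matrix `X` (probes × samples) and a pathway edge set, a
rank-one power iteration alternates:

1. `u ← X v`;
2. per-edge weights `w_h = u_i² + u_j²` (the squared form as the default;
   the square-root variant is a flag — rankings are identical);
3. greedy projection with oversampling: rank edges by weight (ties to the
   lower index, which keeps seeded runs reproducible), keep the top
   `ceil((1+ω)k)`, draw `k` of them uniformly without replacement, and zero
   `u` off the sampled edges' vertices.  ω decays by ρ each iteration,
   floored at 0, so the pool anneals from exploratory to greedy;
4. supervised reweighting: a seeded random forest (200 trees,
   `max_features=1`) is fit on the currently selected probes against the
   binary response labels; its importances, min–max rescaled to [0, 2],
   multiply `u` entrywise.  A logistic alternative (`evaluator="linear"`)
   and an unsupervised mode (`evaluator=None`) are provided;
5. renormalize `u`, update `v = Xᵀu/‖Xᵀu‖`, and stop when
   `‖u − u_prev‖₂ < tol` (default 1e-4, capped at `max_iter=100`).

Further components are extracted after Hotelling deflation
`X ← X − u(uᵀX)`; the key matrix is the original rows indexed by the union
of the component supports.

Parameter choices that were genuinely open:

* **ω = 1.0, ρ = 0.1.**  The candidate pool must be wide enough early on
  that label-informative edges enter the support even when a
  label-independent component carries more variance; with a pool of only
  1.5k edges the supervised reweighting can never see the signal edges it
  is supposed to boost.  A pool of 2k edges annealing to k over ten
  iterations proved stable.
* **`max_features=1` in the forest.**  With ~20 correlated candidate
  probes, default candidate pools let trees ignore weaker informative
  probes entirely; an exact zero importance deletes the probe from the
  support through the [0, 2] rescaling.  Fully random split candidates give
  every informative probe a positive importance.
* **Degenerate importances** (constant vector, single-class labels) fall
  back to all-ones reweighting with a warning.
* `v` is initialized standard-normal (seeded) and unit-normalized.

## Similarity networks

Each key matrix becomes an anchors × queries matrix of rank correlations
between sample probe-vectors: Spearman (rank-transform, then Pearson) for
expression and methylation, Kendall for copy number.  Kendall defaults to
tau-a, `(C − D)/(k(k−1)/2)`; tau-b is a flag for tie-heavy data.  The whole
tau matrix is computed as one inner product of per-sample pairwise sign
vectors.  Anchors are always training samples: a test sample's features are
its similarities to the training cohort, so test samples never influence
each other or the training representation.

## Dip-and-variance fusion

The three similarity blocks are summed entrywise with per-block weights
`α_i · β_i`:

* **α (bimodality).**  Hartigan's dip statistic is computed on the block's
  off-diagonal entries (subsampled to at most 1000, seeded).  The dip is
  the minimal sup-distance between the ECDF and any unimodal CDF, computed
  exactly by the iterative greatest-convex-minorant / least-concave-majorant
  construction; it is validated in the test suite against an exhaustive
  linear-programming oracle on small samples and satisfies
  `1/(2n) ≤ dip ≤ 1/4`.  Tied values are separated by an infinitesimal
  deterministic perturbation (the statistic targets continuous data).
  p-values come from a seeded Monte-Carlo uniform null (default 2000
  draws), cached per sample size.  The raw α score is `1 − p`, a continuous
  version of the significant-bimodality threshold (p < 0.05) which is still
  reported; a hard threshold would discard blocks entirely, a continuous
  weight only demotes them.
* **β (dispersion).**  Mean per-column sample variance (denominator n − 1)
  of the block.

Both raw vectors are independently rescaled to `[a, b] = [0.5, 1.5]`
(user-configurable); if all raw scores tie, everything maps to `(a+b)/2`
with a warning.  Weights are fitted on training-anchor blocks only and then
applied frozen to anchor × query blocks.

## Conv1D + KAN classifier

Each sample's fused row (length = number of training anchors) is
standardized, passed through one 1D convolution (default 2 channels, kernel
5, same padding), ReLU, max-pool 2, and two KAN layers (flat → 4 → 1).  A
KAN layer computes `out_q = Σ_p φ_qp(x_p)` with
`φ(x) = w₁·spline(x) + w₂·b(x)`: a cubic B-spline on an 8-interval grid
over [−1, 1] (linear continuation outside) plus a SiLU residual (identity
optional), all coefficients learnable.  Training is full-batch-shuffled
mini-batch Adam (lr 1e-3, batch 16, 200 epochs) on binary cross-entropy,
with an optional validation split + patience for early stopping (off by
default: with ~100 training samples the split costs more than it saves).
The default network stays under 50k parameters — the point of the KAN head
is accuracy at a parameter budget compatible with small cohorts.  The whole
network is implemented in numpy with hand-written gradients (checked
against finite differences in development) and a hand-written Adam; at this
scale a GPU framework adds nothing.

Ablation switches mirror the component study: `no-weighting` (α = β = 1),
`no-conv` (KAN directly on the fused row), `no-similarity` (concatenated
key-matrix columns as features), `mlp-head` (equal-parameter SiLU MLP).
Switches are one-at-a-time by design.

## Synthetic cohorts

The generator is the package's test substrate and defines its study
conditions: 120 samples; expression / copy-number / methylation blocks of
150 / 180 / 220 probes, the first 80 rows of each being a shared gene
universe; a pathway of 10 planted signal edges, 10 decoy edges and 60
background edges (background edges never join two genes of the same
planted component — the planted pairs are that component's connectivity).
A latent sensitivity factor `z ~ N(0,1)` shifts signal-gene rows in every
block (effect 1.5 in expression, ×0.6 in the others, per-gene loadings
U(0.8, 1)) and sets `log-IC50 = 5 − 2z + N(0, 0.3)`.  Decoy-edge genes
respond, in expression only, to an independent latent with amplitude
1.2 × effect: variance alone prefers the decoy support, only the labels
point at the planted one — this is what makes the semi-supervision
measurable.  The methylation block carries a two-group mean shift (±0.5 on
a random 60% of probes) aligned with the response dichotomy, so its
similarity entries are bimodal — realizing the premise that bimodal
similarity reflects responder subgroups.  The copy-number block's
non-pathway probes follow a continuous factor (strength 1.4) that spreads
its similarity entries without being selectable (no pathway edges touch
those probes).  All randomness flows from one integer seed.

What the generator does not emulate: real GDSC-scale probe counts
(10⁴–10⁵ rows), probe-level annotation structure (multi-probe genes,
CpG-to-gene maps), inter-gene correlation beyond the planted components,
non-Gaussian marginals, batch effects, and missing data beyond what the
reader's imputation path is tested with.  Passing tests therefore
demonstrate correctness of the algorithms and the advertised qualitative
behaviors at desk scale, not clinical performance.

## Evaluation protocol

Stratified 5-fold cross-validation, seeded; labels are computed from IC50
once per drug (the binarization uses no omics data), while selection,
anchors, fusion weights and classifier training are re-fit inside each
fold from training samples only.  Reports carry per-class sensitivity,
specificity, precision, F1 and accuracy, per fold and averaged, and are
byte-identical for identical config + seed.  Benchmarks in
`nmdp.acceptance` re-run every stage against independent oracles (LP dip,
pair-enumeration Kendall, rank-then-Pearson Spearman, exhaustive elbow
scan, double-loop KAN/conv references) and planted ground truth
(support-recovery Jaccard, fusion-weight designations, end-to-end accuracy
with a label-shuffled control); `scripts/acceptance.py` writes them as
JSON.  Problem sizes there (1000 dip instances, 200 kernel pairs and
curves, 20 recovery cohorts, 50 fusion cohorts, one full pipeline with
shuffled control) are the package's chosen validation conditions.

## Known limitations

* The dip implementation assumes effectively continuous data; heavy ties
  are resolved by an order-preserving perturbation rather than a tie-aware
  null.
* Gene-to-probe mapping is exact identifier match; multi-probe genes and
  CpG annotation are out of scope.
* The supervised reweighting can occasionally trade the variance objective
  for label alignment; `uᵀXv` is not guaranteed monotone across iterations.
* Single-drug models only; no combination-therapy response.
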