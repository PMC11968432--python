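# nmdp

Per-drug response prediction from multi-omics cell-line cohorts.

Pharmacogenomic screens measure, for each drug, an IC50 (the concentration
inhibiting half of cell viability — lower means more sensitive) across
hundreds of cell lines, each profiled with gene expression, copy-number and
methylation data.  Predicting the responsive/non-responsive dichotomy from
those profiles is a small-sample, high-dimensional, multi-block problem.
`nmdp` is for computational biologists who want a tested, reusable
implementation of one answer to it: per-drug, pathway-constrained feature
selection, similarity-network data fusion, and a compact
convolution + Kolmogorov–Arnold classifier.

## The model

1. **Labeling (waterfall rule).**  Sort a drug's IC50 values and regress
   them on rank; if Pearson *r* > 0.95, cut at the median, otherwise at the
   point furthest from the chord through the curve's endpoints.  Responsive
   = IC50 ≤ cutoff, with the responsive group kept ≥ 25% of the cohort.

2. **Semi-supervised weighted edge sparse PCA.**  For each omics matrix
   *X* ∈ ℝ^{m×n} and pathway edge set *G*, solve

       max  uᵀXv   s.t. ‖u‖₂ = ‖v‖₂ = 1,  supp(u) ⊆ vertices of k edges of G

   by power iteration with a greedy randomized edge projection (edge weight
   w_h = u_i² + u_j², oversampling pool ⌈(1+ω)k⌉ annealing with ω ← ω − ρ),
   where after each cycle a seeded random forest fit on the currently
   selected probes against the response labels reweights *u* by its
   importances (rescaled to [0, 2]).  The labels steer the support, so each
   drug gets its own probe panel.  Components after the first follow
   Hotelling deflation.

3. **Similarity networks + fusion.**  Each selected key matrix becomes a
   sample × training-anchor rank-correlation matrix (Spearman for
   expression/methylation, Kendall for copy number), and the blocks are
   fused entrywise as X′ = Σᵢ αᵢβᵢ·blockᵢ, where α rewards bimodal
   similarity distributions (Hartigan dip test, Monte-Carlo p-values) and β
   rewards dispersion (mean column variance), both rescaled to [0.5, 1.5].

4. **Classifier.**  Each fused row passes through a 1D convolution and two
   KAN layers — learnable per-edge functions φ(x) = w₁·spline(x) + w₂·SiLU(x)
   summed over inputs — under 50k parameters, trained with Adam on binary
   cross-entropy.  Evaluation is stratified 5-fold cross-validation with
   strict training-anchor isolation.

A seeded synthetic-cohort generator (`nmdp.synthetic`) plants
pathway-structured, label-linked signal plus adversarial structure (a
higher-variance decoy component, a bimodal block, a high-variance block)
and is the substrate for every test.  See `docs/methods.md` for the full
model account and design rationale.

## Worked example

```python
import numpy as np
from nmdp import (SimSpec, simulate_cohort, waterfall_cutoff, assign_labels,
                  SelectionParams, fit_pc, recovery_score, build_similarity,
                  alpha_weights, beta_weights)

blocks, pathways, ic50, truth = simulate_cohort(SimSpec(seed=7))
fit = waterfall_cutoff(ic50["ic50"].to_numpy())
labels = assign_labels(ic50["ic50"].to_numpy(), fit, ic50["sample_id"].tolist())
print(f"waterfall: method={fit.method}, r={fit.pearson_r:.3f}, "
      f"cutoff={labels.cutoff:.2f}, responsive={labels.responsive_fraction:.0%}")

expr = blocks["expression"]
edges = pathways.align(expr.probe_ids)
pc = fit_pc(expr.values, labels.label, edges, SelectionParams(k=10, seed=7))
selected = [expr.probe_ids[i] for i in pc.support]
score = recovery_score(selected, truth.signal_genes)
print(f"selection: {len(selected)} probes in {pc.iterations} iterations, "
      f"Jaccard vs planted signal = {score['jaccard']:.2f}")

sims = [build_similarity(blocks[n].values, blocks[n].sample_ids, n)
        for n in ("expression", "copynumber", "methylation")]
alpha, dips = alpha_weights(sims, n_boot=500, seed=7)
beta, raw_var = beta_weights(sims)
print(f"fusion: alpha={np.round(alpha, 2)}, beta={np.round(beta, 2)} "
      f"(dip p-values {[round(d.pvalue, 3) for d in dips]})")
```

prints

```
waterfall: method=median, r=0.991, cutoff=5.18, responsive=50%
selection: 19 probes in 14 iterations, Jaccard vs planted signal = 0.95
fusion: alpha=[0.51 0.5  1.5 ], beta=[0.68 1.5  0.5 ] (dip p-values [0.99, 1.0, 0.0])
```

The sorted IC50 curve is near-linear (r = 0.991), so the median splits the
cohort 50/50.  The sparse component converges to 19 of the 20 planted
signal genes and nothing else (Jaccard 0.95).  The methylation block —
whose similarity entries are two-peaked (dip p ≈ 0) because it carries the
responder/non-responder split — takes the maximal bimodality weight α,
while the copy-number block, whose similarities are most dispersed, takes
the maximal variance weight β.

The same stages are available as a CLI
(`nmdp simulate | label | select | simnet | fuse | run`); the end-to-end
run writes a JSON report with per-class sensitivity, specificity,
precision, F1 and accuracy per fold, reproducible byte-for-byte from a
config and a seed.  Ablation switches (`no-weighting`, `no-conv`,
`no-similarity`, `mlp-head`) rerun the pipeline with one component removed
on identical folds.

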