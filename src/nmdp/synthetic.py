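"""Seeded multi-omics cohort generator with planted, pathway-structured signal.

The cohort emulates the structure the pipeline is built for:

* a pathway graph (Erdos-Renyi background edges plus injected signal and
  decoy edges over a shared gene universe);
* three omics blocks of unequal width whose first rows are pathway genes
  and whose remaining rows are non-pathway noise probes;
* a per-sample latent sensitivity factor ``z``: the vertices of the signal
  edges respond to ``z`` in every block, and log-IC50 decreases linearly
  with ``z`` plus measurement noise, so the waterfall cutoff recovers the
  latent threshold;
* a decoy component: vertices of separate decoy edges respond, in the
  expression block, to an independent latent with *larger* amplitude than
  the signal.  Variance alone therefore prefers the decoy; only the
  response labels point at the planted support;
* block-specific structure for the fusion weights: the designated bimodal
  block carries a latent two-group split (its similarity entries become
  two-peaked), and the designated high-variance block carries a strong
  continuous factor (its similarity entries spread widely but stay
  one-peaked).

Everything derives from one integer seed; identical seeds give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types_io import OmicsBlock, PathwayEdgeSet


@dataclass
class SimSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 120
    m_expr: int = 150
    m_cnv: int = 180
    m_meth: int = 220
    n_genes: int = 80
    n_background_edges: int = 60
    planted_edges: int = 10
    effect: float = 1.5
    decoy_edges: int = 10
    decoy_scale: float = 1.2
    cnv_signal: float = 0.6
    meth_signal: float = 0.6
    bimodal_block: str = "methylation"
    bimodal_shift: float = 0.5
    highvar_block: str = "copynumber"
    highvar_strength: float = 1.4
    noise_sd: dict = field(default_factory=lambda: {
        "expression": 1.0, "copynumber": 1.0, "methylation": 1.0})
    ic50_base: float = 5.0
    ic50_coef: float = 2.0
    ic50_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        n_pathway_genes = 2 * (self.planted_edges + self.decoy_edges)
        if n_pathway_genes > self.n_genes:
            raise ValueError("more planted+decoy genes than genes in the pathway universe")
        for m in (self.m_expr, self.m_cnv, self.m_meth):
            if m < self.n_genes:
                raise ValueError("omics width smaller than the gene universe")
        for sd in self.noise_sd.values():
            if sd <= 0:
                raise ValueError("noise sd must be > 0")


@dataclass
class CohortTruth:
    """Ground truth for recovery scoring."""

    signal_genes: list[str]
    decoy_genes: list[str]
    signal_edges: list[tuple[str, str]]
    latent: np.ndarray
    true_label: np.ndarray
    bimodal_block: str
    highvar_block: str


def simulate_cohort(spec: SimSpec) -> tuple[dict[str, OmicsBlock], PathwayEdgeSet, pd.DataFrame, CohortTruth]:
    """Generate one cohort: three omics blocks, pathway edges, IC50 table, truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # pathway graph: disjoint signal and decoy edges, then random background
    perm = rng.permutation(spec.n_genes)
    sig_v = perm[: 2 * spec.planted_edges]
    dec_v = perm[2 * spec.planted_edges: 2 * (spec.planted_edges + spec.decoy_edges)]
    signal_edges = [(genes[sig_v[2 * i]], genes[sig_v[2 * i + 1]])
                    for i in range(spec.planted_edges)]
    decoy_edges = [(genes[dec_v[2 * i]], genes[dec_v[2 * i + 1]])
                   for i in range(spec.decoy_edges)]
    edges = list(signal_edges) + list(decoy_edges)
    seen = {frozenset(e) for e in edges}
    sig_set = {genes[i] for i in sig_v}
    dec_set = {genes[i] for i in dec_v}
    while len(edges) < spec.planted_edges + spec.decoy_edges + spec.n_background_edges:
        a, b = rng.integers(0, spec.n_genes, size=2)
        if a == b:
            continue
        ga, gb = genes[a], genes[b]
        # the planted pairs are the only edges inside each planted component:
        # background edges may touch signal/decoy genes but not join two of them
        if (ga in sig_set and gb in sig_set) or (ga in dec_set and gb in dec_set):
            continue
        key = frozenset((ga, gb))
        if key in seen:
            continue
        seen.add(key)
        edges.append((ga, gb))
    edge_set = PathwayEdgeSet(edges=edges)

    signal_genes = [genes[i] for i in sig_v]
    decoy_genes = [genes[i] for i in dec_v]

    # latent factors
    z = rng.standard_normal(n)            # drug sensitivity
    z_decoy = rng.standard_normal(n)      # high-variance, label-independent
    # the bimodal block's two-group split IS the response dichotomy: bimodal
    # similarity distributions are taken as evidence of responder subgroups,
    # so the generator realizes exactly that structure
    group = np.where(z >= np.median(z), 1.0, -1.0)
    b_factor = rng.standard_normal(n)     # continuous high-variance factor

    sig_idx = {g: i for i, g in enumerate(signal_genes)}
    dec_idx = {g: i for i, g in enumerate(decoy_genes)}
    block_specs = {
        "expression": (spec.m_expr, "EP", spec.effect, True),
        "copynumber": (spec.m_cnv, "CP", spec.effect * spec.cnv_signal, False),
        "methylation": (spec.m_meth, "MP", spec.effect * spec.meth_signal, False),
    }
    blocks: dict[str, OmicsBlock] = {}
    for name, (width, prefix, sig_amp, carries_decoy) in block_specs.items():
        probe_ids = genes + [f"{prefix}{i:03d}" for i in range(width - spec.n_genes)]
        values = rng.normal(0.0, spec.noise_sd[name], size=(width, n))
        sig_load = 0.8 + 0.2 * rng.uniform(size=len(signal_genes))
        for g, j in sig_idx.items():
            values[probe_ids.index(g)] += sig_amp * sig_load[j] * z
        if carries_decoy:
            dec_load = 0.8 + 0.2 * rng.uniform(size=len(decoy_genes))
            for g, j in dec_idx.items():
                values[probe_ids.index(g)] += spec.effect * spec.decoy_scale * dec_load[j] * z_decoy
        if name == spec.bimodal_block:
            affected = rng.uniform(size=width) < 0.6
            delta = rng.choice([-1.0, 1.0], size=width) * spec.bimodal_shift * affected
            values += np.outer(delta, group)
        if name == spec.highvar_block:
            # the continuous factor spreads this block's similarity values out,
            # but only non-pathway probes carry it: pathway genes with factor
            # loadings would form spurious high-weight edges and hijack the
            # edge-constrained selection
            loadings = rng.standard_normal(width) * spec.highvar_strength
            lvec = np.zeros(width)
            lvec[spec.n_genes:] = loadings[spec.n_genes:]
            values += np.outer(lvec, b_factor)
        blocks[name] = OmicsBlock(name=name, values=values,
                                  probe_ids=probe_ids, sample_ids=sample_ids)

    # log-IC50 falls linearly with the latent sensitivity factor
    ic50 = spec.ic50_base - spec.ic50_coef * z \
        + rng.normal(0.0, spec.ic50_noise_sd, size=n)
    ic50_df = pd.DataFrame({"sample_id": sample_ids, "ic50": ic50})

    truth = CohortTruth(
        signal_genes=signal_genes, decoy_genes=decoy_genes,
        signal_edges=signal_edges, latent=z,
        true_label=(z >= np.median(z)).astype(int),
        bimodal_block=spec.bimodal_block, highvar_block=spec.highvar_block,
    )
    return blocks, edge_set, ic50_df, truth


def recovery_score(selected_probes, truth_probes) -> dict:
    """Set-overlap metrics between selected and planted probe sets."""
    sel = set(selected_probes)
    tru = set(truth_probes)
    inter = len(sel & tru)
    union = len(sel | tru)
    return {
        "jaccard": inter / union if union else 1.0,
        "precision": inter / len(sel) if sel else 0.0,
        "recall": inter / len(tru) if tru else 0.0,
        "n_selected": len(sel),
        "n_truth": len(tru),
    }
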