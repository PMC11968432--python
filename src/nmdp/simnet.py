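"""Sample-similarity networks from key feature matrices.

Each omics block is reduced to an anchors x queries matrix of rank
correlations between sample probe-vectors: Spearman for expression and
methylation, Kendall for copy number (heavily tied integer-like data).
To avoid train/test leakage, anchors are always the training samples, so a
query (test) sample's feature row never depends on other test samples.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .types_io import ConfigError, SimilarityMatrix

DEFAULT_KERNELS = {
    "expression": "spearman",
    "methylation": "spearman",
    "copynumber": "kendall",
}


def kernel_for_omics(name: str, overrides: dict[str, str] | None = None) -> str:
    """Map an omics label to its correlation kernel."""
    table = dict(DEFAULT_KERNELS)
    if overrides:
        table.update(overrides)
    if name not in table:
        raise ConfigError(f"no kernel configured for omics {name!r}")
    kernel = table[name]
    if kernel not in ("spearman", "kendall"):
        raise ConfigError(f"unknown kernel {kernel!r}")
    return kernel


def _rank_columns(values: np.ndarray) -> np.ndarray:
    # average ranks per sample column, for the rank-then-Pearson Spearman form
    return np.apply_along_axis(stats.rankdata, 0, values)


def _corr_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation between all columns of A and of B."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A * A).sum(axis=0))
    sb = np.sqrt((B * B).sum(axis=0))
    degenerate_a = sa == 0
    degenerate_b = sb == 0
    if degenerate_a.any() or degenerate_b.any():
        warnings.warn("constant sample vector: similarity defined as 0")
    sa[degenerate_a] = 1.0
    sb[degenerate_b] = 1.0
    out = (A.T @ B) / np.outer(sa, sb)
    out[degenerate_a, :] = 0.0
    out[:, degenerate_b] = 0.0
    return np.clip(out, -1.0, 1.0)


def spearman_similarity(
    values: np.ndarray,
    sample_ids: list[str],
    anchors: list[str] | None = None,
    queries: list[str] | None = None,
    name: str = "other",
) -> SimilarityMatrix:
    """Spearman rank correlation between sample columns of a probes x samples block."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 probes for sample similarity")
    anchors = list(sample_ids) if anchors is None else list(anchors)
    queries = list(anchors) if queries is None else list(queries)
    ranked = _rank_columns(values)
    ai = [sample_ids.index(s) for s in anchors]
    qi = [sample_ids.index(s) for s in queries]
    sim = _corr_block(ranked[:, ai], ranked[:, qi])
    if anchors == queries:
        np.fill_diagonal(sim, 1.0)
        sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(anchors=anchors, queries=queries, values=sim,
                            kernel="spearman", name=name)


def kendall_similarity(
    values: np.ndarray,
    sample_ids: list[str],
    anchors: list[str] | None = None,
    queries: list[str] | None = None,
    name: str = "other",
    variant: str = "tau_a",
) -> SimilarityMatrix:
    """Kendall tau between sample columns: (C - D) / (k(k-1)/2) over probe pairs.

    ``variant="tau_b"`` applies the tie-corrected denominator, useful for
    copy-number data where integer values tie heavily.
    """
    values = np.asarray(values, dtype=float)
    k = values.shape[0]
    if k < 2:
        raise ValueError("need >= 2 probes for sample similarity")
    anchors = list(sample_ids) if anchors is None else list(anchors)
    queries = list(anchors) if queries is None else list(queries)
    ai = [sample_ids.index(s) for s in anchors]
    qi = [sample_ids.index(s) for s in queries]
    # pairwise sign vectors over all probe pairs: C - D between two samples is
    # the inner product of their sign vectors, so the whole tau matrix is a
    # single matrix product (ties contribute sign 0)
    iu, ju = np.triu_indices(k, 1)
    n0 = k * (k - 1) / 2.0
    signs = np.sign(values[iu, :] - values[ju, :])  # (n_pairs, n_samples)
    Sa = signs[:, ai]
    Sq = signs[:, qi]
    const_a = np.ptp(values[:, ai], axis=0) == 0
    const_q = np.ptp(values[:, qi], axis=0) == 0
    if const_a.any() or const_q.any():
        warnings.warn("constant sample vector: similarity defined as 0")
    if variant == "tau_b":
        na = (Sa * Sa).sum(axis=0)  # untied pairs per sample
        nq = (Sq * Sq).sum(axis=0)
        denom = np.sqrt(np.outer(na, nq))
        denom[denom == 0] = 1.0
        sim = (Sa.T @ Sq) / denom
    else:
        sim = (Sa.T @ Sq) / n0
    sim[const_a, :] = 0.0
    sim[:, const_q] = 0.0
    if anchors == queries:
        np.fill_diagonal(sim, 1.0)
        sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(anchors=anchors, queries=queries,
                            values=np.clip(sim, -1, 1), kernel="kendall", name=name)


def build_similarity(
    values: np.ndarray,
    sample_ids: list[str],
    name: str,
    anchors: list[str] | None = None,
    queries: list[str] | None = None,
    kernel: str | None = None,
    overrides: dict[str, str] | None = None,
    kendall_variant: str = "tau_a",
) -> SimilarityMatrix:
    """Dispatch to the kernel configured for this omics."""
    kernel = kernel or kernel_for_omics(name, overrides)
    if kernel == "spearman":
        return spearman_similarity(values, sample_ids, anchors, queries, name=name)
    return kendall_similarity(values, sample_ids, anchors, queries, name=name,
                              variant=kendall_variant)
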