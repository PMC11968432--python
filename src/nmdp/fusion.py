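"""Weighted fusion of per-omics similarity matrices.

Each similarity block gets two scalar weights before the entrywise sum
``X' = sum_i alpha_i * beta_i * block_i``:

* ``alpha`` rewards bimodality: a dip test on the block's off-diagonal
  entries (two-peaked similarity distributions mean the block separates
  sample subgroups), raw score ``1 - pvalue``;
* ``beta`` rewards dispersion: the mean per-column sample variance
  (denominator ``n - 1``) of the block.

Both raw score vectors are linearly rescaled to a user range ``[a, b]``
(default [0.5, 1.5]) so that no block is ever discarded outright, only
up- or down-weighted.
"""

from __future__ import annotations

import warnings

import numpy as np

from .dip import DipResult, dip_pvalue, dip_statistic, dip_test
from .types_io import FusedFeatures, SimilarityMatrix

__all__ = [
    "dip_statistic", "dip_pvalue", "dip_test", "DipResult",
    "alpha_weights", "beta_weights", "normalize_range", "fuse",
]

# dip inputs larger than this are subsampled (seeded): the test's power
# saturates long before a thousand points
_DIP_SUBSAMPLE = 1000


def normalize_range(raw: np.ndarray, a: float = 0.5, b: float = 1.5) -> np.ndarray:
    """Linear map of raw scores onto [a, b]; a degenerate spread maps to (a+b)/2."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        warnings.warn("identical raw scores: normalization degenerate, using (a+b)/2")
        return np.full_like(raw, (a + b) / 2.0)
    p = (b - a) / (hi - lo)
    return a + p * (raw - lo)


def _offdiag_entries(sim: SimilarityMatrix) -> np.ndarray:
    v = sim.values
    if sim.anchors == sim.queries:
        iu = np.triu_indices(v.shape[0], k=1)
        return v[iu]
    return v.ravel()


def alpha_weights(
    sim_blocks: list[SimilarityMatrix],
    n_boot: int = 2000,
    seed: int = 0,
    a: float = 0.5,
    b: float = 1.5,
) -> tuple[np.ndarray, list[DipResult]]:
    """Bimodality weights: dip test per block on off-diagonal entries.

    Raw score is ``1 - pvalue`` (continuous, rather than the hard
    significant-bimodality / significant-unimodality thresholds, which are
    still reported in the returned DipResult records); scores are then
    normalized to [a, b].
    """
    raws, results = [], []
    for blk_i, sim in enumerate(sim_blocks):
        entries = _offdiag_entries(sim)
        if entries.size < 4:
            raise ValueError("need >= 4 off-diagonal entries for the dip test")
        if entries.size > _DIP_SUBSAMPLE:
            rng = np.random.default_rng(seed + 7919 * blk_i)
            entries = rng.choice(entries, size=_DIP_SUBSAMPLE, replace=False)
        d = dip_statistic(entries)
        res = dip_pvalue(d, n=entries.size, n_boot=n_boot, seed=seed)
        results.append(res)
        raws.append(1.0 - res.pvalue)
    return normalize_range(np.asarray(raws), a, b), results


def beta_weights(
    sim_blocks: list[SimilarityMatrix],
    a: float = 0.5,
    b: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispersion weights: mean per-column sample variance, normalized to [a, b]."""
    raws = []
    for sim in sim_blocks:
        if sim.values.shape[0] < 2:
            raise ValueError("need >= 2 rows for a column variance")
        raws.append(float(np.mean(np.var(sim.values, axis=0, ddof=1))))
    raws = np.asarray(raws)
    return normalize_range(raws, a, b), raws


def fuse(
    sim_blocks: list[SimilarityMatrix],
    alpha: np.ndarray,
    beta: np.ndarray,
) -> FusedFeatures:
    """Entrywise weighted sum X' = sum_i alpha_i * beta_i * block_i."""
    ref = sim_blocks[0]
    for sim in sim_blocks[1:]:
        if sim.anchors != ref.anchors or sim.queries != ref.queries:
            raise ValueError("similarity blocks are not aligned on the same anchors/queries")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (len(alpha) == len(beta) == len(sim_blocks)):
        raise ValueError("alpha/beta length must equal the number of blocks")
    values = np.zeros_like(ref.values)
    for w_a, w_b, sim in zip(alpha, beta, sim_blocks):
        values = values + w_a * w_b * sim.values
    return FusedFeatures(values=values, alpha=alpha, beta=beta,
                         anchors=list(ref.anchors), queries=list(ref.queries))


class DipVarianceFusion:
    """Fit dip/variance weights on training similarity blocks, apply to any blocks.

    fit() learns (alpha, beta) from anchor x anchor training blocks;
    transform() applies the frozen weights to aligned anchor x query blocks,
    so test-sample features never influence the weights.
    """

    def __init__(self, a: float = 0.5, b: float = 1.5, n_boot: int = 2000,
                 seed: int = 0, unit_weights: bool = False):
        self.a = a
        self.b = b
        self.n_boot = n_boot
        self.seed = seed
        self.unit_weights = unit_weights  # ablation: alpha = beta = 1

    def fit(self, sim_blocks: list[SimilarityMatrix], y=None):
        if self.unit_weights:
            self.alpha_ = np.ones(len(sim_blocks))
            self.beta_ = np.ones(len(sim_blocks))
            self.dip_results_ = []
        else:
            self.alpha_, self.dip_results_ = alpha_weights(
                sim_blocks, n_boot=self.n_boot, seed=self.seed, a=self.a, b=self.b)
            self.beta_, self.raw_variances_ = beta_weights(sim_blocks, a=self.a, b=self.b)
        return self

    def transform(self, sim_blocks: list[SimilarityMatrix]) -> FusedFeatures:
        return fuse(sim_blocks, self.alpha_, self.beta_)

    def fit_transform(self, sim_blocks, y=None):
        return self.fit(sim_blocks, y).transform(sim_blocks)
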