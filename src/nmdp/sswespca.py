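"""Semi-supervised weighted edge sparse PCA.

A rank-one power iteration alternates between the sample-score vector ``v``
and the probe-loading vector ``u``, with two modifications over plain SVD:

* the support of ``u`` is constrained to the vertices of ``k`` pathway
  edges, chosen by a greedy-with-oversampling rule — rank edges by weight
  ``w_h = u_i^2 + u_j^2``, keep the top ``ceil((1+omega) k)``, then sample
  ``k`` of those at random (omega decays by rho per iteration, floored at 0);
* a supervised evaluator (random forest by default) is refit each cycle on
  the currently selected probes against the binary response labels, and its
  per-probe importances, rescaled to [0, 2], multiplicatively reweight the
  loading before renormalization.  This is what makes the selection
  semi-supervised: probes that carry label signal are boosted, so different
  drugs select different probe sets from the same omics matrix.

Convergence is declared when ``||u - u_update||_2`` falls below ``tol``.
Further components are extracted after Hotelling deflation
``X <- X - u (u^T X)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .types_io import PathwayEdgeSet, SparseLoading

logger = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    """Knobs for one sparse-PC extraction."""

    k: int = 10
    omega: float = 1.0
    rho: float = 0.1
    n_pcs: int = 1
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0
    evaluator: str | None = "random_forest"
    sqrt_edge_weights: bool = False

    def validate(self, n_edges: int) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.k > n_edges:
            raise ValueError(f"k={self.k} exceeds edge count {n_edges}")
        if math.ceil((1 + self.omega) * self.k) > n_edges:
            raise ValueError("ceil((1+omega)k) exceeds edge count")


def edge_weights(u: np.ndarray, edges: np.ndarray, sqrt: bool = False) -> np.ndarray:
    """Per-edge weight ``w_h = u_i^2 + u_j^2`` for edge ``e_h = (i, j)``."""
    u = np.asarray(u, dtype=float)
    w = u[edges[:, 0]] ** 2 + u[edges[:, 1]] ** 2
    return np.sqrt(w) if sqrt else w


def sparse_project(
    z: np.ndarray,
    edges: np.ndarray,
    weights: np.ndarray,
    k: int,
    omega: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep ``z`` on the vertices of ``k`` edges sampled from the top candidates.

    Edges are ranked by weight descending, ties broken toward the lower edge
    index; the candidate pool is the top ``ceil((1+omega) k)`` edges, from
    which ``k`` are drawn uniformly without replacement.

    Returns (projected z, sampled edge indices).
    """
    n_edges = len(weights)
    if k > n_edges:
        raise ValueError(f"k={k} exceeds edge count {n_edges}")
    pool_size = min(math.ceil((1 + omega) * k), n_edges)
    # stable sort on (-weight, index): ties favor the lower edge index
    order = np.lexsort((np.arange(n_edges), -np.asarray(weights, dtype=float)))
    pool = order[:pool_size]
    if pool_size == k:
        sampled = pool.copy()
    else:
        sampled = pool[rng.choice(pool_size, size=k, replace=False)]
    sampled = np.sort(sampled)
    out = np.zeros_like(np.asarray(z, dtype=float))
    vertices = np.unique(edges[sampled].ravel())
    out[vertices] = np.asarray(z, dtype=float)[vertices]
    return out, sampled


def evaluator_importance(
    X_hat: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    evaluator: str = "random_forest",
) -> np.ndarray:
    """Supervised per-probe importance on the selected submatrix, scaled to [0, 2].

    ``X_hat`` is probes x samples for the current support.  A single-class
    label vector or constant importances degrade to all-ones (identity
    reweighting) with a warning.
    """
    y = np.asarray(y)
    p = X_hat.shape[0]
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: evaluator skipped, importances set to 1")
        return np.ones(p)
    if evaluator == "random_forest":
        # max_features=1 (fully random split candidates) so every informative
        # probe accumulates importance; with few, correlated probes the default
        # candidate pool lets trees ignore weaker probes entirely
        model = RandomForestClassifier(n_estimators=200, max_features=1,
                                       random_state=seed, n_jobs=1)
        model.fit(X_hat.T, y)
        t = model.feature_importances_.astype(float)
    elif evaluator == "linear":
        model = LogisticRegression(max_iter=1000, random_state=seed)
        model.fit(X_hat.T, y)
        t = np.abs(model.coef_.ravel())
    else:
        raise ValueError(f"unknown evaluator {evaluator!r}")
    lo, hi = t.min(), t.max()
    if hi - lo <= 0:
        warnings.warn("constant importances: rescaling undefined, using 1s")
        return np.ones(p)
    return 2.0 * (t - lo) / (hi - lo)


def reweight_and_normalize(u_hat: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Multiply the loading by the importance vector and renormalize to unit L2."""
    u = np.asarray(u_hat, dtype=float) * np.asarray(t, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise FloatingPointError("loading vanished after importance reweighting")
    return u / norm


def update_v(X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample scores ``v = X^T u / ||X^T u||``."""
    v = X.T @ u
    norm = np.linalg.norm(v)
    if norm == 0:
        raise FloatingPointError("X^T u is the zero vector")
    return v / norm


def fit_pc(
    X: np.ndarray,
    y: np.ndarray | None,
    edges: np.ndarray,
    params: SelectionParams,
    rng: np.random.Generator | None = None,
) -> SparseLoading:
    """Extract one pathway-constrained sparse component from probes x samples X."""
    params.validate(len(edges))
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m, n = X.shape
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    u = np.zeros(m)
    omega = params.omega
    audit: list[list[int]] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        z = X @ v
        w = edge_weights(z, edges, sqrt=params.sqrt_edge_weights)
        u_hat, sampled = sparse_project(z, edges, w, params.k, omega, rng)
        audit.append(sampled.tolist())
        if omega > 0:
            omega = max(0.0, omega - params.rho)
        support = np.flatnonzero(u_hat)
        if params.evaluator is not None and y is not None and support.size:
            t_full = np.zeros(m)
            t_full[support] = evaluator_importance(
                X[support], y, seed=params.seed, evaluator=params.evaluator)
            u_hat = u_hat * t_full
            if not np.any(u_hat):
                # importance zeroed the entire support; keep the unweighted iterate
                u_hat = np.zeros(m)
                u_hat[support] = (X @ v)[support]
        norm = np.linalg.norm(u_hat)
        if norm == 0:
            raise FloatingPointError("loading vanished during iteration")
        u_update = u_hat / norm
        loss = np.linalg.norm(u - u_update)
        u = u_update
        v = update_v(X, u)
        if loss < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_pc: no convergence in %d iterations (last loss above tol)", params.max_iter)
    return SparseLoading(
        u=u, v=v, support=np.flatnonzero(u), k_edges=params.k,
        iterations=it, converged=converged, sampled_edges=audit,
    )


def fit_multi_pc(
    X: np.ndarray,
    y: np.ndarray | None,
    edges: np.ndarray,
    params: SelectionParams,
) -> tuple[list[SparseLoading], np.ndarray]:
    """Extract ``n_pcs`` components with Hotelling deflation between them.

    Returns the loadings and the key matrix: rows of the *original* X indexed
    by the union of all component supports.
    """
    rng = np.random.default_rng(params.seed)
    X_work = np.array(X, dtype=float)
    loadings: list[SparseLoading] = []
    for _ in range(params.n_pcs):
        if np.linalg.norm(X_work) < 1e-12:
            logger.warning("deflated matrix numerically zero; stopping at %d PC(s)", len(loadings))
            break
        pc = fit_pc(X_work, y, edges, params, rng=rng)
        loadings.append(pc)
        X_work = X_work - np.outer(pc.u, pc.u @ X_work)
    union = np.unique(np.concatenate([pc.support for pc in loadings]))
    return loadings, X[union]


class SparsePathwayPCA(BaseEstimator, TransformerMixin):
    """Semi-supervised pathway-edge sparse PCA as an sklearn transformer.

    fit() consumes samples x probes (sklearn orientation) plus binary labels
    ``y``; transform() returns the key submatrix (samples x selected probes).
    Pass ``evaluator=None`` to run the unsupervised edge-sparse variant.

    Attributes
    ----------
    loadings_ : list of fitted SparseLoading records, one per component.
    support_ : sorted union of the component supports (probe indices).
    """

    def __init__(self, edge_set: PathwayEdgeSet | None = None, probe_ids: list[str] | None = None,
                 k: int = 10, omega: float = 1.0, rho: float = 0.1, n_pcs: int = 1,
                 tol: float = 1e-4, max_iter: int = 100, seed: int = 0,
                 evaluator: str | None = "random_forest", sqrt_edge_weights: bool = False):
        self.edge_set = edge_set
        self.probe_ids = probe_ids
        self.k = k
        self.omega = omega
        self.rho = rho
        self.n_pcs = n_pcs
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.evaluator = evaluator
        self.sqrt_edge_weights = sqrt_edge_weights

    def _params(self) -> SelectionParams:
        return SelectionParams(k=self.k, omega=self.omega, rho=self.rho, n_pcs=self.n_pcs,
                               tol=self.tol, max_iter=self.max_iter, seed=self.seed,
                               evaluator=self.evaluator,
                               sqrt_edge_weights=self.sqrt_edge_weights)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.edge_set is None:
            raise ValueError("edge_set is required")
        m = X.shape[1]
        probe_ids = self.probe_ids if self.probe_ids is not None else [str(i) for i in range(m)]
        edges = self.edge_set.align(probe_ids)
        if edges.size == 0:
            raise ValueError("no pathway edge resolves against the probe list")
        self.loadings_, _ = fit_multi_pc(X.T, y, edges, self._params())
        self.support_ = np.unique(np.concatenate([pc.support for pc in self.loadings_]))
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        probe_ids = self.probe_ids if self.probe_ids is not None else [
            str(i) for i in range(self.n_features_in_)]
        return np.asarray([probe_ids[i] for i in self.support_], dtype=object)
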