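"""End-to-end orchestration: label -> select -> similarity -> fuse -> classify.

One pipeline run models one drug.  Evaluation is stratified k-fold
cross-validation; within each fold every anchor-dependent computation
(sparse-PC selection, similarity anchors, fusion weights, classifier
training) sees training samples only, so test-sample values never leak into
feature construction.  Ablation switches mirror the model's component
study: unit fusion weights, no convolution, no similarity step, or an
equal-budget MLP in place of the KAN head.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .fusion import DipVarianceFusion
from .labeling import assign_labels, waterfall_cutoff
from .predictor import ConvKANClassifier, evaluate
from .simnet import build_similarity
from .sswespca import SelectionParams, fit_multi_pc
from .types_io import (ConfigError, OmicsBlock, PathwayEdgeSet, RunConfig,
                       SimilarityMatrix, load_config)

logger = logging.getLogger(__name__)

ABLATIONS = ("no-weighting", "no-conv", "no-similarity", "mlp-head")


@dataclass
class FoldResult:
    fold: int
    metrics: dict
    supports: dict[str, list[str]]
    alpha: list[float]
    beta: list[float]


def _fold_features(blocks, edge_set, y, train_idx, config, seed, ablation):
    """Select probes, build anchor similarities, fuse; returns samples x anchors."""
    sample_ids = blocks[next(iter(blocks))].sample_ids
    train_ids = [sample_ids[i] for i in train_idx]
    supports = {}
    sims = []
    key_columns = []
    for name, block in blocks.items():
        edges = edge_set.align(block.probe_ids)
        params = SelectionParams(k=config.k, omega=config.omega, rho=config.rho,
                                 n_pcs=config.n_pcs, tol=config.tol,
                                 max_iter=config.max_iter, seed=seed,
                                 evaluator=config.evaluator)
        X_train = block.values[:, train_idx]
        pcs, _ = fit_multi_pc(X_train, y[train_idx], edges, params)
        support = np.unique(np.concatenate([pc.support for pc in pcs]))
        supports[name] = [block.probe_ids[i] for i in support]
        key = block.values[support]  # selected probes, all samples
        if ablation == "no-similarity":
            key_columns.append(key)
        else:
            sims.append(build_similarity(
                key, block.sample_ids, name,
                anchors=train_ids, queries=block.sample_ids,
                overrides=config.kernel_overrides,
                kendall_variant=config.kendall_variant))
    if ablation == "no-similarity":
        features = np.vstack(key_columns).T  # samples x (sum of support sizes)
        return features, None, supports
    train_sims = [SimilarityMatrix(anchors=s.anchors, queries=s.anchors,
                                   values=s.values[:, train_idx],
                                   kernel=s.kernel, name=s.name) for s in sims]
    fuser = DipVarianceFusion(a=config.a, b=config.b, n_boot=config.n_boot,
                              seed=seed, unit_weights=(ablation == "no-weighting"))
    fuser.fit(train_sims)
    fused = fuser.transform(sims)
    return fused.values.T, fuser, supports  # samples x anchors


def run_pipeline(
    blocks: dict[str, OmicsBlock],
    edge_set: PathwayEdgeSet,
    ic50: np.ndarray,
    config: RunConfig | None = None,
    ablation: str | None = None,
    shuffle_labels: bool = False,
) -> dict:
    """Cross-validated metrics report for one drug on one cohort."""
    config = config or load_config()
    if ablation is not None and ablation not in ABLATIONS:
        raise ConfigError(f"unknown ablation {ablation!r}")
    seed = int(config.seed)
    rng = np.random.default_rng(seed)
    ic50 = np.asarray(ic50, dtype=float)
    fit = waterfall_cutoff(ic50)
    sample_ids = blocks[next(iter(blocks))].sample_ids
    labels = assign_labels(ic50, fit, sample_ids)
    y = labels.label.copy()
    if shuffle_labels:
        y = rng.permutation(y)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        features, fuser, supports = _fold_features(
            blocks, edge_set, y, train_idx, config, seed + fold, ablation)
        clf = ConvKANClassifier(
            conv_channels=config.conv_channels, kernel_size=config.kernel_size,
            pool=config.pool, kan_hidden=config.kan_hidden,
            grid_size=config.grid_size, spline_order=config.spline_order,
            residual_act=config.residual_act, epochs=config.epochs,
            lr=config.lr, batch_size=config.batch_size, seed=seed + fold,
            use_conv=(ablation != "no-conv"),
            head=("mlp" if ablation == "mlp-head" else "kan"))
        clf.fit(features[train_idx], y[train_idx])
        y_pred = clf.predict(features[test_idx])
        metrics = evaluate(y[test_idx], y_pred)
        folds.append(FoldResult(
            fold=fold, metrics=metrics, supports=supports,
            alpha=list(map(float, fuser.alpha_)) if fuser is not None else [],
            beta=list(map(float, fuser.beta_)) if fuser is not None else []))
        logger.info("fold %d accuracy %.3f", fold, metrics["accuracy"])
    mean = {key: float(np.mean([f.metrics[key] for f in folds]))
            for key in ("sensitivity", "specificity", "precision", "accuracy",
                        "f1", "f1_macro")}
    return {
        "labeling": {"method": fit.method, "pearson_r": fit.pearson_r,
                     "cutoff": labels.cutoff,
                     "responsive_fraction": labels.responsive_fraction},
        "ablation": ablation,
        "shuffled": shuffle_labels,
        "seed": seed,
        "n_folds": config.n_folds,
        "mean": mean,
        "folds": [{"fold": f.fold, "metrics": f.metrics, "alpha": f.alpha,
                   "beta": f.beta, "supports": f.supports} for f in folds],
    }


def ablate(blocks, edge_set, ic50, config=None, switches: list[str] | None = None) -> dict:
    """Run the full pipeline and one-at-a-time ablations on identical folds.

    The component study design is one switch per experiment; requesting two
    at once is a configuration error.
    """
    switches = list(switches or ABLATIONS)
    bad = [s for s in switches if s not in ABLATIONS]
    if bad:
        raise ConfigError(f"unknown ablation switch(es): {bad}")
    if len(switches) != len(set(switches)):
        raise ConfigError("ablation switches must be unique")
    full = run_pipeline(blocks, edge_set, ic50, config)
    out = {"full": full, "ablations": {}}
    for switch in switches:
        rep = run_pipeline(blocks, edge_set, ic50, config, ablation=switch)
        delta = {k: rep["mean"][k] - full["mean"][k] for k in full["mean"]}
        out["ablations"][switch] = {"report": rep, "delta_vs_full": delta}
    return out


def report_to_json(report: dict) -> str:
    """Deterministic serialization (sorted keys, fixed float formatting)."""
    return json.dumps(report, sort_keys=True, indent=2, default=float)
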