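"""Self-validation benchmarks: every stage re-checked against independent oracles.

Each suite regenerates its own inputs from a seed, runs the package's
implementation, and measures agreement with a brute-force or closed-form
reference (LP minimization for the dip, pair enumeration for Kendall,
exhaustive distance scans for the waterfall elbow, double loops for KAN and
convolution layers) or a planted ground truth (support recovery, fusion
weights, end-to-end accuracy).  The functions return flat dictionaries of
named numbers so callers can assert on or report them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import linprog

from .dip import dip_pvalue, dip_statistic
from .fusion import alpha_weights, beta_weights, fuse
from .labeling import assign_labels, waterfall_cutoff
from .pipeline import run_pipeline
from .predictor import Adam, BSplineBasis, ConvKANClassifier, KanLayer, KanLayerSpec, conv1d_forward, kan_phi
from .simnet import build_similarity, kendall_similarity, spearman_similarity
from .sswespca import SelectionParams, fit_pc
from .synthetic import SimSpec, recovery_score, simulate_cohort
from .types_io import load_config


# ---------------------------------------------------------------------------
# dip statistic


def dip_lp_oracle(x: np.ndarray) -> float:
    """Exact dip via linear programming.

    Minimizes the sup-distance between the ECDF and a unimodal
    piecewise-linear CDF with knots at the data points, over every candidate
    mode knot.  Exponential in nothing but linear-programming size, so only
    usable for small n; entirely independent of the iterative GCM/LCM path.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    dx = np.diff(x)
    nv = n + 1
    c = np.zeros(nv)
    c[-1] = 1.0
    A_base, b_base = [], []
    for i in range(n):
        for target in (i / n, (i + 1) / n):
            row = np.zeros(nv); row[i] = 1; row[-1] = -1
            A_base.append(row.copy()); b_base.append(target)
            row = np.zeros(nv); row[i] = -1; row[-1] = -1
            A_base.append(row.copy()); b_base.append(-target)
    for i in range(n - 1):
        row = np.zeros(nv); row[i] = 1; row[i + 1] = -1
        A_base.append(row); b_base.append(0.0)
    best = np.inf
    for j in range(n):
        A, b = list(A_base), list(b_base)
        for i in range(j - 1):
            row = np.zeros(nv)
            row[i] = -1 / dx[i]; row[i + 1] = 1 / dx[i] + 1 / dx[i + 1]; row[i + 2] = -1 / dx[i + 1]
            A.append(row); b.append(0.0)
        for i in range(j, n - 2):
            row = np.zeros(nv)
            row[i] = 1 / dx[i]; row[i + 1] = -1 / dx[i] - 1 / dx[i + 1]; row[i + 2] = 1 / dx[i + 1]
            A.append(row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if not res.success:  # pragma: no cover - defensive
            raise RuntimeError(f"oracle LP failed: {res.message}")
        best = min(best, res.fun)
    return float(best)


def dip_suite(seed: int = 0, n_instances: int = 1000, n_null: int = 500) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    bound_violations = 0
    for trial in range(n_instances):
        n = int(rng.integers(4, 13))
        kind = trial % 3
        if kind == 0:
            x = rng.uniform(size=n)
        elif kind == 1:
            x = rng.normal(size=n)
        else:
            x = np.concatenate([rng.normal(-4, 0.3, n // 2),
                                rng.normal(4, 0.3, n - n // 2)])
        d = dip_statistic(x)
        if abs(d - dip_lp_oracle(x)) <= 1e-9:
            agree += 1
        if not (1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12):
            bound_violations += 1
    # null calibration: p-values of uniform samples should be uniform
    n_cal = 80
    ps = []
    for _ in range(n_null):
        x = rng.uniform(size=n_cal)
        ps.append(dip_pvalue(dip_statistic(x), n=n_cal, n_boot=2000,
                             seed=seed + 1).pvalue)
    ks_p = float(stats.kstest(ps, "uniform").pvalue)
    return {
        "dip_oracle_agreement_rate": agree / n_instances,
        "dip_bound_violations": bound_violations,
        "dip_null_ks_pvalue": ks_p,
    }


# ---------------------------------------------------------------------------
# similarity kernels


def _kendall_pair_oracle(x, y):
    k = len(x)
    c = d = 0
    for i in range(k):
        for j in range(i + 1, k):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            c += s > 0
            d += s < 0
    return (c - d) / (k * (k - 1) / 2)


def kernel_suite(seed: int = 0, n_pairs: int = 200) -> dict:
    rng = np.random.default_rng(seed)
    max_kendall = max_spearman = 0.0
    for _ in range(n_pairs):
        k = int(rng.integers(3, 51))
        v = rng.normal(size=(k, 2))
        tau = kendall_similarity(v, ["a", "b"]).values[0, 1]
        max_kendall = max(max_kendall, abs(tau - _kendall_pair_oracle(v[:, 0], v[:, 1])))
        rho = spearman_similarity(v, ["a", "b"]).values[0, 1] if k >= 2 else 0.0
        rx, ry = stats.rankdata(v[:, 0]), stats.rankdata(v[:, 1])
        ref = stats.pearsonr(rx, ry)[0]
        max_spearman = max(max_spearman, abs(rho - ref))
    # full-matrix invariants
    v = rng.normal(size=(20, 15))
    ids = [f"S{i}" for i in range(15)]
    inv = 0.0
    for sim in (spearman_similarity(v, ids), kendall_similarity(v, ids)):
        inv = max(inv, float(np.max(np.abs(sim.values - sim.values.T))),
                  float(np.max(np.abs(np.diag(sim.values) - 1.0))),
                  float(max(0.0, np.max(np.abs(sim.values)) - 1.0)))
    return {
        "kendall_oracle_max_abs_error": float(max_kendall),
        "spearman_oracle_max_abs_error": float(max_spearman),
        "similarity_invariant_max_violation": inv,
    }


# ---------------------------------------------------------------------------
# waterfall labeling


def waterfall_suite(seed: int = 0, n_curves: int = 200) -> dict:
    rng = np.random.default_rng(seed)
    branch_violations = elbow_mismatches = 0
    min_fraction = 1.0
    for trial in range(n_curves):
        n = int(rng.integers(8, 120))
        kind = trial % 3
        if kind == 0:
            ic50 = rng.normal(size=n) ** 3
        elif kind == 1:
            ic50 = 1 / (1 + np.exp(-rng.normal(0, 3, size=n)))
        else:
            ic50 = rng.exponential(size=n)
        if np.ptp(ic50) == 0:
            continue
        fit = waterfall_cutoff(ic50)
        s = np.sort(ic50)
        r = stats.pearsonr(np.arange(1, n + 1), s)[0]
        if (fit.method == "median") != (r > 0.95):
            branch_violations += 1
        if fit.method == "furthest-point":
            x = np.arange(1, n + 1, dtype=float)
            d = np.abs((s[-1] - s[0]) * (x - 1) - (n - 1) * (s - s[0]))
            d /= np.hypot(n - 1, s[-1] - s[0])
            if fit.cutoff != s[int(np.argmax(d))]:
                elbow_mismatches += 1
        labels = assign_labels(ic50, fit)
        min_fraction = min(min_fraction, labels.responsive_fraction)
    # adversarial: a cutoff that catches almost nothing must be relocated
    ic50 = np.concatenate([[0.0], np.linspace(100, 101, 39)])
    fit = waterfall_cutoff(ic50)
    labels = assign_labels(ic50, fit)
    min_fraction = min(min_fraction, labels.responsive_fraction)
    return {
        "waterfall_branch_violations": branch_violations,
        "waterfall_elbow_mismatches": elbow_mismatches,
        "waterfall_min_responsive_fraction": float(min_fraction),
    }


# ---------------------------------------------------------------------------
# support recovery


def recovery_suite(seed: int = 0, n_seeds: int = 20) -> dict:
    js, js_shuffled = [], []
    norm_dev = 0.0
    legality_violations = 0
    for i in range(n_seeds):
        cohort_seed = seed * 1000 + i
        blocks, edge_set, ic50, truth = simulate_cohort(SimSpec(seed=cohort_seed))
        v = ic50["ic50"].to_numpy()
        labels = assign_labels(v, waterfall_cutoff(v), ic50["sample_id"].tolist())
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        params = SelectionParams(k=10, seed=cohort_seed)
        pc = fit_pc(block.values, labels.label, edges, params)
        norm_dev = max(norm_dev, abs(np.linalg.norm(pc.u) - 1.0),
                       abs(np.linalg.norm(pc.v) - 1.0))
        legal = set(edges[pc.sampled_edges[-1]].ravel())
        if not set(pc.support) <= legal or len(pc.sampled_edges[-1]) != params.k:
            legality_violations += 1
        sel = [block.probe_ids[j] for j in pc.support]
        js.append(recovery_score(sel, truth.signal_genes)["jaccard"])
        rng = np.random.default_rng(cohort_seed + 7)
        pc2 = fit_pc(block.values, rng.permutation(labels.label), edges, params)
        sel2 = [block.probe_ids[j] for j in pc2.support]
        js_shuffled.append(recovery_score(sel2, truth.signal_genes)["jaccard"])
    return {
        "recovery_jaccard_mean": float(np.mean(js)),
        "recovery_jaccard_shuffled_mean": float(np.mean(js_shuffled)),
        "recovery_jaccard_drop": float(np.mean(js) - np.mean(js_shuffled)),
        "recovery_unit_norm_max_deviation": float(norm_dev),
        "recovery_support_legality_violations": legality_violations,
    }


# ---------------------------------------------------------------------------
# fusion weighting


def fusion_suite(seed: int = 0, n_cohorts: int = 50) -> dict:
    names = ["expression", "copynumber", "methylation"]
    alpha_hits = beta_hits = 0
    for i in range(n_cohorts):
        blocks, edge_set, ic50, truth = simulate_cohort(SimSpec(seed=seed * 1000 + i))
        sims = [build_similarity(blocks[nm].values, blocks[nm].sample_ids, nm)
                for nm in names]
        alpha, _ = alpha_weights(sims, n_boot=2000, seed=seed + 1)
        beta, _ = beta_weights(sims)
        alpha_hits += names[int(np.argmax(alpha))] == truth.bimodal_block
        beta_hits += names[int(np.argmax(beta))] == truth.highvar_block
    # entrywise recomputation of the fusion itself
    rng = np.random.default_rng(seed)
    mats = [np.clip(rng.normal(0, 0.3, (8, 8)), -1, 1) for _ in range(3)]
    from .types_io import SimilarityMatrix
    ids = [f"S{i}" for i in range(8)]
    blocks_ = [SimilarityMatrix(anchors=ids, queries=ids, values=m,
                                kernel="spearman") for m in mats]
    a, b = rng.uniform(0.5, 1.5, 3), rng.uniform(0.5, 1.5, 3)
    fused = fuse(blocks_, a, b)
    expected = sum(ai * bi * m for ai, bi, m in zip(a, b, mats))
    return {
        "fusion_alpha_hit_rate": alpha_hits / n_cohorts,
        "fusion_beta_hit_rate": beta_hits / n_cohorts,
        "fusion_recompute_max_abs_error": float(np.max(np.abs(fused.values - expected))),
    }


# ---------------------------------------------------------------------------
# KAN / conv components


def kan_suite(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    # layer forward vs double loop
    spec = KanLayerSpec(4, 3)
    layer = KanLayer(spec, rng)
    X = rng.uniform(-0.9, 0.9, size=(5, 4))
    got, _ = layer.forward(X)
    want = np.zeros((5, 3))
    for bi in range(5):
        for q in range(3):
            for p in range(4):
                want[bi, q] += kan_phi(np.array([X[bi, p]]), layer.w1[q, p],
                                       layer.w2[q, p], layer.coef[q, p],
                                       layer.basis, "silu")[0]
    layer_err = float(np.max(np.abs(got - want)))
    # conv vs sliding window
    row = rng.normal(size=15)
    w = rng.normal(size=(2, 5))
    out = conv1d_forward(row, w)
    pad = np.pad(row, 2)
    conv_err = 0.0
    for ci in range(2):
        for i in range(15):
            conv_err = max(conv_err, abs(out[ci, i] - float(np.sum(pad[i:i + 5] * w[ci]))))
    # sin(3x) regression with a 2-layer KAN
    r = np.random.default_rng(seed + 1)
    l1, l2 = KanLayer(KanLayerSpec(1, 8), r), KanLayer(KanLayerSpec(8, 1), r)
    opt = Adam([l1, l2], lr=5e-3)
    x = np.linspace(-1, 1, 256)[:, None]
    t = np.sin(3 * x[:, 0])
    mse = np.inf
    for _ in range(2000):
        h1, c1 = l1.forward(x)
        h2, c2 = l2.forward(h1)
        err = h2[:, 0] - t
        mse = float(np.mean(err ** 2))
        d1 = l2.backward((2 * err / err.size)[:, None], c2)
        l1.backward(d1, c1)
        opt.step()
    # parameter budget of the default classifier on a 96-feature input
    rr = np.random.default_rng(seed)
    clf = ConvKANClassifier(epochs=1, seed=seed)
    clf.fit(rr.normal(size=(20, 96)), np.tile([0.0, 1.0], 10))
    return {
        "kan_layer_max_abs_error": layer_err,
        "conv1d_max_abs_error": conv_err,
        "kan_sine_fit_mse": mse,
        "predictor_n_parameters": clf.n_parameters_,
    }


# ---------------------------------------------------------------------------
# end to end


def pipeline_suite(seed: int = 0) -> dict:
    blocks, edge_set, ic50, truth = simulate_cohort(SimSpec(seed=seed))
    cfg = load_config(overrides={"seed": seed})
    v = ic50["ic50"].to_numpy()
    full = run_pipeline(blocks, edge_set, v, cfg)
    shuffled = run_pipeline(blocks, edge_set, v, cfg, shuffle_labels=True)
    return {
        "pipeline_cv_accuracy": full["mean"]["accuracy"],
        "pipeline_cv_sensitivity": full["mean"]["sensitivity"],
        "pipeline_cv_specificity": full["mean"]["specificity"],
        "pipeline_cv_f1": full["mean"]["f1"],
        "pipeline_shuffled_accuracy": shuffled["mean"]["accuracy"],
    }
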