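"""Dip statistic, Monte-Carlo p-values and similarity-network fusion."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linprog

from nmdp.fusion import (
    DipVarianceFusion,
    alpha_weights,
    beta_weights,
    dip_pvalue,
    dip_statistic,
    fuse,
    normalize_range,
)
from nmdp.types_io import SimilarityMatrix


def dip_lp_oracle(x):
    """Exact dip by LP: best unimodal piecewise-linear CDF with knots at the
    data, minimized over every candidate mode knot."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    dx = np.diff(x)
    nv = n + 1  # v_0..v_{n-1}, d
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
        for i in range(j - 1):  # convex below the mode
            row = np.zeros(nv)
            row[i] = -1 / dx[i]; row[i + 1] = 1 / dx[i] + 1 / dx[i + 1]; row[i + 2] = -1 / dx[i + 1]
            A.append(row); b.append(0.0)
        for i in range(j, n - 2):  # concave above the mode
            row = np.zeros(nv)
            row[i] = 1 / dx[i]; row[i + 1] = -1 / dx[i] - 1 / dx[i + 1]; row[i + 2] = 1 / dx[i + 1]
            A.append(row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        assert res.success
        best = min(best, res.fun)
    return best


class TestDipStatistic:
    def test_matches_lp_oracle_on_small_samples(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 13))
            kind = trial % 3
            if kind == 0:
                x = rng.uniform(size=n)
            elif kind == 1:
                x = rng.normal(size=n)
            else:
                x = np.concatenate([rng.normal(-4, 0.3, n // 2),
                                    rng.normal(4, 0.3, n - n // 2)])
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-9)

    def test_bounds_hold(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 120))
            d = dip_statistic(rng.uniform(size=n))
            assert 1.0 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_separated_mixture_dips_hard(self, rng):
        x = np.concatenate([rng.normal(-5, 0.1, 100), rng.normal(5, 0.1, 100)])
        d = dip_statistic(x)
        null99 = np.quantile([dip_statistic(rng.uniform(size=200))
                              for _ in range(200)], 0.99)
        assert d > null99
        assert d > 0.2  # near the 0.25 ceiling for a clean half/half split

    def test_uniform_small_sample_mean_near_floor(self, rng):
        dips = [dip_statistic(rng.uniform(size=4)) for _ in range(1000)]
        assert min(dips) >= 0.125 - 1e-12  # 1/(2n)
        assert np.mean(dips) < 0.2

    def test_ties_handled(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 10.0])
        d = dip_statistic(x)
        assert 1.0 / 12 - 1e-9 <= d <= 0.25

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic(np.full(10, 3.0))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic(np.array([1.0, 2.0, 3.0]))


class TestDipPvalue:
    def test_zero_dip_has_p_one(self):
        assert dip_pvalue(0.0, n=50, n_boot=200, seed=0).pvalue == 1.0

    def test_bimodal_is_significant(self, rng):
        x = np.concatenate([rng.normal(-5, 0.1, 100), rng.normal(5, 0.1, 100)])
        res = dip_pvalue(dip_statistic(x), n=200, n_boot=500, seed=0)
        assert res.pvalue < 0.05

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = [dip_pvalue(dip_statistic(rng.uniform(size=80)), n=80,
                         n_boot=500, seed=1).pvalue for _ in range(120)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            dip_pvalue(0.1, n=20, n_boot=50, seed=0)


class TestNormalizeRange:
    def test_linear_map_endpoints_and_midpoint(self):
        out = normalize_range(np.array([0.1, 0.5, 0.9]), a=0.5, b=1.5)
        np.testing.assert_allclose(out, [0.5, 1.0, 1.5])

    def test_degenerate_maps_to_center(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_range(np.array([0.3, 0.3, 0.3]), 0.5, 1.5)
        np.testing.assert_allclose(out, [1.0, 1.0, 1.0])

    def test_monotone(self, rng):
        raw = rng.uniform(size=6)
        out = normalize_range(raw, 0.5, 1.5)
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(out))


def _sim(values, name="other", kernel="spearman"):
    n = values.shape[0]
    ids = [f"S{i}" for i in range(n)]
    return SimilarityMatrix(anchors=ids, queries=ids, values=values,
                            kernel=kernel, name=name)


class TestWeights:
    def test_bimodal_block_gets_max_alpha(self, rng):
        n = 40
        bimodal = np.clip(rng.choice([-0.5, 0.5], size=(n, n)) + rng.normal(0, 0.05, (n, n)), -1, 1)
        uni1 = np.clip(rng.normal(0, 0.2, (n, n)), -1, 1)
        uni2 = np.clip(rng.normal(0, 0.2, (n, n)), -1, 1)
        blocks = [_sim((b + b.T) / 2) for b in (uni1, bimodal, uni2)]
        alpha, results = alpha_weights(blocks, n_boot=300, seed=0)
        assert np.argmax(alpha) == 1
        assert alpha[1] == 1.5  # max raw score maps to b

    def test_variance_weights_textbook_values(self):
        # each column (-1, 0, 1): sample variance exactly 1
        block = np.tile(np.array([[-1.0], [0.0], [1.0]]), (1, 3))
        beta, raw = beta_weights([_sim(np.full((3, 3), 0.5)), _sim(block)], a=0.5, b=1.5)
        assert raw[0] == 0.0
        assert raw[1] == pytest.approx(1.0)
        np.testing.assert_allclose(beta, [0.5, 1.5])

    def test_higher_raw_variance_never_lower_beta(self, rng):
        blocks = [_sim(np.clip(rng.normal(0, s, (10, 10)), -1, 1)) for s in (0.05, 0.15, 0.3)]
        beta, raw = beta_weights(blocks)
        order = np.argsort(raw)
        assert np.all(np.diff(beta[order]) >= 0)


class TestFuse:
    def test_unit_weights_plain_sum(self, rng):
        mats = [np.clip(rng.normal(0, 0.3, (5, 5)), -1, 1) for _ in range(3)]
        blocks = [_sim(m) for m in mats]
        fused = fuse(blocks, np.ones(3), np.ones(3))
        np.testing.assert_allclose(fused.values, sum(mats), atol=1e-12)

    def test_zero_weight_removes_block(self, rng):
        m1, m2 = (np.clip(rng.normal(0, 0.3, (4, 4)), -1, 1) for _ in range(2))
        blocks = [_sim(m1), _sim(m2)]
        f1 = fuse(blocks, np.array([1.0, 0.0]), np.ones(2))
        blocks2 = [_sim(m1), _sim(rng.normal(0, 0.3, (4, 4)).clip(-1, 1))]
        f2 = fuse(blocks2, np.array([1.0, 0.0]), np.ones(2))
        np.testing.assert_allclose(f1.values, f2.values)

    def test_matches_entrywise_recomputation(self, rng):
        mats = [np.clip(rng.normal(0, 0.3, (6, 6)), -1, 1) for _ in range(3)]
        alpha, beta = rng.uniform(0.5, 1.5, 3), rng.uniform(0.5, 1.5, 3)
        fused = fuse([_sim(m) for m in mats], alpha, beta)
        expected = np.zeros((6, 6))
        for i in range(3):
            for r in range(6):
                for c in range(6):
                    expected[r, c] += alpha[i] * beta[i] * mats[i][r, c]
        np.testing.assert_allclose(fused.values, expected, atol=1e-9)

    def test_linearity_in_each_block(self, rng):
        a = np.clip(rng.normal(0, 0.2, (4, 4)), -1, 1)
        b = np.clip(rng.normal(0, 0.2, (4, 4)), -1, 1)
        w = np.array([1.3])
        fa = fuse([_sim(a)], w, w)
        fb = fuse([_sim(b)], w, w)
        fab = fuse([_sim(np.clip(a + b, -1, 1))], w, w)
        if np.all(np.abs(a + b) <= 1):  # stay inside the representable range
            np.testing.assert_allclose(fab.values, fa.values + fb.values, atol=1e-9)

    def test_misaligned_blocks_rejected(self, rng):
        b1 = _sim(np.zeros((4, 4)))
        b2 = SimilarityMatrix(anchors=[f"T{i}" for i in range(4)],
                              queries=[f"T{i}" for i in range(4)],
                              values=np.zeros((4, 4)), kernel="spearman")
        with pytest.raises(ValueError, match="aligned"):
            fuse([b1, b2], np.ones(2), np.ones(2))


class TestDipVarianceFusion:
    def test_unit_weight_ablation(self, rng):
        mats = [np.clip(rng.normal(0, 0.3, (6, 6)), -1, 1) for _ in range(3)]
        blocks = [_sim(m) for m in mats]
        fuser = DipVarianceFusion(unit_weights=True).fit(blocks)
        np.testing.assert_array_equal(fuser.alpha_, np.ones(3))
        fused = fuser.transform(blocks)
        np.testing.assert_allclose(fused.values, sum(mats), atol=1e-12)

    def test_weights_frozen_after_fit(self, rng):
        train = [_sim(np.clip(rng.normal(0, s, (8, 8)), -1, 1)) for s in (0.1, 0.2, 0.3)]
        fuser = DipVarianceFusion(n_boot=200, seed=0).fit(train)
        a1 = fuser.alpha_.copy()
        query = [SimilarityMatrix(anchors=t.anchors, queries=["Q0", "Q1"],
                                  values=np.clip(rng.normal(0, 0.2, (8, 2)), -1, 1),
                                  kernel=t.kernel, name=t.name) for t in train]
        fused = fuser.transform(query)
        np.testing.assert_array_equal(fuser.alpha_, a1)
        assert fused.values.shape == (8, 2)
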