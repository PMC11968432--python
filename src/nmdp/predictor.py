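"""Binary drug-response classifier: 1D convolution + Kolmogorov-Arnold head.

The fused similarity row of each sample is passed through a small 1D
convolution (localizes features, removes noise), max-pooled, and fed to
Kolmogorov-Arnold network (KAN) layers.  A KAN layer replaces the fixed
activation + dense weight of an MLP with a learnable one-dimensional
function per input-output pair:

    out_q = sum_p phi_{q,p}(x_p),    phi(x) = w1 * spline(x) + w2 * b(x)

where ``spline`` is a B-spline curve on a fixed grid and ``b`` a residual
activation (SiLU by default).  The whole network is a few tens of thousands
of parameters, sized for cohorts of a few hundred samples.

Everything is plain numpy with hand-written gradients and Adam; networks of
this size need no GPU framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# B-spline basis on a fixed uniform grid


class BSplineBasis:
    """Cox-de Boor basis of degree ``order`` on ``grid_size`` uniform intervals.

    The grid covers [lo, hi]; outside it the curve continues linearly
    (first-order Taylor extension from the clamped endpoint).
    """

    def __init__(self, grid_size: int = 8, order: int = 3, lo: float = -1.0, hi: float = 1.0):
        if order < 1 or grid_size < order + 1:
            raise ValueError("need order >= 1 and grid_size >= order + 1")
        self.grid_size = grid_size
        self.order = order
        self.lo, self.hi = lo, hi
        h = (hi - lo) / grid_size
        self.knots = np.concatenate([
            lo + h * np.arange(-order, 0), np.linspace(lo, hi, grid_size + 1),
            hi + h * np.arange(1, order + 1)])
        self.n_basis = grid_size + order

    def _raw(self, x: np.ndarray, order: int) -> np.ndarray:
        t = self.knots
        x = np.asarray(x, dtype=float)
        B = ((t[:-1] <= x[..., None]) & (x[..., None] < t[1:])).astype(float)
        for k in range(1, order + 1):
            left = np.zeros_like(B[..., :-1])
            den = t[k:-1] - t[:-k - 1]
            good = den > 0
            left[..., good] = (x[..., None] - t[:-k - 1])[..., good] * B[..., :-1][..., good] / den[good]
            right = np.zeros_like(B[..., 1:])
            den = t[k + 1:] - t[1:-k]
            good = den > 0
            right[..., good] = (t[k + 1:] - x[..., None])[..., good] * B[..., 1:][..., good] / den[good]
            B = left + right
        return B

    def design(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Basis values and derivatives at x, with linear extension off-grid.

        Returns (B, dB), each shaped ``x.shape + (n_basis,)``.
        """
        x = np.asarray(x, dtype=float)
        eps = 1e-9 * (self.hi - self.lo)
        xc = np.clip(x, self.lo, self.hi - eps)  # half-open intervals: stay inside
        B = self._raw(xc, self.order)[..., :self.n_basis]
        dB = self._deriv(xc)
        out = ~np.isclose(x, xc)
        if np.any(out):
            logger.debug("B-spline evaluated outside grid for %d point(s); linear extension", out.sum())
            delta = (x - xc)[..., None]
            B = B + dB * delta * out[..., None]
        return B, dB

    def _deriv(self, x: np.ndarray) -> np.ndarray:
        k = self.order
        t = self.knots
        Bk1 = self._raw(x, k - 1)
        den1 = t[k:-1] - t[:-k - 1]
        den2 = t[k + 1:] - t[1:-k]
        left = np.zeros(x.shape + (len(den1),))
        good = den1 > 0
        left[..., good] = k * Bk1[..., :-1][..., good] / den1[good]
        right = np.zeros(x.shape + (len(den2),))
        good = den2 > 0
        right[..., good] = k * Bk1[..., 1:][..., good] / den2[good]
        d = left - right
        return d[..., :self.n_basis]


def _silu(x):
    return x / (1.0 + np.exp(-x))


def _silu_grad(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


_RESIDUALS = {
    "silu": (_silu, _silu_grad),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class KanLayerSpec:
    n_in: int
    n_out: int
    grid_size: int = 8
    spline_order: int = 3
    residual_act: str = "silu"

    def __post_init__(self):
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError("layer dimensions must be >= 1")
        if self.spline_order < 1 or self.grid_size < self.spline_order + 1:
            raise ValueError("need spline_order >= 1 and grid_size >= spline_order + 1")


def kan_phi(x, w1, w2, spline_coeffs, basis: BSplineBasis, residual_act: str = "silu"):
    """Scalar edge function phi(x) = w1 * spline(x) + w2 * b(x)."""
    b_fn, _ = _RESIDUALS[residual_act]
    B, _ = basis.design(np.asarray(x, dtype=float))
    return w1 * (B @ np.asarray(spline_coeffs, dtype=float)) + w2 * b_fn(np.asarray(x, dtype=float))


class KanLayer:
    """One KAN layer with trainable spline coefficients and edge weights."""

    def __init__(self, spec: KanLayerSpec, rng: np.random.Generator):
        self.spec = spec
        self.basis = BSplineBasis(spec.grid_size, spec.spline_order)
        nb = self.basis.n_basis
        self.coef = rng.normal(0.0, 0.1, size=(spec.n_out, spec.n_in, nb))
        self.w1 = np.ones((spec.n_out, spec.n_in))
        self.w2 = np.ones((spec.n_out, spec.n_in))
        self.b_fn, self.b_grad = _RESIDUALS[spec.residual_act]

    def parameters(self):
        return {"coef": self.coef, "w1": self.w1, "w2": self.w2}

    def forward(self, x: np.ndarray):
        # x: (batch, n_in)
        B, dB = self.basis.design(x)            # (batch, n_in, nb)
        spline = np.einsum("bpk,qpk->bqp", B, self.coef)
        res = self.b_fn(x)                       # (batch, n_in)
        phi = self.w1[None] * spline + self.w2[None] * res[:, None, :]
        out = phi.sum(axis=2)                    # (batch, n_out)
        cache = (x, B, dB, spline, res)
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        x, B, dB, spline, res = cache
        # dout: (batch, n_out)
        d_phi = dout[:, :, None]                                  # (b, q, p)
        self.g_w1 = np.einsum("bqp,bqp->qp", d_phi, spline)
        self.g_w2 = np.einsum("bqp,bp->qp", d_phi, res)
        self.g_coef = np.einsum("bqp,bpk->qpk", d_phi * self.w1[None], B)
        dspline_dx = np.einsum("bpk,qpk->bqp", dB, self.coef)
        dx = np.einsum("bqp,bqp->bp", d_phi, self.w1[None] * dspline_dx)
        dx += np.einsum("bqp->bp", d_phi * self.w2[None]) * self.b_grad(x)
        return dx

    def grads(self):
        return {"coef": self.g_coef, "w1": self.g_w1, "w2": self.g_w2}


def kan_layer_forward(x: np.ndarray, layer: KanLayer) -> np.ndarray:
    """Functional forward pass: out_q = sum_p phi_{q,p}(x_p)."""
    out, _ = layer.forward(np.atleast_2d(np.asarray(x, dtype=float)))
    return out if np.asarray(x).ndim == 2 else out[0]


class DenseLayer:
    """Plain dense layer (SiLU inside, linear at the output) for the MLP ablation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, activation: str = "silu"):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.activation = activation

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        z = x @ self.W.T + self.b
        if self.activation == "silu":
            out = _silu(z)
        else:
            out = z
        return out, (x, z)

    def backward(self, dout, cache):
        x, z = cache
        dz = dout * _silu_grad(z) if self.activation == "silu" else dout
        self.g_W = dz.T @ x
        self.g_b = dz.sum(axis=0)
        return dz @ self.W

    def grads(self):
        return {"W": self.g_W, "b": self.g_b}


# ---------------------------------------------------------------------------
# 1D convolution + pooling


class Conv1DLayer:
    """Single-channel-in, multi-channel-out 1D cross-correlation, same padding."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.channels = channels
        self.kernel_size = kernel_size
        self.W = rng.normal(0.0, np.sqrt(2.0 / kernel_size), size=(channels, kernel_size))
        self.b = np.zeros(channels)

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        # x: (batch, F) -> (batch, C, F)
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (pad, pad)))
        F = x.shape[1]
        cols = np.stack([xp[:, i:i + F] for i in range(self.kernel_size)], axis=2)  # (b, F, K)
        out = np.einsum("bfk,ck->bcf", cols, self.W) + self.b[None, :, None]
        return out, (cols, x.shape)

    def backward(self, dout, cache):
        cols, xshape = cache
        self.g_W = np.einsum("bcf,bfk->ck", dout, cols)
        self.g_b = dout.sum(axis=(0, 2))
        pad = self.kernel_size // 2
        dxp = np.zeros((xshape[0], xshape[1] + 2 * pad))
        for k in range(self.kernel_size):
            dxp[:, k:k + xshape[1]] += np.einsum("bcf,c->bf", dout, self.W[:, k])
        return dxp[:, pad:pad + xshape[1]]

    def grads(self):
        return {"W": self.g_W, "b": self.g_b}


def conv1d_forward(row: np.ndarray, weights: np.ndarray, bias: np.ndarray | float = 0.0) -> np.ndarray:
    """Functional same-padded 1D cross-correlation of a single row."""
    row = np.asarray(row, dtype=float)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    bias = np.broadcast_to(np.asarray(bias, dtype=float), (weights.shape[0],))
    rng = np.random.default_rng(0)
    layer = Conv1DLayer(weights.shape[0], weights.shape[1], rng)
    layer.W = weights
    layer.b = np.asarray(bias, dtype=float)
    out, _ = layer.forward(row[None, :])
    return out[0]


def _maxpool(x, pool):
    # x: (batch, C, F) -> (batch, C, F//pool)
    b, c, f = x.shape
    f2 = f // pool
    xr = x[:, :, :f2 * pool].reshape(b, c, f2, pool)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), (idx, x.shape, pool)


def _maxpool_backward(dout, cache):
    idx, xshape, pool = cache
    b, c, f = xshape
    f2 = f // pool
    dx = np.zeros((b, c, f2, pool))
    np.put_along_axis(dx, idx[..., None], dout[..., None], axis=3)
    return dx.reshape(b, c, f2 * pool if f2 * pool == f else f2 * pool) if f2 * pool == f else \
        np.pad(dx.reshape(b, c, f2 * pool), ((0, 0), (0, 0), (0, f - f2 * pool)))


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in layer.parameters().items()} for layer in layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.parameters().items()} for layer in layers]
        self.t = 0

    def step(self):
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            params, grads = layer.parameters(), layer.grads()
            for key in params:
                g = grads[key]
                m[key] = self.b1 * m[key] + (1 - self.b1) * g
                v[key] = self.b2 * v[key] + (1 - self.b2) * g * g
                mhat = m[key] / (1 - self.b1 ** self.t)
                vhat = v[key] / (1 - self.b2 ** self.t)
                params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the classifier


@dataclass
class PredictorSpec:
    conv_channels: int = 2
    kernel_size: int = 5
    pool: int = 2
    kan_hidden: int = 4
    grid_size: int = 8
    spline_order: int = 3
    residual_act: str = "silu"
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    use_conv: bool = True
    head: str = "kan"  # "kan" | "mlp" (equal-budget ablation)
    validation_fraction: float = 0.0
    patience: int = 20

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.head not in ("kan", "mlp"):
            raise ValueError("head must be 'kan' or 'mlp'")


class ConvKANClassifier(BaseEstimator, ClassifierMixin):
    """1D-conv + KAN binary classifier over fused similarity rows.

    sklearn-compatible: ``fit(X, y)`` with X of shape (n_samples, n_features),
    ``predict_proba`` / ``predict`` with a 0.5 threshold on the sigmoid logit.

    Parameters mirror PredictorSpec; ``use_conv=False`` and ``head="mlp"``
    are the ablation switches.
    """

    def __init__(self, conv_channels=2, kernel_size=5, pool=2, kan_hidden=4,
                 grid_size=8, spline_order=3, residual_act="silu", epochs=200,
                 lr=1e-3, batch_size=16, seed=0, use_conv=True, head="kan",
                 validation_fraction=0.0, patience=20):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.pool = pool
        self.kan_hidden = kan_hidden
        self.grid_size = grid_size
        self.spline_order = spline_order
        self.residual_act = residual_act
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.use_conv = use_conv
        self.head = head
        self.validation_fraction = validation_fraction
        self.patience = patience

    # -- architecture ------------------------------------------------------

    def _build(self, n_features: int, rng: np.random.Generator):
        spec = PredictorSpec(self.conv_channels, self.kernel_size, self.pool,
                             self.kan_hidden, self.grid_size, self.spline_order,
                             self.residual_act, self.epochs, self.lr,
                             self.batch_size, self.seed, self.use_conv, self.head,
                             self.validation_fraction, self.patience)
        layers = []
        if spec.use_conv:
            conv = Conv1DLayer(spec.conv_channels, spec.kernel_size, rng)
            flat = spec.conv_channels * (n_features // spec.pool)
            layers.append(conv)
        else:
            conv = None
            flat = n_features
        if spec.head == "kan":
            h1 = KanLayer(KanLayerSpec(flat, spec.kan_hidden, spec.grid_size,
                                       spec.spline_order, spec.residual_act), rng)
            h2 = KanLayer(KanLayerSpec(spec.kan_hidden, 1, spec.grid_size,
                                       spec.spline_order, spec.residual_act), rng)
            head = [h1, h2]
        else:
            # match the KAN budget: per-edge count is n_basis + 2
            per_edge = spec.grid_size + spec.spline_order + 2
            hidden = max(2, round((flat * spec.kan_hidden + spec.kan_hidden) * per_edge
                                  / (flat + spec.kan_hidden + 2)))
            head = [DenseLayer(flat, hidden, rng, "silu"),
                    DenseLayer(hidden, 1, rng, "linear")]
        layers.extend(head)
        return spec, conv, head, layers

    def _forward(self, X, train=False):
        caches = []
        h = X
        if self._conv is not None:
            h, c = self._conv.forward(h)
            h = np.maximum(h, 0.0)
            relu_mask = h > 0
            h, pc = _maxpool(h, self._spec.pool)
            caches.append((c, relu_mask, pc))
            h = h.reshape(h.shape[0], -1)
        for layer in self._head:
            h, c = layer.forward(h)
            caches.append(c)
        return h[:, 0], caches

    def _backward(self, dlogit, caches):
        d = dlogit[:, None]
        off = 1 if self._conv is not None else 0
        for i in range(len(self._head) - 1, -1, -1):
            d = self._head[i].backward(d, caches[off + i])
        if self._conv is not None:
            c, relu_mask, pc = caches[0]
            b = d.shape[0]
            f2 = relu_mask.shape[2] // self._spec.pool
            d = d.reshape(b, self._spec.conv_channels, f2)
            d = _maxpool_backward(d, pc)
            d = d * relu_mask
            self._conv.backward(d, c)

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present in y")
        rng = np.random.default_rng(self.seed)
        self._spec, self._conv, self._head, layers = self._build(X.shape[1], rng)
        self.n_parameters_ = int(sum(p.size for layer in layers
                                     for p in layer.parameters().values()))
        logger.info("predictor has %d trainable parameters", self.n_parameters_)
        # standardize inputs onto the spline grid's working range
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        n = Xs.shape[0]
        n_val = int(round(self._spec.validation_fraction * n))
        if n_val > 0:
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xval, yval = Xs[val_idx], y[val_idx]
            Xtr, ytr = Xs[tr_idx], y[tr_idx]
        else:
            Xtr, ytr = Xs, y
            Xval = yval = None
        opt = Adam(layers, lr=self._spec.lr)
        self.loss_history_ = []
        best_val, best_state, stall = np.inf, None, 0
        for epoch in range(self._spec.epochs):
            perm = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(Xtr), self._spec.batch_size):
                idx = perm[start:start + self._spec.batch_size]
                logit, caches = self._forward(Xtr[idx], train=True)
                p = 1.0 / (1.0 + np.exp(-logit))
                eps = 1e-12
                loss = -np.mean(ytr[idx] * np.log(p + eps) + (1 - ytr[idx]) * np.log(1 - p + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss}")
                losses.append(loss)
                self._backward((p - ytr[idx]) / len(idx), caches)
                opt.step()
            self.loss_history_.append(float(np.mean(losses)))
            if Xval is not None:
                vlogit, _ = self._forward(Xval)
                vp = 1.0 / (1.0 + np.exp(-vlogit))
                vloss = -np.mean(yval * np.log(vp + 1e-12) + (1 - yval) * np.log(1 - vp + 1e-12))
                if vloss < best_val - 1e-6:
                    best_val, stall = vloss, 0
                    best_state = [{k: v.copy() for k, v in layer.parameters().items()}
                                  for layer in layers]
                else:
                    stall += 1
                    if stall >= self._spec.patience:
                        break
        if Xval is not None and best_state is not None:
            for layer, state in zip(layers, best_state):
                for k, v in layer.parameters().items():
                    v[:] = state[k]
        return self

    def decision_function(self, X):
        X = (np.asarray(X, dtype=float) - self._mu) / self._sd
        logit, _ = self._forward(X)
        return logit

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)


# ---------------------------------------------------------------------------
# metrics


def evaluate(y_true, y_pred) -> dict:
    """Sensitivity, specificity, precision, accuracy and F1, per class and macro."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def _safe(num, den):
        return num / den if den else 0.0

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    prec_pos = _safe(tp, tp + fp)
    prec_neg = _safe(tn, tn + fn)
    acc = _safe(tp + tn, tp + tn + fp + fn)
    f1_pos = _safe(2 * prec_pos * sens, prec_pos + sens)
    f1_neg = _safe(2 * prec_neg * spec, prec_neg + spec)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec_pos,
        "precision_negative": prec_neg,
        "accuracy": acc,
        "f1": f1_pos,
        "f1_negative": f1_neg,
        "f1_macro": (f1_pos + f1_neg) / 2.0,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
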