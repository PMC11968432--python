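"""Hartigan dip statistic and Monte-Carlo p-value, from scratch.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to a mode, concave after it).  It is
computed with the classical iterative construction: on a shrinking modal
window, build the greatest convex minorant (GCM) and least concave majorant
(LCM) of the ECDF midpoints, take the largest separation between the two
curves, and accumulate the one-sided fit errors of the regions outside the
window.  The statistic lives in ``[1/(2n), 1/4]``.

The computation assumes continuous data; tied values are broken by an
infinitesimal deterministic perturbation of the sort order, which leaves
untied samples untouched.

p-values are calibrated by Monte Carlo against the uniform null: the dip of
``n_boot`` uniform(0,1) samples of the same size.  Null tables are cached
per (n, n_boot, seed) because every similarity block of a cohort shares the
same sample count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np


@dataclass
class DipResult:
    dip: float
    pvalue: float
    n_boot: int
    n: int


def _gcm_touch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the greatest convex minorant touch points of (x, y)."""
    stack = [0]
    for i in range(1, len(x)):
        # pop while the last touch point lies on or above the chord
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            if (y[b] - y[a]) * (x[i] - x[b]) >= (y[i] - y[b]) * (x[b] - x[a]):
                stack.pop()
            else:
                break
        stack.append(i)
    return np.asarray(stack, dtype=int)


def _lcm_touch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the least concave majorant touch points of (x, y)."""
    stack = [0]
    for i in range(1, len(x)):
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            if (y[b] - y[a]) * (x[i] - x[b]) <= (y[i] - y[b]) * (x[b] - x[a]):
                stack.pop()
            else:
                break
        stack.append(i)
    return np.asarray(stack, dtype=int)


def _interp_curve(touch: np.ndarray, x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    return np.interp(xq, x[touch], y[touch])


def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic of a one-dimensional sample (n >= 4, non-constant)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"dip needs n >= 4, got {n}")
    if x[0] == x[-1]:
        raise ValueError("constant input: dip undefined")
    if np.any(np.diff(x) == 0):
        # break ties: keep order, nudge positions apart by a negligible amount
        span = x[-1] - x[0]
        x = x + np.arange(n) * (span * 1e-12)
    mids = (np.arange(n) + 0.5) / n  # ECDF midpoints, the fit targets
    low, high = 0, n - 1
    delta = 0.0
    for _ in range(n):  # the window shrinks strictly; n iterations is a safe cap
        xs = x[low:high + 1]
        ys = mids[low:high + 1]
        g = _gcm_touch(xs, ys)
        l = _lcm_touch(xs, ys)
        # largest separation between the two curves, tracked with the touch
        # points bracketing it
        g_on_l = _interp_curve(l, xs, ys, xs[g])
        l_on_g = _interp_curve(g, xs, ys, xs[l])
        sep_g = g_on_l - ys[g]          # lcm curve above a gcm touch point
        sep_l = ys[l] - l_on_g          # lcm touch point above the gcm curve
        ig_pos = int(np.argmax(sep_g))
        il_pos = int(np.argmax(sep_l))
        if sep_g[ig_pos] >= sep_l[il_pos]:
            d = float(sep_g[ig_pos])
            new_low = low + int(g[ig_pos])
            # lcm touch point at or after the separation point
            after = l[xs[l] >= xs[g[ig_pos]]]
            new_high = low + int(after[0]) if after.size else high
        else:
            d = float(sep_l[il_pos])
            new_high = low + int(l[il_pos])
            before = g[xs[g] <= xs[l[il_pos]]]
            new_low = low + int(before[-1]) if before.size else low
        if d <= delta:
            break
        # one-sided fit errors of the regions outside the new modal window
        gcm_curve = _interp_curve(g, xs, ys, xs)
        lcm_curve = _interp_curve(l, xs, ys, xs)
        left = slice(0, new_low - low + 1)
        right = slice(new_high - low, high - low + 1)
        delta_l = float(np.max(ys[left] - gcm_curve[left])) if new_low > low else 0.0
        delta_u = float(np.max(lcm_curve[right] - ys[right])) if new_high < high else 0.0
        delta = max(delta, delta_l, delta_u)
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high
    return delta / 2.0 + 1.0 / (2.0 * n)


@lru_cache(maxsize=32)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot))


def dip_pvalue(dip: float, n: int, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Monte-Carlo p-value: fraction of uniform-null dips >= the observed dip."""
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: p-value resolution is poor")
    null = np.asarray(_null_dips(n, n_boot, seed))
    p = float(np.mean(null >= dip))
    return DipResult(dip=float(dip), pvalue=p, n_boot=n_boot, n=n)


def dip_test(x: np.ndarray, n_boot: int = 2000, seed: int = 0) -> DipResult:
    d = dip_statistic(x)
    return dip_pvalue(d, n=len(np.asarray(x)), n_boot=n_boot, seed=seed)
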