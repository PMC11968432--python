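"""Waterfall binarization of per-drug IC50 vectors.

Samples are sorted by IC50 and the sorted curve is fit with a linear model
against rank.  A near-linear curve (Pearson r > 0.95) has no natural elbow,
so the median splits the cohort; otherwise the cutoff is the sorted point
furthest from the chord joining the curve's endpoints.  Responsive means
IC50 <= cutoff (lower concentration needed = more sensitive).  A balancing
rule guarantees the responsive group is at least 25% of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .types_io import ResponseLabels

logger = logging.getLogger(__name__)

PEARSON_THRESHOLD = 0.95
MIN_RESPONSIVE_FRACTION = 0.25


class DrugSkipped(ValueError):
    """Too few IC50 measurements for this drug."""


class DegenerateInput(ValueError):
    """IC50 vector is constant; no cutoff exists."""


@dataclass
class WaterfallFit:
    pearson_r: float
    cutoff: float
    method: str  # "median" | "furthest-point"


def filter_drug(ic50: np.ndarray, min_samples: int = 200) -> np.ndarray:
    """Drop missing IC50 entries; signal a skip below the minimum count."""
    ic50 = np.asarray(ic50, dtype=float)
    finite = ic50[np.isfinite(ic50)]
    if finite.size < min_samples:
        raise DrugSkipped(f"{finite.size} finite IC50 values < minimum {min_samples}")
    return finite


def _chord_distances(sorted_vals: np.ndarray, vertical: bool = False) -> np.ndarray:
    """Distance from every sorted point to the chord through the endpoints.

    Ranks are 1..n on the x axis.  Perpendicular distance by default;
    vertical (residual) distance behind the flag.
    """
    n = sorted_vals.size
    x = np.arange(1, n + 1, dtype=float)
    x0, y0 = x[0], sorted_vals[0]
    x1, y1 = x[-1], sorted_vals[-1]
    # line: (y1-y0)(x-x0) - (x1-x0)(y-y0) = 0
    num = np.abs((y1 - y0) * (x - x0) - (x1 - x0) * (sorted_vals - y0))
    if vertical:
        return num / abs(x1 - x0)
    return num / np.hypot(x1 - x0, y1 - y0)


def waterfall_cutoff(ic50: np.ndarray, vertical_distance: bool = False) -> WaterfallFit:
    """Choose the IC50 cutoff from the shape of the sorted curve."""
    ic50 = np.asarray(ic50, dtype=float)
    ic50 = ic50[np.isfinite(ic50)]
    if ic50.size < 4:
        raise DegenerateInput(f"need >= 4 finite IC50 values, got {ic50.size}")
    if np.ptp(ic50) == 0:
        raise DegenerateInput("constant IC50 vector")
    s = np.sort(ic50)
    ranks = np.arange(1, s.size + 1, dtype=float)
    r = float(stats.pearsonr(ranks, s)[0])
    if r > PEARSON_THRESHOLD:
        return WaterfallFit(pearson_r=r, cutoff=float(np.median(s)), method="median")
    dist = _chord_distances(s, vertical=vertical_distance)
    elbow = int(np.argmax(dist))
    return WaterfallFit(pearson_r=r, cutoff=float(s[elbow]), method="furthest-point")


def assign_labels(
    ic50: np.ndarray,
    fit: WaterfallFit,
    sample_ids: list[str] | None = None,
) -> ResponseLabels:
    """Label responsive iff IC50 <= cutoff, enforcing >= 25% responsive.

    If the responsive group falls short the cutoff is raised to the 25th
    percentile, keeping every sample in the cohort.
    """
    ic50 = np.asarray(ic50, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(ic50.size)]
    cutoff = fit.cutoff
    label = (ic50 <= cutoff).astype(int)
    if label.mean() < MIN_RESPONSIVE_FRACTION:
        cutoff = float(np.quantile(ic50, MIN_RESPONSIVE_FRACTION, method="inverted_cdf"))
        label = (ic50 <= cutoff).astype(int)
        logger.info("responsive fraction below %.0f%%; cutoff moved to 25th percentile %.4g",
                    100 * MIN_RESPONSIVE_FRACTION, cutoff)
    if label.all():
        logger.warning("all samples labeled responsive (every IC50 below cutoff)")
    return ResponseLabels(sample_ids=list(sample_ids), ic50=ic50, label=label,
                          cutoff=cutoff, method=fit.method)


class WaterfallLabeler(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit on an IC50 vector, transform IC50 -> binary labels.

    Parameters
    ----------
    min_samples : minimum finite IC50 count for a drug to be modeled.
    vertical_distance : use vertical instead of perpendicular chord distance
        when locating the elbow.
    """

    def __init__(self, min_samples: int = 200, vertical_distance: bool = False):
        self.min_samples = min_samples
        self.vertical_distance = vertical_distance

    def fit(self, ic50, y=None):
        ic50 = filter_drug(np.asarray(ic50, dtype=float).ravel(), self.min_samples)
        fit = waterfall_cutoff(ic50, vertical_distance=self.vertical_distance)
        labels = assign_labels(ic50, fit)
        self.pearson_r_ = fit.pearson_r
        self.method_ = fit.method
        self.cutoff_ = labels.cutoff
        return self

    def transform(self, ic50):
        ic50 = np.asarray(ic50, dtype=float).ravel()
        return (ic50 <= self.cutoff_).astype(int)

    def fit_transform(self, ic50, y=None, **kwargs):
        return self.fit(ic50).transform(np.asarray(ic50, dtype=float).ravel()[
            np.isfinite(np.asarray(ic50, dtype=float).ravel())])
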