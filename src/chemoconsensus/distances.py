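"""Compound–compound dissimilarities with pairwise-complete missing handling.

Seven measures, matching the Cluster-3.0 family used to cluster compound
interaction profiles:

============================  =====================================================
name                          dissimilarity for profiles x, y (over co-present genes)
============================  =====================================================
``centered_corr``             ``1 - r`` (Pearson)
``uncentered_corr``           ``1 - Σxy / sqrt(Σx² · Σy²)`` (cosine-like, no centering)
``abs_centered_corr``         ``1 - |r|``
``abs_uncentered_corr``       ``1 - |Σxy / sqrt(Σx² · Σy²)|``
``spearman``                  ``1 - r_s`` (Pearson of mid-ranks, average-tie method)
``euclidean``                 ``sqrt(Σ(x - y)²)``
``cityblock``                 ``Σ|x - y|``
============================  =====================================================

Missing entries are handled by pairwise-complete deletion: each pair is
compared only over genes present in both profiles, and the euclidean /
cityblock sums are *not* rescaled by the shared-gene count unless
``scale_by_shared`` is set. Undefined correlations (constant profile, or
fewer than two shared genes) are assigned the measure's maximum distance —
no evidence of similarity — with a logged warning. A pair with *zero*
shared genes under euclidean/cityblock carries no information at all and is
set to NaN, which downstream stages treat as a degenerate trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

from .errors import ParameterError
from .matrixio import ChemGenMatrix

log = logging.getLogger(__name__)

MEASURES = (
    "centered_corr",
    "uncentered_corr",
    "abs_centered_corr",
    "abs_uncentered_corr",
    "spearman",
    "euclidean",
    "cityblock",
)

#: Maximum attainable distance for the correlation family (fallback for
#: undefined correlations). Metric measures have no finite maximum.
_CORR_MAX = {
    "centered_corr": 2.0,
    "uncentered_corr": 2.0,
    "abs_centered_corr": 1.0,
    "abs_uncentered_corr": 1.0,
    "spearman": 2.0,
}


@dataclass
class DistanceMatrix:
    """Symmetric compound × compound dissimilarity matrix under one measure."""

    ids: list[str]
    d: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ParameterError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ParameterError("distance matrix must be symmetric")
        if not np.all(np.diag(self.d) == 0.0):
            raise ParameterError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_degenerate(self) -> bool:
        """True if any off-diagonal entry is NaN (uninformative pair)."""
        return bool(np.isnan(self.d).any())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, or NaN if either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _uncentered(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0.0:
        return np.nan
    return float(np.clip((x @ y) / denom, -1.0, 1.0))


def profile_distance(
    x: np.ndarray,
    y: np.ndarray,
    shared: np.ndarray,
    measure: str,
    scale_by_shared: bool = False,
) -> float:
    """Dissimilarity between two full-length profiles over ``shared`` genes.

    ``shared`` is the boolean co-presence mask. This is the single authority
    for the measure formulas; both the pairwise driver and centroid linkage
    call it.
    """
    if measure not in MEASURES:
        raise ParameterError(f"unknown measure {measure!r}")
    k = int(shared.sum())
    xs = np.asarray(x, dtype=float)[shared]
    ys = np.asarray(y, dtype=float)[shared]

    if measure in _CORR_MAX:
        if k < 2:
            log.warning("measure %s undefined with %d shared genes; using max", measure, k)
            return _CORR_MAX[measure]
        if measure == "spearman":
            xs = rankdata(xs, method="average")
            ys = rankdata(ys, method="average")
            r = _pearson(xs, ys)
        elif measure in ("centered_corr", "abs_centered_corr"):
            r = _pearson(xs, ys)
        else:
            r = _uncentered(xs, ys)
        if np.isnan(r):
            log.warning("measure %s undefined (constant profile); using max", measure)
            return _CORR_MAX[measure]
        if measure.startswith("abs_"):
            return 1.0 - abs(r)
        return 1.0 - r

    if k == 0:
        log.warning("measure %s has no shared genes for a pair; distance is NaN", measure)
        return np.nan
    diff = xs - ys
    if measure == "euclidean":
        s = float(diff @ diff)
        if scale_by_shared:
            s /= k
        return float(np.sqrt(s))
    s = float(np.abs(diff).sum())
    if scale_by_shared:
        s /= k
    return s


def _complete_data_fast(values: np.ndarray, measure: str) -> np.ndarray:
    """Vectorised distances when no cell is missing (identical formulas)."""
    if measure == "spearman":
        values = np.apply_along_axis(rankdata, 1, values)
    if measure in ("spearman", "centered_corr", "abs_centered_corr"):
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(values)
    elif measure in ("uncentered_corr", "abs_uncentered_corr"):
        norms = np.sqrt((values * values).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (values @ values.T) / np.outer(norms, norms)
    elif measure == "euclidean":
        return squareform(pdist(values, metric="euclidean"))
    else:
        return squareform(pdist(values, metric="cityblock"))
    r = np.clip(r, -1.0, 1.0)
    if measure.startswith("abs_"):
        d = 1.0 - np.abs(r)
    else:
        d = 1.0 - r
    # constant profiles yield NaN correlations -> maximum distance
    bad = np.isnan(d)
    if bad.any():
        log.warning("constant profile(s) under %s; assigning maximum distance", measure)
        d[bad] = _CORR_MAX[measure]
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distance(
    m: ChemGenMatrix, measure: str, scale_by_shared: bool = False
) -> DistanceMatrix:
    """All-pairs compound dissimilarity matrix under ``measure``."""
    if measure not in MEASURES:
        raise ParameterError(f"unknown measure {measure!r}")
    n = len(m.compound_ids)
    if n < 2:
        raise ParameterError("need at least two compounds")

    if m.mask.all() and not scale_by_shared:
        d = _complete_data_fast(np.where(m.mask, m.values, 0.0), measure)
    else:
        d = np.zeros((n, n))
        for i in range(n):
            xi, mi = m.values[i], m.mask[i]
            for j in range(i + 1, n):
                shared = mi & m.mask[j]
                d[i, j] = d[j, i] = profile_distance(
                    xi, m.values[j], shared, measure, scale_by_shared
                )
    # guard against tiny negative round-off in the correlation family
    if measure in _CORR_MAX:
        np.clip(d, 0.0, _CORR_MAX[measure], out=d)
    return DistanceMatrix(list(m.compound_ids), d, measure)
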