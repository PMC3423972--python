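"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles —
direct formulas, from-scratch re-scans, exhaustive enumeration — so they
share no code path with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from chemoconsensus import ChemGenMatrix, SimParams, generate

# ---------------------------------------------------------------- distance oracle


def naive_distance(values, mask, i, j, measure):
    """Direct-formula dissimilarity between rows i and j over co-present genes."""
    shared = mask[i] & mask[j]
    x = values[i][shared]
    y = values[j][shared]
    k = len(x)
    if measure in ("euclidean", "cityblock"):
        diff = x - y
        return math.sqrt(float(np.sum(diff * diff))) if measure == "euclidean" \
            else float(np.sum(np.abs(diff)))
    if k < 2:
        return 1.0 if measure.startswith("abs_") else 2.0
    if measure in ("centered_corr", "abs_centered_corr"):
        if np.std(x) == 0 or np.std(y) == 0:
            return 1.0 if measure.startswith("abs_") else 2.0
        r = stats.pearsonr(x, y).statistic
    elif measure == "spearman":
        if np.std(x) == 0 or np.std(y) == 0:
            return 2.0
        r = stats.spearmanr(x, y).statistic
        if np.isnan(r):  # constant ranks
            return 2.0
    else:  # uncentered family
        denom = math.sqrt(float(np.sum(x * x)) * float(np.sum(y * y)))
        if denom == 0:
            return 1.0 if measure.startswith("abs_") else 2.0
        r = float(np.sum(x * y)) / denom
    if measure.startswith("abs_"):
        return 1.0 - abs(r)
    return 1.0 - float(r)


def naive_distance_matrix(values, mask, measure):
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = naive_distance(values, mask, i, j, measure)
    return d


# ---------------------------------------------------------------- clustering oracle


def rescan_cluster(d0, linkage, values=None, mask=None, measure=None):
    """From-scratch agglomeration oracle.

    Clusters are explicit member lists; at every step *all* inter-cluster
    distances are recomputed from the original pairwise matrix (or, for
    centroid linkage, from mean profiles recomputed from the original
    values). Tie-break: lexicographically least (min-member, max-member)
    pair among ties. Returns (list of merged member-frozenset pairs, heights).
    """
    n = d0.shape[0]
    clusters = [[i] for i in range(n)]
    merges, heights = [], []

    def inter(ca, cb):
        if linkage == "centroid":
            da = np.asarray([values[i] for i in ca], float)
            db = np.asarray([values[i] for i in cb], float)
            ma = np.asarray([mask[i] for i in ca], bool)
            mb = np.asarray([mask[i] for i in cb], bool)
            with np.errstate(invalid="ignore"):
                cen_a = np.where(ma, da, 0).sum(0) / np.maximum(ma.sum(0), 1)
                cen_b = np.where(mb, db, 0).sum(0) / np.maximum(mb.sum(0), 1)
            sh = (ma.sum(0) > 0) & (mb.sum(0) > 0)
            vv = np.vstack([np.where(sh, cen_a, np.nan), np.where(sh, cen_b, np.nan)])
            mm = np.vstack([sh, sh])
            return naive_distance(vv, mm, 0, 1, measure)
        cross = [d0[i, j] for i in ca for j in cb]
        if linkage == "single":
            return min(cross)
        if linkage == "complete":
            return max(cross)
        return sum(cross) / len(cross)

    for _ in range(n - 1):
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = inter(clusters[a], clusters[b])
                ra = min(clusters[a] + clusters[b])
                rb = max(min(clusters[a]), min(clusters[b]))
                key = (dist, (ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _), a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b])))
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges, heights


def assert_same_tree(dend, oracle_merges, oracle_heights, tol=1e-9):
    """Topology + heights agreement between a Dendrogram and the oracle."""
    for k, mg in enumerate(dend.merges):
        left = frozenset(dend.members(mg.left))
        right = frozenset(dend.members(mg.right))
        assert {left, right} == {oracle_merges[k][0], oracle_merges[k][1]}, (
            f"merge {k} topology differs"
        )
        assert mg.height == pytest.approx(oracle_heights[k], abs=tol)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def planted_screen():
    """Default synthetic screen with a strong planted module."""
    return generate(SimParams(seed=11))


@pytest.fixture()
def tiny_matrix():
    """3 compounds x 4 genes, one missing cell, hand-checkable."""
    values = np.array(
        [
            [0.01, 0.02, 0.90, 0.50],
            [0.02, 0.01, 0.80, 0.40],
            [0.90, 0.95, np.nan, 0.10],
        ]
    )
    return ChemGenMatrix(["sig", "near", "far"], list("ABCD"), values)


def random_masked_matrix(rng, n=10, g=30, missing=0.1):
    """Random raw-p matrix with MCAR missingness, every pair co-complete."""
    values = rng.uniform(size=(n, g))
    while True:
        mask = rng.uniform(size=(n, g)) >= missing
        shared_ok = all(
            (mask[i] & mask[j]).sum() >= 2
            for i in range(n)
            for j in range(i + 1, n)
        )
        if shared_ok:
            break
    ids = [f"c{i:02d}" for i in range(n)]
    genes = [f"g{j:02d}" for j in range(g)]
    return ChemGenMatrix(ids, genes, values, mask)
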