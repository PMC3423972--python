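"""Agglomerative hierarchical clustering with the four classic linkages.

The tree is built greedily: at each step the pair of active clusters at
minimum inter-cluster dissimilarity is merged, and that dissimilarity is
recorded as the merge height. Inter-cluster dissimilarity per linkage:

* ``single``   — minimum over all cross pairs,
* ``complete`` — maximum over all cross pairs,
* ``average``  — unweighted arithmetic mean over all cross pairs (UPGMA),
* ``centroid`` — the trial's *measure* applied to the coordinate-wise mean
  profiles of the two clusters (mean over present entries per gene).

The centroid rule follows Cluster-3.0 semantics — the centroid is formed in
profile space and compared under whatever measure the trial uses — rather
than the Lance–Williams update, which is valid only for squared-Euclidean
geometry. This is what lets centroid linkage pair with correlation
measures. Centroid heights may therefore invert (decrease); inversions are
logged, not rejected.

Ties at the minimum distance are broken deterministically: among tied pairs,
merge the one whose (smaller, larger) tuple of cluster representatives —
each cluster represented by its smallest original leaf index — is
lexicographically least.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .distances import DistanceMatrix, profile_distance
from .errors import ParameterError
from .matrixio import ChemGenMatrix

log = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average", "centroid")


class Merge(NamedTuple):
    """One agglomeration step. Node ids: leaves are ``0..n-1``; the k-th
    merge (0-based) creates node ``n + k``."""

    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    """Result of one clustering trial: ordered merges over named leaves."""

    leaf_ids: list[str]
    merges: list[Merge]
    linkage: str
    measure: str

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ParameterError(f"expected {n - 1} merges, got {len(self.merges)}")
        seen: set[int] = set()
        for k, mg in enumerate(self.merges):
            for child in (mg.left, mg.right):
                if child in seen:
                    raise ParameterError(f"node {child} consumed twice")
                if child >= n + k:
                    raise ParameterError(f"merge {k} references undefined node {child}")
                seen.add(child)
            if mg.height < 0 and not np.isclose(mg.height, 0.0):
                raise ParameterError("negative merge height")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def members(self, node: int) -> list[int]:
        """Original leaf indices under ``node``, in traversal order."""
        n = self.n_leaves
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                mg = self.merges[v - n]
                stack.append(mg.right)
                stack.append(mg.left)
        return out

    def leaf_order(self) -> list[int]:
        """Display order of leaves: depth-first from the root, left first."""
        return self.members(self.n_leaves + len(self.merges) - 1)

    def cut(self, k: int) -> list[list[str]]:
        """Partition the leaves into ``k`` groups by undoing the last
        ``k - 1`` merges (ties in height are thereby broken by merge order:
        later merges are undone first). Groups are ordered by their smallest
        original leaf index."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ParameterError(f"k={k} out of range [1, {n}]")
        roots = [mg.left for mg in self.merges[n - k :]] + [
            mg.right for mg in self.merges[n - k :]
        ]
        if k == 1:
            roots = [n + len(self.merges) - 1]
        else:
            # roots are exactly the children of undone merges that are not
            # themselves undone merges
            undone = {n + i for i in range(n - k, n - 1)}
            roots = [r for r in roots if r not in undone]
        groups = [sorted(self.members(r)) for r in roots]
        groups.sort(key=lambda g: g[0])
        return [[self.leaf_ids[i] for i in g] for g in groups]

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances: entry (i, j) is the height of the
        merge that first joins leaves i and j."""
        n = self.n_leaves
        coph = np.zeros((n, n))
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for k, mg in enumerate(self.merges):
            left, right = members.pop(mg.left), members.pop(mg.right)
            for i in left:
                for j in right:
                    coph[i, j] = coph[j, i] = mg.height
            members[n + k] = left + right
        return DistanceMatrix(list(self.leaf_ids), coph, "cophenetic")


def _centroid_state(profiles: ChemGenMatrix, idx: int):
    vals = np.where(profiles.mask[idx], profiles.values[idx], 0.0)
    return vals.copy(), profiles.mask[idx].astype(float).copy()


def cluster(
    d: DistanceMatrix,
    linkage: str,
    profiles: Optional[ChemGenMatrix] = None,
) -> Dendrogram:
    """Agglomerate ``d`` under ``linkage`` into a :class:`Dendrogram`.

    ``profiles`` (the matrix that produced ``d``) is required for centroid
    linkage, whose inter-cluster distance is computed between mean profiles
    rather than from the input distances.
    """
    if linkage not in LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    n = d.n
    if n < 2:
        raise ParameterError("need at least two items to cluster")
    if np.isnan(d.d).any():
        raise ParameterError("distance matrix contains NaN (degenerate pair)")
    if linkage == "centroid":
        if profiles is None:
            raise ParameterError("centroid linkage requires the profile matrix")
        if list(profiles.compound_ids) != list(d.ids):
            raise ParameterError("profiles do not match distance matrix ids")

    # active cluster state, keyed by node id
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # smallest original leaf index
    cur: dict[tuple[int, int], float] = {
        (i, j): float(d.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    if linkage == "centroid":
        csum: dict[int, np.ndarray] = {}
        ccnt: dict[int, np.ndarray] = {}
        for i in range(n):
            csum[i], ccnt[i] = _centroid_state(profiles, i)

    merges: list[Merge] = []
    active = set(range(n))
    prev_height = -np.inf
    for step in range(n - 1):
        best_key = None
        best = (np.inf, (np.inf, np.inf))
        for (a, b), dist in cur.items():
            tie = (min(rep[a], rep[b]), max(rep[a], rep[b]))
            if (dist, tie) < best:
                best = (dist, tie)
                best_key = (a, b)
        assert best_key is not None
        a, b = best_key
        height = best[0]
        if height < prev_height and not np.isclose(height, prev_height):
            log.info(
                "height inversion at step %d (%s linkage): %.6g < %.6g",
                step, linkage, height, prev_height,
            )
        prev_height = height
        new = n + step
        merges.append(Merge(a, b, height))
        active.discard(a)
        active.discard(b)
        del cur[(a, b)]

        if linkage == "centroid":
            csum[new] = csum.pop(a) + csum.pop(b)
            ccnt[new] = ccnt.pop(a) + ccnt.pop(b)
            with np.errstate(invalid="ignore"):
                cen_new = csum[new] / np.maximum(ccnt[new], 1.0)

        for c in active:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            da, db = cur.pop(ka), cur.pop(kb)
            if linkage == "single":
                nd = min(da, db)
            elif linkage == "complete":
                nd = max(da, db)
            elif linkage == "average":
                nd = (size[a] * da + size[b] * db) / (size[a] + size[b])
            else:
                with np.errstate(invalid="ignore"):
                    cen_c = csum[c] / np.maximum(ccnt[c], 1.0)
                shared = (ccnt[new] > 0) & (ccnt[c] > 0)
                nd = profile_distance(cen_new, cen_c, shared, d.measure)
            cur[(min(new, c), max(new, c))] = nd

        size[new] = size.pop(a) + size.pop(b)
        rep[new] = min(rep.pop(a), rep.pop(b))
        active.add(new)

    return Dendrogram(list(d.ids), merges, linkage, d.measure)
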