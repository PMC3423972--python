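"""Consensus co-clustering prioritization around a signature compound.

The idea: a single hierarchical clustering of compound interaction profiles
depends heavily on the arbitrary choice of similarity measure and linkage.
Compounds that share a mechanism with the signature compound should land in
its subcluster under *many* such choices, not just one. So we run a grid of
clustering trials — each a (measure, linkage) pair — extract the signature's
subcluster in each tree, and rank every compound by the fraction of trials
in which it co-clusters with the signature. That fraction is the consensus
frequency; high-frequency compounds are the prioritized candidates.

"Subcluster" is operationalized two ways:

* ``MinSize(m)`` (default) — the smallest ancestor cluster of the signature
  leaf containing at least ``m`` leaves: the compounds nearest the signature
  in the tree, robust to overall tree depth;
* ``CutK(k)`` — the block containing the signature after cutting the tree
  into ``k`` clusters.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .distances import MEASURES, DistanceMatrix, pairwise_distance
from .errors import IdentifierError, ParameterError
from .hierarchy import LINKAGES, Dendrogram, cluster
from .matrixio import ChemGenMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialSpec:
    """One clustering trial: a (similarity measure, linkage) combination."""

    measure: str
    linkage: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ParameterError(f"unknown measure {self.measure!r}")
        if self.linkage not in LINKAGES:
            raise ParameterError(f"unknown linkage {self.linkage!r}")

    def __str__(self) -> str:
        return f"{self.measure}:{self.linkage}"

    @classmethod
    def parse(cls, text: str) -> "TrialSpec":
        try:
            measure, linkage = text.split(":")
        except ValueError:
            raise ParameterError(
                f"trial spec {text!r} is not of the form measure:linkage"
            ) from None
        return cls(measure.strip(), linkage.strip())


@dataclass(frozen=True)
class CutK:
    """Subcluster policy: block containing the signature after a k-cut."""

    k: int


@dataclass(frozen=True)
class MinSize:
    """Subcluster policy: smallest signature ancestor with >= m leaves."""

    m: int


Policy = Union[CutK, MinSize]


def default_min_size(n_compounds: int) -> int:
    """Default subcluster window: max(2, ceil(0.05 * n))."""
    return max(2, math.ceil(0.05 * n_compounds))


def parse_policy(text: str) -> Policy:
    """Parse ``min_size:8`` or ``cut_k:5``."""
    try:
        name, num = text.split(":")
        num_i = int(num)
    except ValueError:
        raise ParameterError(f"bad policy spec {text!r}") from None
    if name == "min_size":
        return MinSize(num_i)
    if name == "cut_k":
        return CutK(num_i)
    raise ParameterError(f"unknown policy {name!r}")


def enumerate_trials(
    measures: Sequence[str],
    linkages: Sequence[str],
    exclude: Iterable[TrialSpec] = (),
) -> list[TrialSpec]:
    """Cartesian product of measures × linkages minus exclusions,
    deterministic measures-major order."""
    if not measures or not linkages:
        raise ParameterError("measure and linkage lists must be nonempty")
    excluded = set(exclude)
    trials = [
        t
        for t in (
            TrialSpec(m, l) for m, l in itertools.product(measures, linkages)
        )
        if t not in excluded
    ]
    return trials


def signature_subcluster(
    t: Dendrogram, signature_id: str, policy: Policy
) -> set[str]:
    """Leaf ids of the signature's subcluster in one tree, under ``policy``."""
    if signature_id not in t.leaf_ids:
        raise IdentifierError(f"signature {signature_id!r} not among leaves")
    if isinstance(policy, CutK):
        for group in t.cut(policy.k):
            if signature_id in group:
                return set(group)
        raise AssertionError("cut lost the signature leaf")  # pragma: no cover
    if isinstance(policy, MinSize):
        if policy.m < 1:
            raise ParameterError("min_size requires m >= 1")
        n = t.n_leaves
        node = t.leaf_ids.index(signature_id)
        parent_of = {}
        for k, mg in enumerate(t.merges):
            parent_of[mg.left] = n + k
            parent_of[mg.right] = n + k
        members = [node]
        while len(members) < policy.m and node in parent_of:
            node = parent_of[node]
            members = t.members(node)
        return {t.leaf_ids[i] for i in members}
    raise ParameterError(f"unknown policy {policy!r}")


@dataclass
class ConsensusRanking:
    """Per-compound co-clustering frequency with the signature compound."""

    signature_id: str
    trials_run: int
    frequency: dict[str, float]
    per_trial_members: dict[TrialSpec, frozenset[str]]
    policy: Policy
    skipped: list[TrialSpec] = field(default_factory=list)

    def ranking(self) -> list[tuple[str, float]]:
        """(compound, frequency) sorted by descending frequency, ties by id."""
        return sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int, include_signature: bool = False) -> list[str]:
        """Top-k compounds by frequency (signature excluded by default)."""
        out = [
            c for c, _ in self.ranking() if include_signature or c != self.signature_id
        ]
        return out[:k]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": r,
                "compound_id": c,
                "frequency": f,
                "n_trials": self.trials_run,
            }
            for r, (c, f) in enumerate(self.ranking(), start=1)
        ]
        return pd.DataFrame(rows)


def consensus_rank(
    m: ChemGenMatrix,
    signature_id: str,
    trials: Sequence[TrialSpec],
    policy: Optional[Policy] = None,
    scale_by_shared: bool = False,
) -> ConsensusRanking:
    """Run every trial, collect signature subclusters, rank by frequency.

    A trial whose distance matrix is degenerate (an uninformative pair) is
    skipped with a warning and excluded from the denominator: a failed trial
    carries no evidence either way.
    """
    if signature_id not in m.compound_ids:
        raise IdentifierError(f"signature {signature_id!r} not in matrix")
    if not trials:
        raise ParameterError("need at least one trial")
    if policy is None:
        policy = MinSize(default_min_size(len(m.compound_ids)))

    dist_cache: dict[str, DistanceMatrix] = {}
    counts = {c: 0 for c in m.compound_ids}
    per_trial: dict[TrialSpec, frozenset[str]] = {}
    skipped: list[TrialSpec] = []
    for trial in trials:
        if trial.measure not in dist_cache:
            dist_cache[trial.measure] = pairwise_distance(
                m, trial.measure, scale_by_shared
            )
        d = dist_cache[trial.measure]
        if d.is_degenerate():
            log.warning("trial %s skipped: degenerate distance matrix", trial)
            skipped.append(trial)
            continue
        tree = cluster(d, trial.linkage, profiles=m)
        members = signature_subcluster(tree, signature_id, policy)
        log.debug("trial %s subcluster size %d", trial, len(members))
        per_trial[trial] = frozenset(members)
        for c in members:
            counts[c] += 1

    trials_run = len(trials) - len(skipped)
    if trials_run == 0:
        raise ParameterError("every trial was degenerate; no ranking possible")
    frequency = {c: counts[c] / trials_run for c in m.compound_ids}
    return ConsensusRanking(
        signature_id=signature_id,
        trials_run=trials_run,
        frequency=frequency,
        per_trial_members=per_trial,
        policy=policy,
        skipped=skipped,
    )
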