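"""Iterative post-clustering merge of clusters sharing high-confidence seeds.

Greedy clustering can split one gene family over several clusters when
reads did not share enough seeds at the time they were visited (noise, or
exon/SNV information that only accumulated later).  The merge step repairs
this by sweeping over the clusters in ascending order of representation
size (number of HCS): a cluster ``c1`` merges into the cluster ``c2`` with
which it shares the most HCS, provided ``c2`` is larger and the shared
fraction relative to ``|hcs(c1)|`` strictly exceeds ``T3``.

All merge decisions within a sweep are taken against the state at the
start of the sweep.  If the chosen target ``c2`` itself merges away during
the sweep, ``c1``'s merge is postponed to the next sweep, where it can be
re-evaluated against the enlarged target.  Sweeps repeat until none merges.
Merging touches only representations and member-id lists — read sequences
are never reloaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .cluster import Cluster, SeedIndex

__all__ = ["MergeParams", "merge_pass", "merge_until_fixpoint"]


@dataclass(frozen=True)
class MergeParams:
    """``t3``: strict lower bound on |hcs(c1) ∩ hcs(c2)| / |hcs(c1)|."""

    t3: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.t3 <= 1.0:
            raise ValueError("t3 must lie in [0, 1]")


def _decide_merges(
    clusters: Dict[int, Cluster], index: SeedIndex, t3: float
) -> Dict[int, int]:
    """Target choice per cluster, all evaluated on the sweep-start state.

    Eligible targets have a strictly larger representation, or an equal-size
    representation with a smaller id (so identical twins can still merge).
    Ties on the overlap go to the smallest target id.
    """
    sizes = {cid: len(c.hcs) for cid, c in clusters.items()}
    decisions: Dict[int, int] = {}
    for cid in sorted(clusters, key=lambda c: (sizes[c], c)):
        size1 = sizes[cid]
        if size1 == 0:
            continue
        overlaps: Dict[int, int] = {}
        for v in clusters[cid].hcs:
            for other in index.get(v, ()):
                if other != cid:
                    overlaps[other] = overlaps.get(other, 0) + 1
        best_cid: Optional[int] = None
        best = 0
        for other, n in overlaps.items():
            if sizes[other] > size1 or (sizes[other] == size1 and other < cid):
                if n > best or (n == best and best_cid is not None and other < best_cid):
                    best, best_cid = n, other
        if best_cid is not None and best / size1 > t3:
            decisions[cid] = best_cid
    return decisions


def merge_pass(
    clusters: Dict[int, Cluster], index: SeedIndex, params: MergeParams
) -> int:
    """One full sweep; mutates ``clusters`` and ``index``; returns the
    number of merges performed.

    A decided merge ``c1 -> c2`` executes only if ``c2`` does not itself
    merge away this sweep (chain merges are deferred one sweep).  Decision
    edges strictly increase (size, -id), so this resolution is acyclic.
    """
    decisions = _decide_merges(clusters, index, params.t3)

    executes: Dict[int, bool] = {}

    def _executes(cid: int) -> bool:
        if cid not in decisions:
            return False
        if cid not in executes:
            executes[cid] = not _executes(decisions[cid])
        return executes[cid]

    merged = 0
    order = sorted(decisions, key=lambda c: (len(clusters[c].hcs), c))
    for cid in order:
        if not _executes(cid):
            continue
        target = clusters[decisions[cid]]
        source = clusters[cid]
        target.members.extend(source.members)
        new_vals = source.hcs - target.hcs
        target.hcs |= source.hcs
        for v in source.hcs:
            lst = index[v]
            lst.remove(cid)
        for v in new_vals:
            lst = index.setdefault(v, [])
            if target.cluster_id not in lst:
                lst.append(target.cluster_id)
        del clusters[cid]
        merged += 1
    return merged


def merge_until_fixpoint(
    clusters: Dict[int, Cluster], index: SeedIndex, params: MergeParams
) -> Tuple[Dict[int, Cluster], int]:
    """Sweep until a sweep merges nothing; returns (clusters, sweeps).

    ``sweeps`` counts all sweeps including the terminating empty one.
    The cluster count strictly decreases on every productive sweep, so at
    most ``len(clusters)`` sweeps can occur.
    """
    limit = len(clusters) + 1
    sweeps = 0
    while True:
        sweeps += 1
        if merge_pass(clusters, index, params) == 0:
            return clusters, sweeps
        if sweeps > limit:  # pragma: no cover - termination guard
            raise RuntimeError("merge did not reach a fixpoint")
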