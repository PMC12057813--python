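"""Single-pass greedy clustering with dynamically growing representations.

The sorted reads are streamed once.  The first read founds a cluster and
its high-confidence seeds (HCS) become the cluster *representation*.  Every
later read is compared, through an inverted seed index, against all
clusters sharing at least one seed with it: if the best cluster contains at
least a fraction ``T2`` of the read's distinct seed values, the read joins
it and any of the read's HCS not yet in the representation are added —
this on-the-fly growth is what lets a cluster absorb isoforms whose exon
structure only chain-overlaps the founder.  Otherwise the read founds a new
cluster.

A *static* ablation mode (representations frozen at the founder's HCS) is
provided for comparison; it reproduces the behaviour of older founder-read
clustering schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

from .sortreads import PreparedRead

__all__ = [
    "Cluster",
    "ClusterParams",
    "SeedIndex",
    "shared_seed_counts",
    "assign_read",
    "greedy_cluster",
]

# seed value -> cluster ids whose representation contains it (no duplicates)
SeedIndex = Dict[int, List[int]]


@dataclass
class Cluster:
    """A cluster: id in creation order, member read ids, HCS representation."""

    cluster_id: int
    members: List[str]
    hcs: Set[int]
    zero_seed: bool = False


@dataclass(frozen=True)
class ClusterParams:
    """``t2``: minimum shared fraction of a read's distinct seed values
    (inclusive ``>=``) required to join the best-matching cluster."""

    t2: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.t2 <= 1.0:
            raise ValueError("t2 must lie in [0, 1]")


def shared_seed_counts(read_values: Set[int], index: SeedIndex) -> Dict[int, int]:
    """Per-cluster count of the read's distinct seed values present in the
    cluster representation; clusters sharing nothing are absent."""
    counts: Dict[int, int] = {}
    for v in read_values:
        for cid in index.get(v, ()):
            counts[cid] = counts.get(cid, 0) + 1
    return counts


def _index_add(index: SeedIndex, value: int, cid: int) -> None:
    lst = index.setdefault(value, [])
    if not lst or lst[-1] != cid:  # a cid is only ever appended once per value
        lst.append(cid)


def assign_read(
    prepared: PreparedRead,
    clusters: List[Cluster],
    index: SeedIndex,
    params: ClusterParams,
    dynamic: bool = True,
) -> int:
    """Assign one read, mutating ``clusters`` and ``index``; returns the
    cluster id.

    The denominator of the join fraction is the number of *distinct* seed
    values of the read — all seeds, not only HCS.  Ties on the best shared
    count go to the smallest (oldest) cluster id.  A read with no seeds
    founds its own cluster, flagged ``zero_seed``.
    """
    values = {s.value for s in prepared.seeds}
    d = len(values)
    if d > 0:
        counts = shared_seed_counts(values, index)
        if counts:
            best = max(counts.values())
            best_cid = min(c for c, n in counts.items() if n == best)
            if best / d >= params.t2:
                cluster = clusters[best_cid]
                cluster.members.append(prepared.read.read_id)
                if dynamic:
                    for v in prepared.hcs - cluster.hcs:
                        cluster.hcs.add(v)
                        _index_add(index, v, best_cid)
                return best_cid
    cid = len(clusters)
    rep = set(prepared.hcs)
    clusters.append(
        Cluster(cluster_id=cid, members=[prepared.read.read_id], hcs=rep, zero_seed=d == 0)
    )
    for v in rep:
        _index_add(index, v, cid)
    return cid


def greedy_cluster(
    stream: Iterable[PreparedRead],
    params: ClusterParams,
    dynamic: bool = True,
) -> Tuple[List[Cluster], Dict[str, int], SeedIndex]:
    """Cluster a sorted read stream in one greedy pass.

    Returns the clusters (numbered in creation order), the read-id ->
    cluster-id assignment, and the seed index (reusable by the merge step).
    """
    clusters: List[Cluster] = []
    index: SeedIndex = {}
    assignment: Dict[str, int] = {}
    for prepared in stream:
        assignment[prepared.read.read_id] = assign_read(
            prepared, clusters, index, params, dynamic=dynamic
        )
    return clusters, assignment, index
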