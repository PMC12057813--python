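"""Ordering reads by informativeness before clustering.

Reads are sorted in decreasing order of their number of high-confidence
seeds (HCS), so the greedy clustering pass sees the most informative reads
first: early cluster founders then carry rich representations.  The sort is
stable — reads with equal HCS counts keep their input order — which makes
the whole pipeline deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

from .seeds import Read, Seed, SeedParams, hcs_of, minimizer_seeds

__all__ = ["PreparedRead", "prepare_read", "sort_reads", "write_sorted_fastq"]


@dataclass(frozen=True)
class PreparedRead:
    """A read together with its seeds, HCS values and HCS count.

    ``hcs_count`` counts seed *positions* classified high-confidence (one
    per emitted seed), not distinct values; ``hcs`` is the distinct-value
    set used as representation material downstream.
    """

    read: Read
    seeds: Sequence[Seed]
    hcs: Set[int]
    hcs_count: int


def prepare_read(read: Read, params: SeedParams) -> PreparedRead:
    seeds = minimizer_seeds(read, params)
    return PreparedRead(
        read=read,
        seeds=seeds,
        hcs=hcs_of(seeds, params.t1),
        hcs_count=sum(1 for s in seeds if s.confidence > params.t1),
    )


def sort_reads(
    reads: Iterable[Read],
    params: SeedParams,
    spill_path: Optional[str] = None,
) -> List[PreparedRead]:
    """Seed every read and return them sorted by decreasing HCS count.

    The sort is stable (ties keep input order).  When ``spill_path`` is
    given, the sorted reads are also written out as FASTQ so the clustering
    pass can be re-streamed from disk.
    """
    prepared = [prepare_read(r, params) for r in reads]
    prepared.sort(key=lambda pr: -pr.hcs_count)  # list.sort is stable
    if spill_path is not None:
        write_sorted_fastq(spill_path, prepared)
    return prepared


def write_sorted_fastq(path: str, prepared: Sequence[PreparedRead]) -> None:
    with open(path, "w") as fh:
        for pr in prepared:
            r = pr.read
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
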