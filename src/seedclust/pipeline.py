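"""End-to-end pipeline: seed, sort, cluster, optionally merge, write.

Technology presets bundle the seeding and threshold parameters:

========  ====  ====  =====  ====  ====
preset     k     w     T1     T2    T3
========  ====  ====  =====  ====  ====
ont        13    21   0.95   0.5   0.5
pacbio     15    51   0.98   0.5   0.8
========  ====  ====  =====  ====  ====

ONT's lower T1 reflects its lower base qualities; PacBio's higher T3
guards against over-merging driven by artificial concatamer reads.  The
pipeline is single-threaded and deterministic: the same input and
configuration always produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .cluster import Cluster, ClusterParams, greedy_cluster
from .fastq import read_fastq, write_outputs
from .merge import MergeParams, merge_until_fixpoint
from .seeds import Read, SeedParams
from .sortreads import sort_reads

__all__ = ["RunConfig", "RunResult", "PRESETS", "make_config", "run"]

logger = logging.getLogger(__name__)

PRESETS: Dict[str, Dict[str, float]] = {
    "ont": {"k": 13, "w": 21, "t1": 0.95, "t2": 0.5, "t3": 0.5},
    "pacbio": {"k": 15, "w": 51, "t1": 0.98, "t2": 0.5, "t3": 0.8},
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (see :data:`PRESETS` for defaults)."""

    mode: str = "ont"
    k: int = 13
    w: int = 21
    t1: float = 0.95
    t2: float = 0.5
    t3: float = 0.5
    canonical: bool = True
    post_cluster: bool = False
    min_cluster_output_size: int = 1
    outfolder: str = "seedclust_out"
    ordering: str = "hash"
    spill_sorted: bool = False
    dynamic_representation: bool = True

    def seed_params(self) -> SeedParams:
        return SeedParams(
            k=self.k, w=self.w, canonical=self.canonical,
            t1=self.t1, ordering=self.ordering,
        )


def make_config(mode: str = "ont", **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a technology preset plus overrides."""
    if mode in PRESETS:
        params = {**PRESETS[mode], **overrides}
    elif mode == "custom":
        params = overrides
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'ont', 'pacbio' or 'custom'")
    params["k"] = int(params.get("k", 13))
    params["w"] = int(params.get("w", 21))
    return RunConfig(mode=mode, **params)


@dataclass
class RunResult:
    n_reads: int
    n_skipped: int
    n_clusters_initial: int
    n_clusters_final: int
    merge_sweeps: int
    assignment: Dict[str, int]
    clusters: List[Cluster]
    tsv_path: Optional[str]
    stage_seconds: Dict[str, float] = field(default_factory=dict)


def run(
    config: RunConfig,
    fastq_path: Optional[str] = None,
    reads: Optional[Sequence[Read]] = None,
    write: bool = True,
) -> RunResult:
    """Execute the full pipeline on a FASTQ file or in-memory reads.

    Stages: sorting (seeding included), greedy clustering, optional
    iterative merging (``post_cluster``), output.  Per-stage wall times and
    counts are logged and returned.
    """
    if (fastq_path is None) == (reads is None):
        raise ValueError("provide exactly one of fastq_path or reads")
    times: Dict[str, float] = {}
    n_skipped = 0
    if fastq_path is not None:
        reader = read_fastq(fastq_path)
        reads = list(reader)
        n_skipped = reader.n_skipped

    t0 = time.perf_counter()
    spill = None
    if config.spill_sorted and write:
        import os

        os.makedirs(config.outfolder, exist_ok=True)
        spill = os.path.join(config.outfolder, "sorted_reads.fastq")
    stream = sort_reads(reads, config.seed_params(), spill_path=spill)
    times["sorting"] = time.perf_counter() - t0
    logger.info("sorted %d reads (%d skipped) in %.2fs", len(stream), n_skipped, times["sorting"])

    t0 = time.perf_counter()
    clusters, assignment, index = greedy_cluster(
        stream, ClusterParams(t2=config.t2), dynamic=config.dynamic_representation
    )
    times["clustering"] = time.perf_counter() - t0
    n_initial = len(clusters)
    logger.info("greedy pass: %d clusters in %.2fs", n_initial, times["clustering"])

    sweeps = 0
    live = {c.cluster_id: c for c in clusters}
    if config.post_cluster:
        t0 = time.perf_counter()
        live, sweeps = merge_until_fixpoint(live, index, MergeParams(t3=config.t3))
        times["merging"] = time.perf_counter() - t0
        for cid, c in live.items():
            assignment.update({m: cid for m in c.members})
        logger.info(
            "merging: %d -> %d clusters in %d sweeps, %.2fs",
            n_initial, len(live), sweeps, times["merging"],
        )

    final_clusters = [live[cid] for cid in sorted(live)]
    tsv_path = None
    if write:
        t0 = time.perf_counter()
        tsv_path = write_outputs(
            final_clusters, assignment, reads, config.outfolder,
            min_cluster_output_size=config.min_cluster_output_size,
        )
        times["output"] = time.perf_counter() - t0

    return RunResult(
        n_reads=len(stream),
        n_skipped=n_skipped,
        n_clusters_initial=n_initial,
        n_clusters_final=len(final_clusters),
        merge_sweeps=sweeps,
        assignment=assignment,
        clusters=final_clusters,
        tsv_path=tsv_path,
        stage_seconds=times,
    )
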