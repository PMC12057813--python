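"""Lenient streaming FASTQ input and cluster output files.

The reader accepts plain or gzip-compressed 4-line FASTQ with Phred+33
qualities.  Malformed records (missing lines, length mismatch between
sequence and quality, quality characters outside the Phred+33 range) are
skipped with a logged warning and counted, rather than aborting the run —
long-read files in the wild do contain the occasional truncated record.
"""

from __future__ import annotations

import gzip
import logging
import os
from typing import IO, Iterator, Sequence

from .cluster import Cluster
from .seeds import Read

__all__ = ["FastqReader", "read_fastq", "write_fastq", "write_outputs"]

logger = logging.getLogger(__name__)


def _open_text(path: str) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


class FastqReader:
    """Iterable over the valid records of a FASTQ file.

    After (or during) iteration, ``n_read`` and ``n_skipped`` report how
    many records were yielded and how many were dropped as malformed.
    """

    def __init__(self, path: str):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        self.path = path
        self.n_read = 0
        self.n_skipped = 0

    def __iter__(self) -> Iterator[Read]:
        with _open_text(self.path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                if not qual:
                    self.n_skipped += 1
                    logger.warning("truncated FASTQ record at end of %s", self.path)
                    return
                header, seq, qual = header.rstrip("\n"), seq.strip(), qual.rstrip("\n")
                if not header.startswith("@") or not plus.startswith("+"):
                    self.n_skipped += 1
                    logger.warning("malformed record %r in %s", header[:40], self.path)
                    continue
                if len(seq) != len(qual) or any(not (33 <= ord(c) <= 126) for c in qual):
                    self.n_skipped += 1
                    logger.warning("bad sequence/quality for %r in %s", header[:40], self.path)
                    continue
                self.n_read += 1
                yield Read(header[1:].split()[0], seq, qual)


def read_fastq(path: str) -> FastqReader:
    """Stream the valid reads of a (possibly gzipped) FASTQ file."""
    return FastqReader(path)


def write_fastq(path: str, reads: Sequence[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_outputs(
    clusters: Sequence[Cluster],
    assignment: dict,
    reads: Sequence[Read],
    outfolder: str,
    min_cluster_output_size: int = 1,
) -> str:
    """Write ``final_clusters.tsv`` plus one FASTQ per sufficiently large
    cluster; returns the TSV path.

    Cluster ids in the outputs are renumbered ``0..C-1`` by decreasing
    member count, ties resolved by creation order.  The TSV has one
    ``cluster_id <tab> read_id`` line per read; per-cluster FASTQ files are
    only written for clusters with at least ``min_cluster_output_size``
    members (downstream tools typically need a handful of reads).
    """
    os.makedirs(outfolder, exist_ok=True)
    order = sorted(clusters, key=lambda c: (-len(c.members), c.cluster_id))
    renumber = {c.cluster_id: new_id for new_id, c in enumerate(order)}
    tsv_path = os.path.join(outfolder, "final_clusters.tsv")
    with open(tsv_path, "w") as fh:
        for c in order:
            for read_id in c.members:
                fh.write(f"{renumber[c.cluster_id]}\t{read_id}\n")
    by_id = {r.read_id: r for r in reads}
    for c in order:
        if len(c.members) >= min_cluster_output_size:
            write_fastq(
                os.path.join(outfolder, f"cluster_{renumber[c.cluster_id]}.fastq"),
                [by_id[m] for m in c.members],
            )
    return tsv_path
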