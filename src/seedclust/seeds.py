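"""Quality-aware minimizer seeds.

A *(k, w)-minimizer* is the k-mer with the smallest value, under a
hash-induced total ordering, among the ``w`` k-mers starting in a window of
``w`` consecutive start positions; ties are broken by the leftmost
occurrence.  A *canonical* minimizer additionally considers the reverse
complement of every candidate k-mer, so the chosen seed value is
strand-independent.

Each seed carries a *confidence*: the probability, estimated from the
Phred base-call qualities, that all ``k`` bases of the k-mer were called
correctly, ``P = prod_j (1 - 10^(-q_j/10))``.  Seeds whose confidence
exceeds a threshold ``T1`` are *high-confidence seeds* (HCS) — the only
seeds allowed into cluster representations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Set

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Read",
    "Seed",
    "SeedParams",
    "phred_to_prob",
    "seed_confidence",
    "kmer_hash",
    "reverse_complement",
    "minimizers",
    "canonical_minimizers",
    "minimizer_seeds",
    "hcs_of",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; anything not ACGT maps to -1 (invalid)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class Read:
    """A sequencing read: identifier, nucleotide string, Phred+33 qualities."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )


@dataclass(frozen=True)
class Seed:
    """A minimizer seed: 64-bit value, 0-based start position, confidence."""

    value: int
    position: int
    confidence: float


@dataclass(frozen=True)
class SeedParams:
    """Seeding parameters.

    Parameters
    ----------
    k : int
        k-mer length.
    w : int
        Window size, counted in k-mer start positions.  Both even and odd
        values are accepted.
    canonical : bool
        Use canonical (strand-independent) minimizers.
    t1 : float
        High-confidence threshold on the seed confidence (strict ``>``).
    ordering : str
        ``"hash"`` (default; avalanche-mixed 64-bit hash) or
        ``"lexicographic"`` (plain 2-bit encoding, A<C<G<T), the latter
        intended for tests and worked examples where the chosen k-mer
        should be predictable by eye.
    """

    k: int = 13
    w: int = 21
    canonical: bool = True
    t1: float = 0.95
    ordering: str = "hash"

    def __post_init__(self) -> None:
        if self.k < 1 or self.w < 1:
            raise ValueError("k and w must be >= 1")
        if self.ordering not in ("hash", "lexicographic"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


def phred_to_prob(q: float) -> float:
    """Probability that a base with Phred score ``q`` was called correctly.

    ``p = 1 - 10^(-q/10)``; q must lie in [0, 93] (the Phred+33 range).
    """
    if not 0 <= q <= 93:
        raise ValueError(f"Phred score {q} outside [0, 93]")
    return 1.0 - 10.0 ** (-q / 10.0)


def seed_confidence(quality: str) -> float:
    """Probability that every base under a k-mer was correctly called.

    ``quality`` is the Phred+33 substring covering the k-mer.
    """
    p = 1.0
    for ch in quality:
        p *= phred_to_prob(ord(ch) - 33)
    return p


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer: bijective on 64-bit ints, good avalanche.
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def kmer_hash(kmer: str, ordering: str = "hash") -> int:
    """Order-inducing 64-bit value of a k-mer.

    ``ordering="hash"`` applies a splitmix64 mix to the 2-bit encoding;
    ``ordering="lexicographic"`` returns the 2-bit encoding itself, whose
    integer order equals lexicographic order with A<C<G<T.
    """
    codes = _CODE[np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError(f"k-mer {kmer!r} contains a non-ACGT base")
    val = np.uint64(0)
    enc = np.zeros(1, dtype=np.uint64)
    for c in codes:
        enc = (enc << np.uint64(2)) | np.uint64(c)
    if ordering == "lexicographic":
        return int(enc[0])
    return int(_splitmix64(enc)[0])


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-encoded k-mer integers at every start position, plus validity."""
    npos = len(codes) - k + 1
    vals = np.zeros(npos, dtype=np.uint64)
    safe = np.where(codes >= 0, codes, 0).astype(np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | safe[j : j + npos]
    bad = (codes < 0).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return vals, valid


def _confidences(quality: str, k: int) -> np.ndarray:
    q = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.float64) - 33.0
    p = 1.0 - 10.0 ** (-q / 10.0)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    # window sums of log-probabilities; -inf (q=0) propagates to conf 0
    return np.exp(sliding_window_view(logp, k).sum(axis=1))


def _select_windows(vals: np.ndarray, w: int) -> np.ndarray:
    """Positions of per-window minima (leftmost on ties), deduplicated.

    A window is ``w`` consecutive k-mer start positions; reads with fewer
    than ``w`` positions are treated as a single window over all of them.
    Windows containing no valid k-mer (all sentinel) select nothing.
    """
    npos = len(vals)
    w_eff = min(w, npos)
    win = sliding_window_view(vals, w_eff)
    arg = win.argmin(axis=1)  # argmin -> first (leftmost) occurrence
    pos = arg + np.arange(win.shape[0])
    keep = vals[pos] != _SENTINEL
    # same position can only be re-selected by consecutive windows
    return np.unique(pos[keep])


def _ordered_values(vals: np.ndarray, valid: np.ndarray, ordering: str) -> np.ndarray:
    out = _splitmix64(vals) if ordering == "hash" else vals.copy()
    out[~valid] = _SENTINEL
    return out


def _build_seeds(read: Read, positions: np.ndarray, values: np.ndarray, k: int) -> List[Seed]:
    conf = _confidences(read.quality, k)
    return [
        Seed(value=int(values[p]), position=int(p), confidence=float(conf[p]))
        for p in positions
    ]


def minimizers(read: Read, params: SeedParams) -> List[Seed]:
    """Forward-strand (k, w)-minimizers of a read, sorted by position.

    Reads shorter than ``k`` yield an empty list.  k-mers containing
    non-ACGT characters are excluded from candidacy; a window with no
    valid k-mer emits no seed.
    """
    k = params.k
    if len(read.sequence) < k:
        return []
    codes = _CODE[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
    vals, valid = _kmer_values(codes, k)
    ordered = _ordered_values(vals, valid, params.ordering)
    positions = _select_windows(ordered, params.w)
    return _build_seeds(read, positions, ordered, k)


def canonical_minimizers(read: Read, params: SeedParams) -> List[Seed]:
    """Canonical (strand-independent) (k, w)-minimizers of a read.

    Every window candidate is the canonical value of a k-mer: the smaller,
    under the chosen ordering, of the k-mer and its reverse complement.
    Confidence always comes from the forward-read quality substring, since
    qualities belong to the bases as sequenced.
    """
    k = params.k
    if len(read.sequence) < k:
        return []
    codes = _CODE[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
    vals, valid = _kmer_values(codes, k)
    # k-mer values of the reverse-complement read, mirrored back onto
    # forward coordinates: rc of the k-mer at p sits at npos-1-p there
    rc_codes = np.where(codes >= 0, 3 - codes, -1)[::-1]
    rc_vals, _ = _kmer_values(rc_codes, k)
    rc_on_fwd = rc_vals[::-1]
    fwd = _ordered_values(vals, valid, params.ordering)
    rev = _ordered_values(rc_on_fwd, valid, params.ordering)
    canonical = np.minimum(fwd, rev)
    positions = _select_windows(canonical, params.w)
    return _build_seeds(read, positions, canonical, k)


def minimizer_seeds(read: Read, params: SeedParams) -> List[Seed]:
    """Dispatch to canonical or forward-strand minimizers per ``params``."""
    if params.canonical:
        return canonical_minimizers(read, params)
    return minimizers(read, params)


def hcs_of(seeds: Iterable[Seed], t1: float) -> Set[int]:
    """Distinct values of seeds whose confidence strictly exceeds ``t1``."""
    return {s.value for s in seeds if s.confidence > t1}
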