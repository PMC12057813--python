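"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written straight from the definitions —
per-window scans, pair enumeration, direct entropy sums, straight-line
replays of the greedy rules — and shares no code path with the vectorised
implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Iterator, List, Sequence, Set, Tuple

from seedclust import kmer_hash, reverse_complement, seed_confidence

# ---------------------------------------------------------------- seeds


def naive_minimizers(
    sequence: str,
    quality: str,
    k: int,
    w: int,
    canonical: bool,
    ordering: str = "hash",
) -> List[Tuple[int, int, float]]:
    """Per-window min scan: returns sorted (position, value, confidence)."""
    npos = len(sequence) - k + 1
    if npos < 1:
        return []
    values: List[int] = []
    valid: List[bool] = []
    for p in range(npos):
        kmer = sequence[p : p + k].upper()
        if any(c not in "ACGT" for c in kmer):
            values.append(-1)
            valid.append(False)
            continue
        v = kmer_hash(kmer, ordering)
        if canonical:
            v = min(v, kmer_hash(reverse_complement(kmer), ordering))
        values.append(v)
        valid.append(True)
    w_eff = min(w, npos)
    chosen: Dict[int, int] = {}
    for start in range(npos - w_eff + 1):
        best_pos = None
        for p in range(start, start + w_eff):
            if not valid[p]:
                continue
            if best_pos is None or values[p] < values[best_pos]:
                best_pos = p  # strict < keeps the leftmost on ties
        if best_pos is not None:
            chosen[best_pos] = values[best_pos]
    return sorted(
        (p, v, seed_confidence(quality[p : p + k])) for p, v in chosen.items()
    )


# ---------------------------------------------------------------- metrics


def set_partitions(n: int) -> Iterator[List[int]]:
    """All set partitions of n elements as restricted-growth label lists."""

    def rec(prefix: List[int], n_used: int) -> Iterator[List[int]]:
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(n_used + 1):
            prefix.append(lab)
            yield from rec(prefix, max(n_used, lab + 1))
            prefix.pop()

    yield from rec([], 0)


def pair_confusion(x: Sequence, y: Sequence) -> Tuple[int, int, int, int]:
    """(TP, FP, FN, TN) by enumerating every unordered pair."""
    tp = fp = fn = tn = 0
    for i, j in combinations(range(len(x)), 2):
        same_x = x[i] == x[j]
        same_y = y[i] == y[j]
        if same_x and same_y:
            tp += 1
        elif same_x:
            fp += 1
        elif same_y:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def pair_rand_index(x: Sequence, y: Sequence) -> float:
    tp, fp, fn, tn = pair_confusion(x, y)
    return (tp + tn) / (tp + fp + fn + tn)


def pair_adjusted_rand_index(x: Sequence, y: Sequence) -> float:
    """Chance-corrected pair agreement from raw pair counts."""
    tp, fp, fn, tn = pair_confusion(x, y)
    total = tp + fp + fn + tn
    same_x = tp + fp
    same_y = tp + fn
    expected = same_x * same_y / total
    maximum = 0.5 * (same_x + same_y)
    if maximum == expected:
        return 1.0 if (fp == 0 and fn == 0) else 0.0
    return (tp - expected) / (maximum - expected)


def _entropy(labels: Sequence) -> float:
    n = len(labels)
    counts: Dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def _conditional_entropy(target: Sequence, given: Sequence) -> float:
    n = len(target)
    groups: Dict = {}
    for t, g in zip(target, given):
        groups.setdefault(g, []).append(t)
    return sum((len(sub) / n) * _entropy(sub) for sub in groups.values())


def entropy_homogeneity(x: Sequence, y: Sequence) -> float:
    hy = _entropy(y)
    if hy == 0.0:
        return 1.0
    return 1.0 - _conditional_entropy(y, x) / hy


def entropy_completeness(x: Sequence, y: Sequence) -> float:
    return entropy_homogeneity(y, x)


def entropy_v_measure(x: Sequence, y: Sequence) -> float:
    h = entropy_homogeneity(x, y)
    c = entropy_completeness(x, y)
    return 0.0 if h + c == 0 else 2 * h * c / (h + c)


# ---------------------------------------------------------------- clustering


def replay_greedy(
    reads: Sequence[Tuple[str, Set[int], Set[int]]],
    t2: float,
    dynamic: bool = True,
) -> Dict[str, int]:
    """Straight-line replay of the greedy rule without the seed index.

    ``reads``: (read_id, all distinct seed values, HCS values) in the
    already-sorted order.  Returns read id -> cluster id.
    """
    reps: List[Set[int]] = []
    assignment: Dict[str, int] = {}
    for read_id, values, hcs in reads:
        best_cid, best_count = None, 0
        for cid, rep in enumerate(reps):
            shared = len(values & rep)
            if shared > best_count:
                best_cid, best_count = cid, shared
        if values and best_cid is not None and best_count / len(values) >= t2:
            assignment[read_id] = best_cid
            if dynamic:
                reps[best_cid] |= hcs
        else:
            assignment[read_id] = len(reps)
            reps.append(set(hcs))
    return assignment


def replay_merge(
    reps: Dict[int, Set[int]], t3: float
) -> Tuple[Dict[int, Set[int]], Dict[int, int], List[int]]:
    """Straight-line replay of the iterative merge (all-pairs, no index).

    Returns (final representations, source -> final container id,
    merges-per-sweep including the terminating zero).
    """
    reps = {cid: set(s) for cid, s in reps.items()}
    container = {cid: cid for cid in reps}
    history: List[int] = []
    while True:
        sizes = {cid: len(s) for cid, s in reps.items()}
        decisions: Dict[int, int] = {}
        for cid in sorted(reps, key=lambda c: (sizes[c], c)):
            if sizes[cid] == 0:
                continue
            best_cid, best = None, 0
            for other in sorted(reps):
                if other == cid:
                    continue
                if not (
                    sizes[other] > sizes[cid]
                    or (sizes[other] == sizes[cid] and other < cid)
                ):
                    continue
                shared = len(reps[cid] & reps[other])
                if shared > best:
                    best_cid, best = other, shared
            if best_cid is not None and best / sizes[cid] > t3:
                decisions[cid] = best_cid
        def chain_edges(c: int) -> int:
            n = 0
            while c in decisions:
                c = decisions[c]
                n += 1
            return n

        merged = 0
        for cid in sorted(decisions, key=lambda c: (sizes[c], c)):
            # a decided merge executes iff its target does not itself
            # merge this sweep; along a decision chain that alternates,
            # so cid executes iff its remaining chain has odd length
            if chain_edges(cid) % 2 == 0:
                continue
            target = decisions[cid]
            reps[target] |= reps[cid]
            for src, cont in container.items():
                if cont == cid:
                    container[src] = target
            del reps[cid]
            merged += 1
        history.append(merged)
        if merged == 0:
            return reps, container, history
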