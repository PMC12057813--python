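"""Synthetic long-read transcriptome generator with ground-truth labels.

The generator emulates the data characteristics the clustering algorithm
targets, at desk scale:

* *gene families* are independent random sequences built from exons, so
  different families share essentially no k-mers;
* each family expresses several *isoforms* — ordered exon subsets that all
  contain a common anchor exon, so isoforms of a family overlap;
* *reads* are isoform copies with optional 5'/3' truncation, random strand
  orientation, and substitution/insertion/deletion errors;
* *qualities* follow a two-regime segment model — long clean stretches at
  a high mean Phred interleaved with shorter noisy segments at a low mean,
  as in real long-read data where most of the error mass sits in a
  minority of bases — and errors are then injected base-by-base with
  probability ``1 - p_i`` implied by the drawn quality, so the quality
  strings are statistically consistent with the injected error rate and
  quality-gated seed selection behaves as it does on real data.

The noisy-regime mean Phred is calibrated numerically so that the overall
expected error rate ``E[10^(-Q/10)]`` over the (rounded, clamped) quality
distribution equals the configured ``error_rate``.  Everything is driven
by one ``numpy`` generator seed, making the output byte-identical across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .seeds import Read, reverse_complement

__all__ = ["SimConfig", "GroundTruth", "simulate", "chain_family_reads",
           "write_fastq", "write_ground_truth"]

_BASES = np.array(list("ACGT"))

_Q_MIN, _Q_MAX = 2, 50  # clamp range of emitted Phred scores
_HIGH_Q = 60            # constant quality used when error_rate == 0


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Ranges are inclusive ``(low, high)`` pairs sampled uniformly.
    ``error_rate`` is the expected per-base error probability; it is split
    into substitution/insertion/deletion according to ``error_split``.

    Qualities come from a two-regime segment model: clean segments (mean
    Phred ``quality_good_q``, mean length ``segment_good_len`` bases)
    alternate with noisy segments (mean length ``segment_bad_len``) whose
    mean Phred is solved so the overall expected error probability equals
    ``error_rate``; per-base scores scatter around the regime mean with
    standard deviation ``quality_sd``.
    """

    n_families: int = 10
    exons_per_family: Tuple[int, int] = (4, 8)
    exon_length: Tuple[int, int] = (100, 300)
    isoforms_per_family: Tuple[int, int] = (2, 4)
    reads_per_family: Tuple[int, int] = (50, 50)
    error_rate: float = 0.05
    error_split: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    truncation_prob: float = 0.2
    truncation_max_frac: float = 0.3
    reverse_strand_prob: float = 0.5
    quality_good_q: float = 30.0
    quality_sd: float = 3.0
    segment_good_len: int = 200
    segment_bad_len: int = 50
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.truncation_prob, self.reverse_strand_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.error_split) - 1.0) > 1e-9:
            raise ValueError("error_split must sum to 1")
        if self.exon_length[0] < 1 or self.exons_per_family[0] < 1:
            raise ValueError("lengths and counts must be positive")


@dataclass
class GroundTruth:
    """Per-read truth: family label plus provenance details."""

    family: Dict[str, int] = field(default_factory=dict)
    isoform: Dict[str, int] = field(default_factory=dict)
    strand: Dict[str, str] = field(default_factory=dict)
    n_errors: Dict[str, int] = field(default_factory=dict)
    n_template_bases: Dict[str, int] = field(default_factory=dict)


def _regime_error(mean_q: float, sd: float) -> float:
    """Expected error probability of a rounded, clamped N(mean_q, sd) Phred."""
    from scipy.stats import norm

    qs = np.arange(_Q_MIN, _Q_MAX + 1, dtype=float)
    edges = np.concatenate(([-np.inf], qs[:-1] + 0.5, [np.inf]))
    probs = np.diff(norm.cdf(edges, loc=mean_q, scale=sd))
    return float((probs * 10.0 ** (-qs / 10.0)).sum())


def _calibrate_regimes(config: "SimConfig") -> Tuple[float, float]:
    """Clean/noisy regime mean Phreds whose mixture hits ``error_rate``.

    The clean mean stays at ``quality_good_q`` and the noisy mean is
    solved by root finding; for error rates outside the range that the
    noisy regime alone can absorb, a common mean for both regimes is
    solved instead.
    """
    from scipy.optimize import brentq

    f_good = config.segment_good_len / (config.segment_good_len + config.segment_bad_len)
    sd, mg, target = config.quality_sd, config.quality_good_q, config.error_rate

    def mix(mb: float, mg_: float) -> float:
        return f_good * _regime_error(mg_, sd) + (1 - f_good) * _regime_error(mb, sd)

    lo, hi = -60.0, 200.0
    if mix(hi, mg) > target:  # even an error-free noisy regime is too noisy
        m = brentq(lambda x: mix(x, x) - target, mg, 300.0, xtol=1e-6)
        return float(m), float(m)
    if mix(lo, mg) < target:  # clean regime must be degraded as well
        m = brentq(lambda x: mix(x, x) - target, lo, mg, xtol=1e-6)
        return float(m), float(m)
    mb = brentq(lambda x: mix(x, mg) - target, lo, hi, xtol=1e-6)
    return float(mg), float(mb)


def _quality_scores(
    n: int, m_good: float, m_bad: float, config: "SimConfig", rng: np.random.Generator
) -> np.ndarray:
    """Integer Phred scores from the two-regime segment model."""
    good = rng.random() < config.segment_good_len / (
        config.segment_good_len + config.segment_bad_len
    )
    means = np.empty(n)
    pos = 0
    while pos < n:
        mean_len = config.segment_good_len if good else config.segment_bad_len
        seg = int(rng.geometric(1.0 / mean_len))
        means[pos : pos + seg] = m_good if good else m_bad
        pos += seg
        good = not good
    q = np.rint(means + config.quality_sd * rng.standard_normal(n))
    return np.clip(q, _Q_MIN, _Q_MAX).astype(np.int64)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_isoforms(
    n_exons: int, n_isoforms: int, rng: np.random.Generator
) -> List[Tuple[int, ...]]:
    """Ordered exon subsets, all containing a shared anchor exon."""
    anchor = int(rng.integers(0, n_exons))
    max_distinct = 2 ** (n_exons - 1)
    if n_isoforms > max_distinct:
        raise ValueError(
            f"cannot draw {n_isoforms} distinct isoforms from {n_exons} exons"
        )
    isoforms: List[Tuple[int, ...]] = []
    seen = set()
    while len(isoforms) < n_isoforms:
        keep = tuple(
            e for e in range(n_exons)
            if e == anchor or rng.random() < 0.7
        )
        if keep not in seen:
            seen.add(keep)
            isoforms.append(keep)
    return isoforms


def _inject_errors(
    template: str,
    qs: np.ndarray,
    split: Tuple[float, float, float],
    rng: np.random.Generator,
) -> Tuple[str, str, int]:
    """Per-base error injection with probability ``1 - p_i`` implied by the
    drawn quality; returns (sequence, quality string, error count)."""
    p_err = 10.0 ** (-qs / 10.0)
    hits = rng.random(len(template)) < p_err
    seq_parts: List[str] = []
    q_parts: List[int] = []
    n_err = 0
    sub_p, ins_p, _ = split
    for i, base in enumerate(template):
        q = int(qs[i])
        if not hits[i]:
            seq_parts.append(base)
            q_parts.append(q)
            continue
        n_err += 1
        u = rng.random()
        if u < sub_p:  # substitution: wrong base, same quality
            choices = [b for b in "ACGT" if b != base]
            seq_parts.append(choices[int(rng.integers(0, 3))])
            q_parts.append(q)
        elif u < sub_p + ins_p:  # insertion after the (kept) base
            seq_parts.append(base)
            q_parts.append(q)
            seq_parts.append(str(_BASES[int(rng.integers(0, 4))]))
            q_parts.append(q)
        # deletion: emit nothing
    qual = "".join(chr(q + 33) for q in q_parts)
    return "".join(seq_parts), qual, n_err


def simulate(config: SimConfig) -> Tuple[List[Read], GroundTruth]:
    """Generate reads and ground truth; fully reproducible from the seed."""
    if config.isoforms_per_family[0] > 2 ** (config.exons_per_family[0] - 1):
        raise ValueError(
            "infeasible config: more isoforms requested than distinct "
            "anchored exon subsets available in the smallest family"
        )
    rng = np.random.default_rng(config.seed)
    noisy = config.error_rate > 0.0
    m_good = m_bad = None
    if noisy:
        m_good, m_bad = _calibrate_regimes(config)

    reads: List[Read] = []
    truth = GroundTruth()
    for fam in range(config.n_families):
        n_exons = int(rng.integers(config.exons_per_family[0], config.exons_per_family[1] + 1))
        exons = [
            _random_seq(rng, int(rng.integers(config.exon_length[0], config.exon_length[1] + 1)))
            for _ in range(n_exons)
        ]
        n_iso = min(int(rng.integers(config.isoforms_per_family[0],
                                     config.isoforms_per_family[1] + 1)),
                    2 ** (n_exons - 1))
        isoforms = _make_isoforms(n_exons, n_iso, rng)
        n_reads = int(rng.integers(config.reads_per_family[0], config.reads_per_family[1] + 1))
        for ridx in range(n_reads):
            iso_id = int(rng.integers(0, len(isoforms)))
            template = "".join(exons[e] for e in isoforms[iso_id])
            # 5'/3' truncation of the transcript copy
            if rng.random() < config.truncation_prob and len(template) > 100:
                cut = int(rng.random() * config.truncation_max_frac * len(template))
                cut = min(cut, len(template) - 50)
                if rng.random() < 0.5:
                    template = template[cut:]
                else:
                    template = template[: len(template) - cut] if cut else template
            if noisy:
                qs = _quality_scores(len(template), m_good, m_bad, config, rng)
                seq, qual, n_err = _inject_errors(template, qs, config.error_split, rng)
            else:
                seq = template
                qual = chr(_HIGH_Q + 33) * len(seq)
                n_err = 0
            strand = "+"
            if rng.random() < config.reverse_strand_prob:
                seq = reverse_complement(seq)
                qual = qual[::-1]
                strand = "-"
            read_id = f"fam{fam}_iso{iso_id}_read{ridx}"
            reads.append(Read(read_id, seq, qual))
            truth.family[read_id] = fam
            truth.isoform[read_id] = iso_id
            truth.strand[read_id] = strand
            truth.n_errors[read_id] = n_err
            truth.n_template_bases[read_id] = len(template)
    return reads, truth


def chain_family_reads(
    n_exons: int = 5,
    exon_length: int = 300,
    copies: int = 1,
    seed: int = 0,
) -> Tuple[List[Read], GroundTruth]:
    """One gene family whose isoforms only chain-overlap.

    Isoform ``i`` spans exons ``(i, i+1, i+2)``, so consecutive isoforms
    share two of their three exons (about two thirds of their seeds) while
    isoforms two apart share only one (about a third).  All reads are
    error-free with uniformly high quality.  Exon lengths decrease along
    the chain, so isoform 0 carries the most seeds and is always visited
    first in HCS-sorted order.  This is the minimal structure on which
    dynamically updated cluster representations keep the family together
    while founder-frozen representations split it: the last isoform
    overlaps the founder too little, but overlaps the seeds the
    representation picked up from the middle isoform.
    """
    rng = np.random.default_rng(seed)
    exons = [
        _random_seq(rng, exon_length + 50 * (n_exons - 1 - i))
        for i in range(n_exons)
    ]
    reads: List[Read] = []
    truth = GroundTruth()
    for i in range(n_exons - 2):
        template = exons[i] + exons[i + 1] + exons[i + 2]
        for c in range(copies):
            read_id = f"chain_iso{i}_read{c}"
            reads.append(Read(read_id, template, chr(_HIGH_Q + 33) * len(template)))
            truth.family[read_id] = 0
            truth.isoform[read_id] = i
            truth.strand[read_id] = "+"
            truth.n_errors[read_id] = 0
            truth.n_template_bases[read_id] = len(template)
    return reads, truth


def write_fastq(path: str, reads: Sequence[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_ground_truth(path: str, truth: GroundTruth) -> None:
    """TSV ``read_id <tab> family_id``, directly consumable by the metrics."""
    with open(path, "w") as fh:
        for read_id, fam in truth.family.items():
            fh.write(f"{read_id}\t{fam}\n")
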