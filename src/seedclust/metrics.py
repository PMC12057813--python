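"""External clustering-quality metrics.

Given a predicted clustering ``X`` and ground-truth classes ``Y`` over the
same ``n`` reads, this module computes:

* homogeneity  ``h = 1 - H(Y|X) / H(Y)``  (penalises mixing classes),
* completeness ``c = 1 - H(X|Y) / H(X)``  (penalises splitting classes),
* V-measure, the harmonic mean of ``h`` and ``c``,
* the Rand index (fraction of read pairs on which the two partitions
  agree) and the Adjusted Rand Index, its chance-corrected form
  ``ARI = (sum_ij C(n_ij,2) - t3) / (0.5 (t1 + t2) - t3)`` with
  ``t1 = sum_i C(n_i.,2)``, ``t2 = sum_j C(n_.j,2)`` and
  ``t3 = 2 t1 t2 / (n (n-1))``,
* singleton / non-singleton summary counts.

Entropies use the natural logarithm; being ratios, the metrics are
base-independent.  Conventions for degenerate inputs: ``h = 1`` when
``H(Y) = 0``, ``c = 1`` when ``H(X) = 0``, and when the ARI denominator is
zero (e.g. both partitions all singletons) the ARI is 1 for identical
partitions and 0 otherwise.  Labels are opaque: only equality matters, so
every metric is invariant under relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import entropy as _entropy

__all__ = [
    "Labeling",
    "contingency_table",
    "homogeneity",
    "completeness",
    "v_measure",
    "rand_index",
    "adjusted_rand_index",
    "summarize",
    "evaluate",
    "load_labeling",
]


@dataclass(frozen=True)
class Labeling:
    """Paired label arrays: predicted cluster ids X, true class ids Y."""

    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_sequences(cls, x: Sequence, y: Sequence) -> "Labeling":
        xa, ya = np.asarray(list(x)), np.asarray(list(y))
        if len(xa) != len(ya):
            raise ValueError(f"label arrays differ in length: {len(xa)} vs {len(ya)}")
        if len(xa) == 0:
            raise ValueError("labeling must cover at least one read")
        return cls(xa, ya)


def _as_labeling(labeling, y=None) -> Labeling:
    if isinstance(labeling, Labeling):
        return labeling
    return Labeling.from_sequences(labeling, y)


def contingency_table(labeling: Labeling) -> np.ndarray:
    """Dense cluster-by-class count matrix ``n_ij``."""
    _, xi = np.unique(labeling.x, return_inverse=True)
    _, yi = np.unique(labeling.y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def _conditional_entropy(table: np.ndarray) -> float:
    """H(columns | rows) in nats."""
    n = table.sum()
    h = 0.0
    for row in table:
        m = row.sum()
        if m > 0:
            h += (m / n) * _entropy(row)
    return float(h)


def homogeneity(labeling, y=None) -> float:
    """``1 - H(Y|X)/H(Y)``; 1 when the classes carry no entropy."""
    lab = _as_labeling(labeling, y)
    table = contingency_table(lab)
    hy = float(_entropy(table.sum(axis=0)))
    if hy == 0.0:
        return 1.0
    return 1.0 - _conditional_entropy(table) / hy


def completeness(labeling, y=None) -> float:
    """``1 - H(X|Y)/H(X)``; 1 when the clustering carries no entropy."""
    lab = _as_labeling(labeling, y)
    return homogeneity(Labeling(lab.y, lab.x))


def v_measure(labeling, y=None) -> float:
    """Harmonic mean of homogeneity and completeness (0 when both are 0)."""
    lab = _as_labeling(labeling, y)
    h, c = homogeneity(lab), completeness(lab)
    if h + c == 0.0:
        return 0.0
    return 2.0 * h * c / (h + c)


def _pair_counts(table: np.ndarray) -> Tuple[float, float, float, float]:
    """(TP, FP, FN, TN) over all unordered read pairs."""
    n = table.sum()
    total = comb(n, 2)
    tp = comb(table, 2).sum()
    same_x = comb(table.sum(axis=1), 2).sum()
    same_y = comb(table.sum(axis=0), 2).sum()
    fp = same_x - tp
    fn = same_y - tp
    tn = total - tp - fp - fn
    return float(tp), float(fp), float(fn), float(tn)


def rand_index(labeling, y=None) -> float:
    """Fraction of read pairs on which clustering and classes agree."""
    lab = _as_labeling(labeling, y)
    if len(lab.x) < 2:
        raise ValueError("Rand index requires at least two reads")
    tp, fp, fn, tn = _pair_counts(contingency_table(lab))
    return (tp + tn) / (tp + fp + fn + tn)


def _partitions_identical(table: np.ndarray) -> bool:
    return bool(
        ((table > 0).sum(axis=0) <= 1).all() and ((table > 0).sum(axis=1) <= 1).all()
    )


def adjusted_rand_index(labeling, y=None) -> float:
    """Rand index corrected for chance; 1 for identical partitions,
    about 0 for random labelings, can be negative."""
    lab = _as_labeling(labeling, y)
    n = len(lab.x)
    if n < 2:
        raise ValueError("ARI requires at least two reads")
    table = contingency_table(lab)
    sum_ij = comb(table, 2).sum()
    t1 = comb(table.sum(axis=1), 2).sum()
    t2 = comb(table.sum(axis=0), 2).sum()
    t3 = 2.0 * t1 * t2 / (n * (n - 1))
    denom = 0.5 * (t1 + t2) - t3
    if denom == 0.0:
        return 1.0 if _partitions_identical(table) else 0.0
    return float((sum_ij - t3) / denom)


def summarize(labeling, y=None, min_size: int = 2) -> Dict[str, float]:
    """Singleton / non-singleton counts and percentage of reads in clusters
    of size >= ``min_size`` (default: non-trivial clusters, size > 1)."""
    lab = _as_labeling(labeling, y)
    _, x_sizes = np.unique(lab.x, return_counts=True)
    _, y_sizes = np.unique(lab.y, return_counts=True)
    n = len(lab.x)
    return {
        "n_reads": int(n),
        "n_clusters": int(len(x_sizes)),
        "n_classes": int(len(y_sizes)),
        "nonsingleton_clusters": int((x_sizes > 1).sum()),
        "singleton_clusters": int((x_sizes == 1).sum()),
        "nonsingleton_classes": int((y_sizes > 1).sum()),
        "singleton_classes": int((y_sizes == 1).sum()),
        "pct_reads_in_nontrivial_clusters": float(
            100.0 * x_sizes[x_sizes >= min_size].sum() / n
        ),
    }


def evaluate(labeling, y=None, min_size: int = 2) -> Dict[str, float]:
    """Flat report with h, c, V, RI, ARI and the summary counts."""
    lab = _as_labeling(labeling, y)
    report = {
        "homogeneity": homogeneity(lab),
        "completeness": completeness(lab),
        "v_measure": v_measure(lab),
        "rand_index": rand_index(lab),
        "adjusted_rand_index": adjusted_rand_index(lab),
    }
    report.update(summarize(lab, min_size=min_size))
    return report


def load_labeling(
    clusters_tsv: str,
    classes_tsv: str,
    unclassified: str = "singleton",
) -> Labeling:
    """Build a :class:`Labeling` from two headerless TSV files.

    ``clusters_tsv``: ``cluster_id <tab> read_id`` (the tool's output);
    ``classes_tsv``: ``read_id <tab> class_id`` (ground truth).  Reads
    missing from the class file are *unclassified*: under the default
    ``"singleton"`` policy each receives a unique class of its own, so all
    reads enter the metrics; under ``"exclude"`` they are dropped.  Reads
    present only in the class file likewise get unique singleton cluster
    ids (the clustering never saw them).
    """
    if unclassified not in ("singleton", "exclude"):
        raise ValueError(f"unknown unclassified policy {unclassified!r}")
    pred = pd.read_csv(
        clusters_tsv, sep="\t", header=None, names=["cluster_id", "read_id"],
        dtype={"cluster_id": str, "read_id": str},
    )
    truth = pd.read_csv(
        classes_tsv, sep="\t", header=None, names=["read_id", "class_id"],
        dtype={"read_id": str, "class_id": str},
    )
    merged = pred.merge(truth, on="read_id", how="outer", sort=False)
    missing_class = merged["class_id"].isna()
    if unclassified == "exclude":
        merged = merged[~missing_class].reset_index(drop=True)
        missing_class = merged["class_id"].isna()
    x = merged["cluster_id"].to_numpy(dtype=object)
    y = merged["class_id"].to_numpy(dtype=object)
    for i in np.flatnonzero(missing_class.to_numpy()):
        y[i] = f"__unclassified_{i}"
    for i in np.flatnonzero(merged["cluster_id"].isna().to_numpy()):
        x[i] = f"__unclustered_{i}"
    return Labeling.from_sequences(x, y)
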