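"""Clustering agreement metrics with a size-preserving random-partition null.

Implements the two normalized-mutual-information conventions used when
benchmarking topic models against a known sample annotation:

* the V-measure — harmonic mean of homogeneity ``h = 1 - H(C|K)/H(C)``
  and completeness ``C = 1 - H(K|C)/H(K)`` — for scoring a clustering
  against a reference partition, and
* the asymmetric ``NMI(X, Y) = I(X, Y) / H(X)`` for comparing two
  arbitrary partitions (gene-side or sample-side).

Because a random partition of the same shape does not score zero (there
is residual entropy, especially at high cluster counts), observed scores
are rescaled by the mean score of random partitions that preserve the
observed cluster-size multiset; the rescaled quantity is called NMI*.

All entropies use natural logarithms.  Every NMI-type quantity here is a
ratio of entropies, so the choice of base cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PartitionLabels",
    "NullDistribution",
    "NmiStarResult",
    "contingency_table",
    "homogeneity_completeness",
    "v_measure",
    "nmi_asymmetric",
    "random_partition_null",
    "nmi_star",
]


@dataclass
class PartitionLabels:
    """An assignment of items (samples or genes) to clusters.

    Cluster identifiers are arbitrary hashables; all metrics below are
    invariant under relabeling.
    """

    item_ids: np.ndarray
    labels: np.ndarray

    def __init__(self, item_ids: Sequence, labels: Sequence):
        self.item_ids = np.asarray(item_ids)
        self.labels = np.asarray(labels)
        if self.item_ids.shape != self.labels.shape or self.item_ids.ndim != 1:
            raise ValueError(
                "item_ids and labels must be 1-d sequences of equal length"
            )
        if len(self.item_ids) == 0:
            raise ValueError("empty partition")
        if len(set(self.item_ids.tolist())) != len(self.item_ids):
            raise ValueError("duplicate item ids in partition")

    def __len__(self) -> int:
        return len(self.item_ids)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def restrict(self, ids: Sequence) -> "PartitionLabels":
        """Subset to ``ids`` (order taken from ``ids``)."""
        index = {v: i for i, v in enumerate(self.item_ids.tolist())}
        try:
            pos = [index[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"item {e.args[0]!r} not in partition") from None
        return PartitionLabels(np.asarray(list(ids)), self.labels[pos])


@dataclass
class NullDistribution:
    """Replicate scores under size-preserving random partitions."""

    replicate_nmis: np.ndarray
    n_replicates: int
    seed: int
    preserved_sizes: tuple = field(default_factory=tuple)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_nmis))

    @property
    def std(self) -> float:
        return float(np.std(self.replicate_nmis))


@dataclass
class NmiStarResult:
    value: float
    per_replicate: np.ndarray


def _align(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    """Coerce two partitions to aligned label arrays over the same items."""
    if isinstance(truth, PartitionLabels) and isinstance(pred, PartitionLabels):
        a = set(truth.item_ids.tolist())
        b = set(pred.item_ids.tolist())
        if a != b:
            missing = sorted(map(str, a.symmetric_difference(b)))[:5]
            raise ValueError(
                f"partitions cover different item sets (e.g. {missing})"
            )
        order = truth.item_ids.tolist()
        return truth.labels, pred.restrict(order).labels
    x = truth.labels if isinstance(truth, PartitionLabels) else np.asarray(truth)
    y = pred.labels if isinstance(pred, PartitionLabels) else np.asarray(pred)
    if x.shape != y.shape:
        raise ValueError("label vectors differ in length")
    return x, y


def contingency_table(truth, pred) -> np.ndarray:
    """Cross-tabulation n_ck of reference classes (rows) vs clusters (cols)."""
    x, y = _align(truth, pred)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _conditional_entropy(table: np.ndarray, axis: int) -> float:
    # H(rows|cols) for axis=1: -sum n_ck/N log(n_ck / n_col)
    n = table.sum()
    marg = table.sum(axis=0 if axis == 1 else 1, keepdims=True)
    if axis == 0:
        marg = marg.reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(table > 0, table / marg, 1.0)
    return float(-(table[table > 0] / n * np.log(ratio[table > 0])).sum())


def homogeneity_completeness(truth, pred) -> tuple[float, float]:
    """Homogeneity h = 1 - H(C|K)/H(C) and completeness C = 1 - H(K|C)/H(K).

    ``truth`` holds the reference classes C, ``pred`` the clustering K.
    Degenerate references (a single class, entropy 0) score 1 by the
    0/0 -> 1 convention: a partition cannot split or mix what has no
    structure.
    """
    table = contingency_table(truth, pred)
    h_c = _entropy(table.sum(axis=1))
    h_k = _entropy(table.sum(axis=0))
    h_c_given_k = _conditional_entropy(table, axis=1)
    h_k_given_c = _conditional_entropy(table, axis=0)
    h = 1.0 if h_c == 0.0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0.0 else 1.0 - h_k_given_c / h_k
    return h, c


def v_measure(truth, pred) -> float:
    """Harmonic mean of homogeneity and completeness (0 when both vanish)."""
    h, c = homogeneity_completeness(truth, pred)
    if h + c == 0.0:
        return 0.0
    return 2.0 * h * c / (h + c)


def nmi_asymmetric(X, Y) -> float:
    """Mutual information of the two label sequences divided by H(X).

    Equals 1 when Y determines X (reading Y adds nothing once X is
    known, up to relabeling) and 0 for independent partitions.  When
    H(X) = 0 the ratio is taken as 1 if Y is also a single cluster and
    0 otherwise.
    """
    table = contingency_table(X, Y)
    h_x = _entropy(table.sum(axis=1))
    h_y = _entropy(table.sum(axis=0))
    if h_x == 0.0:
        return 1.0 if h_y == 0.0 else 0.0
    n = table.sum()
    px = table.sum(axis=1, keepdims=True) / n
    py = table.sum(axis=0, keepdims=True) / n
    pxy = table / n
    mask = pxy > 0
    mi = float((pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])).sum())
    return mi / h_x


def random_partition_null(
    truth,
    observed,
    n_replicates: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Score size-preserving random partitions against ``truth``.

    Each replicate permutes the observed item->cluster assignment
    uniformly at random, which preserves the cluster-size multiset
    exactly, then scores the V-measure against the reference.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    x, y = _align(truth, observed)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_replicates)
    for r in range(n_replicates):
        scores[r] = v_measure(x, rng.permutation(y))
    vals, counts = np.unique(y, return_counts=True)
    return NullDistribution(
        replicate_nmis=scores,
        n_replicates=n_replicates,
        seed=seed,
        preserved_sizes=tuple(sorted(counts.tolist())),
    )


def nmi_star(observed_nmi: float, null: NullDistribution) -> NmiStarResult:
    """Observed score divided by the null mean (the NMI* convention).

    Also returns the observed score divided by each individual
    replicate, the distribution induced by the intrinsic variability of
    the random-partition normalization.
    """
    if len(null.replicate_nmis) == 0:
        raise ValueError("empty null distribution")
    mean = null.mean
    if mean == 0.0:
        warnings.warn("null mean is 0; NMI* is infinite", RuntimeWarning)
        return NmiStarResult(np.inf, np.full(len(null.replicate_nmis), np.inf))
    with np.errstate(divide="ignore"):
        per_rep = observed_nmi / null.replicate_nmis
    return NmiStarResult(float(observed_nmi / mean), per_rep)
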