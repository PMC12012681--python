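"""Concordance of topic structures produced by different methods.

Two complementary comparisons: exact hypergeometric tests on the
overlap of topic gene lists (do two methods prioritize the same genes,
given the universe of genes both actually processed?), and pairwise
asymmetric NMI between gene-side or sample-side partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .partition_metrics import (
    NullDistribution,
    PartitionLabels,
    nmi_asymmetric,
    random_partition_null,
)

__all__ = ["OverlapTest", "hypergeometric_overlap", "cross_method_partition_nmi"]

_EXACT_N_MAX = 2000  # exact rational binomials below this population size


@dataclass
class OverlapTest:
    """Hypergeometric overlap of two gene lists within a shared universe."""

    N: int  # universe size: genes processed by both algorithms
    K: int  # first list size
    n: int  # second list size
    k: int  # observed intersection
    p_point: float  # P(exactly k) — the headline value
    p_tail: float  # P(>= k), the conventional enrichment tail

    def __post_init__(self):
        if self.k > min(self.K, self.n) or max(self.K, self.n) > self.N:
            raise ValueError("inconsistent overlap counts")
        for p in (self.p_point, self.p_tail):
            if not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError("probability out of range")


def _pmf_exact(N: int, K: int, n: int, k: int) -> Fraction:
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeometric_overlap(
    list_a: Sequence[str], list_b: Sequence[str], universe: Sequence[str]
) -> OverlapTest:
    """Probability that two gene lists overlap by chance.

    ``P(k) = C(K, k) C(N-K, n-k) / C(N, n)`` with N the universe size,
    K and n the list sizes, and k the observed intersection.  The
    universe must be the genes processed by both algorithms (methods
    may drop genes during their analyses, which shrinks N).  Exact
    integer arithmetic is used for moderate N, log-space survival
    functions beyond.
    """
    uni = set(universe)
    if len(uni) != len(list(universe)):
        raise ValueError("duplicate genes in universe")
    a, b = set(list_a), set(list_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValueError(f"genes outside the universe: {stray[:10]}")
    N, K, n, k = len(uni), len(a), len(b), len(a & b)
    if N <= _EXACT_N_MAX:
        p_point = float(_pmf_exact(N, K, n, k))
        p_tail = float(
            sum(_pmf_exact(N, K, n, j) for j in range(k, min(K, n) + 1))
        )
    else:
        p_point = float(hypergeom.pmf(k, N, K, n))
        p_tail = float(hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(N=N, K=K, n=n, k=k, p_point=p_point, p_tail=min(p_tail, 1.0))


def cross_method_partition_nmi(
    partitions: Sequence[PartitionLabels],
    names: Sequence[str] | None = None,
    null_replicates: int = 0,
    seed: int = 0,
) -> dict:
    """Pairwise asymmetric NMI between partitions from different methods.

    Each ordered pair (i, j) is scored as NMI(X_i, X_j) = I/H(X_i) on
    the intersection of their item sets (methods may cover different
    gene universes).  The symmetrized mean is also returned, and, when
    ``null_replicates > 0``, a size-preserving-shuffle normalization of
    each pair.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    names = list(names) if names is not None else [
        f"model_{i}" for i in range(len(partitions))
    ]
    m = len(partitions)
    directed = np.full((m, m), np.nan)
    normalized = np.full((m, m), np.nan) if null_replicates else None
    for i in range(m):
        for j in range(m):
            if i == j:
                directed[i, j] = 1.0
                if normalized is not None:
                    normalized[i, j] = np.nan
                continue
            shared = [
                x
                for x in partitions[i].item_ids.tolist()
                if x in set(partitions[j].item_ids.tolist())
            ]
            if not shared:
                raise ValueError(
                    f"no shared items between {names[i]} and {names[j]}"
                )
            xi = partitions[i].restrict(shared)
            xj = partitions[j].restrict(shared)
            directed[i, j] = nmi_asymmetric(xi, xj)
            if normalized is not None:
                null = _asymmetric_null(xi, xj, null_replicates, seed + i * m + j)
                normalized[i, j] = (
                    directed[i, j] / null.mean if null.mean > 0 else np.inf
                )
    out = {
        "directed": pd.DataFrame(directed, index=names, columns=names),
        "symmetric_mean": pd.DataFrame(
            (directed + directed.T) / 2.0, index=names, columns=names
        ),
    }
    if normalized is not None:
        out["normalized"] = pd.DataFrame(normalized, index=names, columns=names)
    return out


def _asymmetric_null(
    x: PartitionLabels, y: PartitionLabels, n_replicates: int, seed: int
) -> NullDistribution:
    rng = np.random.default_rng(seed)
    ylab = y.restrict(x.item_ids.tolist()).labels
    scores = np.array(
        [nmi_asymmetric(x.labels, rng.permutation(ylab)) for _ in range(n_replicates)]
    )
    vals, counts = np.unique(ylab, return_counts=True)
    return NullDistribution(scores, n_replicates, seed, tuple(sorted(counts.tolist())))
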