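"""Topic model fitting and ingestion for gene-by-sample count matrices.

The expression matrix is read as a bag of words: genes play the role of
words, samples the role of documents, and an expression value the
multiplicity of the corresponding gene-sample edge in a bipartite
network.  Two routes produce a :class:`TopicModelResult`:

* :func:`lda_gibbs_fit` — a self-contained collapsed Gibbs sampler for
  latent Dirichlet allocation with symmetric priors alpha = beta = 1/K
  by default, the natural choice when nothing is known about topic
  balance.
* :func:`external_membership_adapter` — consumes hard gene/sample block
  memberships exported by external tools (nested block models, WGCNA
  modules, topic-mapping output) and converts them to probabilistic
  theta/phi by counting half-edges: P(topic|sample) is the fraction of
  a sample's expression weight falling on the topic's genes, and
  P(gene|topic) is the gene's share of the topic's total weight.

Hard sample clusters are derived from theta by argmax; note that a
topic that is never maximal yields no cluster, so the number of
clusters can be smaller than K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .partition_metrics import PartitionLabels

__all__ = [
    "CountMatrix",
    "TopicModelResult",
    "GibbsConfig",
    "lda_gibbs_fit",
    "clusters_from_theta",
    "build_ranked_corpus",
    "external_membership_adapter",
    "match_topics",
]


@dataclass
class CountMatrix:
    """Genes x samples non-negative expression values with identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("negative expression values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_frequencies(self) -> np.ndarray:
        """Column-normalized values: P(gene|sample)."""
        totals = self.values.sum(axis=0, keepdims=True)
        if np.any(totals == 0):
            bad = [s for s, t in zip(self.sample_ids, totals.ravel()) if t == 0]
            raise ValueError(f"samples with zero total expression: {bad}")
        return self.values / totals

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        pos = [index[g] for g in gene_ids]
        return CountMatrix(self.values[pos], list(gene_ids), self.sample_ids)


@dataclass
class TopicModelResult:
    """theta = P(topic|sample) and phi = P(gene|topic) plus hard memberships.

    ``theta`` is samples x K with rows summing to 1; ``phi`` is
    genes x K with columns summing to 1.  ``gene_topic_membership`` is
    an optional hard gene -> topic assignment (index into topics, -1
    for genes dropped by the producing algorithm).
    """

    theta: np.ndarray
    phi: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    model_name: str = "model"
    gene_topic_membership: np.ndarray | None = None
    levels: list | None = None
    log_likelihood: float | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.theta.ndim != 2 or self.phi.ndim != 2:
            raise ValueError("theta and phi must be 2-d")
        if self.theta.shape[1] != self.phi.shape[1]:
            raise ValueError("theta and phi disagree on the number of topics")
        if self.theta.shape[0] != len(self.sample_ids):
            raise ValueError("theta rows must match sample_ids")
        if self.phi.shape[0] != len(self.gene_ids):
            raise ValueError("phi rows must match gene_ids")
        if self.n_topics < 1:
            raise ValueError("at least one topic required")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.phi.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("phi columns must sum to 1")

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]

    @property
    def topic_frequencies(self) -> np.ndarray:
        """Empirical topic weights f_t: mean of P(topic|sample) over samples."""
        return self.theta.mean(axis=0)


@dataclass
class GibbsConfig:
    """Settings for the collapsed Gibbs sampler.

    alpha and beta default to 1/K, the natural symmetric choice.
    Posterior means are averaged over the ``n_sweeps - burn_in`` final
    sweeps.
    """

    K: int
    alpha: float | None = None
    beta: float | None = None
    n_sweeps: int = 200
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha is None:
            self.alpha = 1.0 / self.K
        if self.beta is None:
            self.beta = 1.0 / self.K
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("require 0 <= burn_in < n_sweeps")


@njit(cache=True)
def _gibbs_kernel(
    sample_ix, gene_ix, K, n_genes, n_samples, alpha, beta, n_sweeps, burn_in, seed
):  # pragma: no cover - exercised via lda_gibbs_fit
    np.random.seed(seed)
    n_tokens = sample_ix.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    n_sk = np.zeros((n_samples, K), dtype=np.int64)
    n_gk = np.zeros((n_genes, K), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    n_s = np.zeros(n_samples, dtype=np.int64)
    for t in range(n_tokens):
        k = np.random.randint(0, K)
        z[t] = k
        n_sk[sample_ix[t], k] += 1
        n_gk[gene_ix[t], k] += 1
        n_k[k] += 1
        n_s[sample_ix[t]] += 1
    cum = np.empty(K)
    theta_acc = np.zeros((n_samples, K))
    phi_acc = np.zeros((n_genes, K))
    kept = 0
    for sweep in range(n_sweeps):
        for t in range(n_tokens):
            s = sample_ix[t]
            g = gene_ix[t]
            k = z[t]
            n_sk[s, k] -= 1
            n_gk[g, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                p = (n_sk[s, kk] + alpha) * (n_gk[g, kk] + beta) / (
                    n_k[kk] + n_genes * beta
                )
                total += p
                cum[kk] = total
            u = np.random.random() * total
            k = 0
            while cum[k] < u:
                k += 1
            z[t] = k
            n_sk[s, k] += 1
            n_gk[g, k] += 1
            n_k[k] += 1
        if sweep >= burn_in:
            kept += 1
            for s in range(n_samples):
                denom = n_s[s] + K * alpha
                for kk in range(K):
                    theta_acc[s, kk] += (n_sk[s, kk] + alpha) / denom
            for kk in range(K):
                denom = n_k[kk] + n_genes * beta
                for g in range(n_genes):
                    phi_acc[g, kk] += (n_gk[g, kk] + beta) / denom
    return theta_acc / kept, phi_acc / kept


def lda_gibbs_fit(counts: CountMatrix, cfg: GibbsConfig) -> TopicModelResult:
    """Fit LDA by collapsed Gibbs sampling over token-topic assignments.

    Token t in sample s carrying gene g is resampled from
    ``p(k) ~ (n_sk + alpha) (n_gk + beta) / (n_k + N beta)`` with its
    own assignment removed.  theta and phi are Dirichlet-smoothed
    posterior means averaged over post-burn-in sweeps.  Deterministic
    given ``cfg.seed``.

    Real-valued matrices (TPM/FPKM) are rounded to integers with a
    warning; expression then acts as edge multiplicity.
    """
    values = counts.values
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.rint(values)
        if not np.allclose(values, rounded):
            warnings.warn(
                "real-valued expression rounded to integer token counts",
                UserWarning,
            )
        values = rounded.astype(np.int64)
    col_sums = values.sum(axis=0)
    if np.any(col_sums == 0):
        bad = [s for s, t in zip(counts.sample_ids, col_sums) if t == 0]
        raise ValueError(f"samples with no tokens: {bad}")

    gene_nz, sample_nz = np.nonzero(values)
    reps = values[gene_nz, sample_nz]
    gene_ix = np.repeat(gene_nz, reps).astype(np.int32)
    sample_ix = np.repeat(sample_nz, reps).astype(np.int32)

    theta, phi = _gibbs_kernel(
        sample_ix,
        gene_ix,
        cfg.K,
        counts.n_genes,
        counts.n_samples,
        float(cfg.alpha),
        float(cfg.beta),
        cfg.n_sweeps,
        cfg.burn_in,
        cfg.seed,
    )
    # renormalize away floating-point drift from sweep averaging
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = phi / phi.sum(axis=0, keepdims=True)
    freq = values / col_sums
    with np.errstate(divide="ignore"):
        ll = float(
            (values * np.where(freq > 0, np.log(np.clip(phi @ theta.T, 1e-300, None)), 0.0)).sum()
        )
    return TopicModelResult(
        theta=theta,
        phi=phi,
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        model_name=f"lda_gibbs(K={cfg.K})",
        log_likelihood=ll,
    )


def clusters_from_theta(result: TopicModelResult) -> PartitionLabels:
    """Label each sample by its maximal topic (ties to the lowest index).

    Topics never maximal in any sample produce no cluster, so the
    number of distinct labels may be below K.
    """
    labels = np.argmax(result.theta, axis=1)
    return PartitionLabels(np.asarray(result.sample_ids), labels)


def build_ranked_corpus(
    counts: CountMatrix, top_n: int = 1000
) -> dict[str, list[str]]:
    """Per-sample token lists of the ``top_n`` most expressed genes.

    Expression ties are broken by gene-id lexical order.  Samples with
    fewer than ``top_n`` nonzero genes contribute all their nonzero
    genes (with a warning); tokens are unweighted.
    """
    if top_n > counts.n_genes:
        raise ValueError("top_n exceeds the number of genes")
    genes = np.asarray(counts.gene_ids)
    corpus: dict[str, list[str]] = {}
    short = []
    for j, sid in enumerate(counts.sample_ids):
        col = counts.values[:, j]
        order = np.lexsort((genes, -col))
        nonzero = int((col > 0).sum())
        take = min(top_n, nonzero)
        if nonzero < top_n:
            short.append(sid)
        corpus[sid] = genes[order[:take]].tolist()
    if short:
        warnings.warn(
            f"{len(short)} sample(s) had fewer than {top_n} nonzero genes: "
            f"{short[:5]}...",
            UserWarning,
        )
    return corpus


def external_membership_adapter(
    sample_blocks: Mapping[str, object] | PartitionLabels | None,
    gene_blocks: Mapping[str, object] | PartitionLabels,
    counts: CountMatrix,
    on_missing_gene: str = "drop",
    model_name: str = "external",
) -> TopicModelResult:
    """Build theta/phi from hard block memberships by counting half-edges.

    ``gene_blocks`` maps gene id -> topic id (a partition of the genes
    into topics); expression values act as half-edge multiplicities.
    For each sample, P(topic|sample) is the sample's expression weight
    on the topic's genes divided by its total weight; P(gene|topic) is
    the gene's total weight divided by the topic's total weight.

    Genes present in ``counts`` but absent from ``gene_blocks`` are
    dropped with a warning when ``on_missing_gene='drop'`` (some
    algorithms drop genes during their analyses) or raise when
    ``'error'``.  An optional sample partition is carried along in
    ``levels``.
    """
    if isinstance(gene_blocks, PartitionLabels):
        gene_blocks = dict(zip(gene_blocks.item_ids.tolist(), gene_blocks.labels.tolist()))
    missing = [g for g in counts.gene_ids if g not in gene_blocks]
    if missing:
        if on_missing_gene == "error":
            raise ValueError(f"genes missing from gene_blocks: {missing[:10]}")
        warnings.warn(
            f"dropping {len(missing)} gene(s) absent from gene_blocks",
            UserWarning,
        )
    kept = [g for g in counts.gene_ids if g in gene_blocks]
    if not kept:
        raise ValueError("no genes shared between counts and gene_blocks")
    sub = counts.subset_genes(kept)
    topic_ids = sorted({gene_blocks[g] for g in kept}, key=str)
    topic_index = {t: i for i, t in enumerate(topic_ids)}
    membership = np.array([topic_index[gene_blocks[g]] for g in kept])
    K = len(topic_ids)

    values = sub.values.astype(float)
    indicator = np.zeros((len(kept), K))
    indicator[np.arange(len(kept)), membership] = 1.0
    per_topic_sample = values.T @ indicator  # samples x K weights
    sample_tot = per_topic_sample.sum(axis=1, keepdims=True)
    if np.any(sample_tot == 0):
        bad = [
            s for s, t in zip(sub.sample_ids, sample_tot.ravel()) if t == 0
        ]
        raise ValueError(f"samples with zero weight on kept genes: {bad}")
    theta = per_topic_sample / sample_tot

    gene_tot = values.sum(axis=1)  # weight per gene
    topic_tot = indicator.T @ gene_tot  # weight per topic
    if np.any(topic_tot == 0):
        warnings.warn("topic(s) with zero total weight", UserWarning)
    phi = indicator * gene_tot[:, None]
    phi = phi / np.where(topic_tot == 0, 1.0, topic_tot)[None, :]
    # empty topics get a uniform column so phi stays column-stochastic
    for k in np.nonzero(topic_tot == 0)[0]:
        phi[:, k] = indicator[:, k] / max(indicator[:, k].sum(), 1.0)

    levels = None
    if sample_blocks is not None:
        if not isinstance(sample_blocks, PartitionLabels):
            ids = list(sample_blocks)
            sample_blocks = PartitionLabels(
                np.asarray(ids), np.asarray([sample_blocks[s] for s in ids])
            )
        levels = [
            (
                sample_blocks,
                PartitionLabels(np.asarray(kept), membership),
            )
        ]
    return TopicModelResult(
        theta=theta,
        phi=phi,
        gene_ids=kept,
        sample_ids=sub.sample_ids,
        model_name=model_name,
        gene_topic_membership=membership,
        levels=levels,
    )


def match_topics(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Match columns of two gene-topic matrices by maximum-weight assignment.

    Returns ``perm`` such that topic k of ``phi_a`` corresponds to topic
    ``perm[k]`` of ``phi_b``, using Pearson correlation of the
    P(gene|topic) columns as the assignment weight.
    """
    from scipy.optimize import linear_sum_assignment

    a = phi_a - phi_a.mean(axis=0, keepdims=True)
    b = phi_b - phi_b.mean(axis=0, keepdims=True)
    a = a / np.maximum(np.linalg.norm(a, axis=0, keepdims=True), 1e-12)
    b = b / np.maximum(np.linalg.norm(b, axis=0, keepdims=True), 1e-12)
    corr = a.T @ b
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(phi_a.shape[1], dtype=int)
    perm[rows] = cols
    return perm
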