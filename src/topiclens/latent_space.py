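"""Statistics characterizing a fitted topic space.

Given a topic model (theta = P(topic|sample), phi = P(gene|topic)) and
a tissue annotation, this module computes the quantities used to read
biological structure off the latent space:

* per-tissue topic distributions P(topic|tissue) and their centered
  deviations ``P̄(topic|sample) = P(topic|sample) - mean_s P(topic|s)``,
  summarized per tissue with z-scores to flag tissue-enriched topics;
* rank-abundance curves of P(topic|tissue);
* the correlation between a topic's mean gene frequency and its
  frequency across samples (a signature distinguishing models whose
  topics track the word distribution from models that decorrelate it);
* archetype analysis — how well euclidean distances between per-tissue
  mean positions are preserved between expression space and topic
  space (Spearman rank correlation per tissue);
* the distinctiveness score, the minimum Kullback-Leibler-type Bregman
  divergence between a gene's probability under one topic and its
  nearest alternative, used to extract topic marker-gene lists;
* percentile-threshold gene lists on P(topic|gene).

P(topic|gene) is not part of the LDA parameterization; it is obtained
from phi by Bayes inversion with the empirical topic frequencies
(optionally a uniform topic prior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

from .partition_metrics import PartitionLabels
from .topic_inference import CountMatrix, TopicModelResult

__all__ = [
    "TopicTissueProfile",
    "GeneTopicScores",
    "topic_tissue_distribution",
    "topic_zscore",
    "rank_abundance",
    "gene_topic_scores",
    "topic_gene_frequency_correlation",
    "archetype_distance_preservation",
    "distinctiveness",
    "top_distinctive_genes",
    "percentile_gene_list",
]


@dataclass
class TopicTissueProfile:
    """Per-tissue topic distributions and centered deviations.

    ``P_topic_tissue`` rows (tissues x K) are within-tissue means of
    theta, hence sum to 1.  ``centered`` holds the tissue means of the
    sample-level centered values; ``centered_samples`` keeps the
    sample-level values for box statistics and z-scores.
    """

    tissues: list[str]
    P_topic_tissue: np.ndarray
    centered: np.ndarray
    centered_samples: np.ndarray
    sample_tissues: np.ndarray
    z_scores: np.ndarray | None = None


@dataclass
class GeneTopicScores:
    """P(topic|gene) rows and the per-gene distinctiveness matrix."""

    gene_ids: list[str]
    theta_gt: np.ndarray  # genes x K, rows sum to 1
    distinctiveness: np.ndarray | None = None


def topic_tissue_distribution(
    result: TopicModelResult, tissues: PartitionLabels
) -> TopicTissueProfile:
    """Group theta by tissue: P(topic|tissue) and centered deviations.

    P(topic|tissue) is the within-tissue mean of P(topic|sample)
    (the sum over the tissue's samples, renormalized).  Centered values
    subtract the grand mean over all samples, so their sample-weighted
    average is 0 for every topic.
    """
    labels = tissues.restrict(result.sample_ids).labels
    tissue_names = sorted(set(labels.tolist()), key=str)
    theta = result.theta
    grand_mean = theta.mean(axis=0)
    centered_samples = theta - grand_mean
    P = np.zeros((len(tissue_names), result.n_topics))
    centered = np.zeros_like(P)
    for i, t in enumerate(tissue_names):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"empty tissue {t!r}")
        P[i] = theta[mask].mean(axis=0)
        centered[i] = centered_samples[mask].mean(axis=0)
    return TopicTissueProfile(
        tissues=[str(t) for t in tissue_names],
        P_topic_tissue=P,
        centered=centered,
        centered_samples=centered_samples,
        sample_tissues=labels,
    )


def topic_zscore(
    profile: TopicTissueProfile, threshold: float = 3.0
) -> tuple[TopicTissueProfile, pd.DataFrame]:
    """z-scores of per-tissue centered deviations; flag enriched topics.

    For tissue t and topic k:
    ``z = mean_{s in t} P̄_k(s) / (sd_all_samples(P̄_k) / sqrt(n_t))``.
    Topics with zero variance across samples get z = 0 (warned).
    Returns the profile with ``z_scores`` filled plus a table of
    (tissue, topic, z) rows exceeding ``threshold``.
    """
    sds = profile.centered_samples.std(axis=0, ddof=1)
    zero_var = sds == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} topic(s) have zero variance; z set to 0",
            UserWarning,
        )
    z = np.zeros_like(profile.centered)
    for i, t in enumerate(profile.tissues):
        n_t = int((profile.sample_tissues == t).sum())
        if n_t < 2:
            warnings.warn(f"tissue {t!r} has < 2 samples", UserWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            z[i] = np.where(
                zero_var, 0.0, profile.centered[i] / (sds / np.sqrt(n_t))
            )
    profile.z_scores = z
    rows = [
        {"tissue": t, "topic": k, "z": z[i, k]}
        for i, t in enumerate(profile.tissues)
        for k in range(z.shape[1])
        if z[i, k] > threshold
    ]
    return profile, pd.DataFrame(rows, columns=["tissue", "topic", "z"])


def rank_abundance(profile: TopicTissueProfile) -> pd.DataFrame:
    """Descending-sorted P(topic|tissue) per tissue, indexed by rank."""
    data = {
        t: np.sort(profile.P_topic_tissue[i])[::-1]
        for i, t in enumerate(profile.tissues)
    }
    df = pd.DataFrame(data)
    df.index = np.arange(1, profile.P_topic_tissue.shape[1] + 1)
    df.index.name = "rank"
    return df


def gene_topic_scores(
    result: TopicModelResult, prior: str = "empirical"
) -> GeneTopicScores:
    """P(topic|gene) by Bayes inversion of phi.

    ``P(k|g) ∝ phi[g, k] * f_k`` with f_k the empirical topic
    frequency (mean of theta over samples), or uniform when
    ``prior='uniform'``.  Genes with zero weight in all topics get
    all-zero rows (warned).
    """
    if prior == "empirical":
        f = result.topic_frequencies
    elif prior == "uniform":
        f = np.full(result.n_topics, 1.0 / result.n_topics)
    else:
        raise ValueError("prior must be 'empirical' or 'uniform'")
    joint = result.phi * f[None, :]
    totals = joint.sum(axis=1, keepdims=True)
    dead = totals.ravel() == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} gene(s) have zero weight in every topic",
            UserWarning,
        )
    theta_gt = np.divide(
        joint, np.where(totals == 0, 1.0, totals), out=np.zeros_like(joint)
    )
    return GeneTopicScores(gene_ids=list(result.gene_ids), theta_gt=theta_gt)


def topic_gene_frequency_correlation(
    result: TopicModelResult, counts: CountMatrix
) -> dict:
    """Correlate mean gene frequency per topic with topic frequency.

    For topic t with member genes i (hard memberships if present, else
    argmax of P(topic|gene)):
    ``<f_i>_t = (1/|t|) sum_{i in t} sum_j n_ij / R`` on per-sample
    normalized counts, and ``f_t = (1/R) sum_s P(t|s)``.  Returns
    Spearman and Pearson coefficients plus the per-topic pairs.
    """
    freq = counts.sample_frequencies()
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    pos = [gene_index[g] for g in result.gene_ids]
    mean_freq = freq[pos].sum(axis=1) / counts.n_samples  # sum_j n_ij / R
    if result.gene_topic_membership is not None:
        member = result.gene_topic_membership
    else:
        member = np.argmax(gene_topic_scores(result).theta_gt, axis=1)
    f_t = result.topic_frequencies
    rows = []
    for k in range(result.n_topics):
        mask = member == k
        if not mask.any():
            warnings.warn(f"topic {k} has no member genes; skipped", UserWarning)
            continue
        rows.append(
            {"topic": k, "mean_gene_freq": mean_freq[mask].mean(), "topic_freq": f_t[k]}
        )
    pairs = pd.DataFrame(rows, columns=["topic", "mean_gene_freq", "topic_freq"])
    if len(pairs) < 2:
        warnings.warn("fewer than 2 topics with members; correlation undefined")
        return {"pairs": pairs, "spearman": np.nan, "pearson": np.nan}
    rho = spearmanr(pairs.mean_gene_freq, pairs.topic_freq).statistic
    r = pearsonr(pairs.mean_gene_freq, pairs.topic_freq).statistic
    return {"pairs": pairs, "spearman": float(rho), "pearson": float(r)}


def archetype_distance_preservation(
    result: TopicModelResult,
    counts: CountMatrix,
    tissues: PartitionLabels,
    expression_transform: str = "log",
    log_base: float = 2.0,
    normalize_samples: bool = False,
) -> dict:
    """Spearman agreement of tissue distances in expression vs topic space.

    A tissue archetype is the within-tissue mean P(topic|sample); its
    expression-space counterpart is the within-tissue mean expression
    profile, log_b(x+1)-transformed by default (``'raw'`` to skip),
    optionally on per-sample normalized frequencies.  For each tissue
    the two vectors of euclidean distances to all other tissues are
    rank-correlated; the across-tissue mean is also returned.
    """
    labels = tissues.restrict(result.sample_ids).labels
    tissue_names = sorted(set(labels.tolist()), key=str)
    if len(tissue_names) < 3:
        raise ValueError("need >= 3 tissues for distance rank correlations")
    expr = counts.values.astype(float)
    if normalize_samples:
        expr = counts.sample_frequencies()
    if expression_transform == "log":
        expr = np.log1p(expr) / np.log(log_base)
    elif expression_transform != "raw":
        raise ValueError("expression_transform must be 'log' or 'raw'")
    sample_index = {s: j for j, s in enumerate(counts.sample_ids)}
    cols = [sample_index[s] for s in result.sample_ids]
    expr = expr[:, cols]

    arch_topic = np.stack(
        [result.theta[labels == t].mean(axis=0) for t in tissue_names]
    )
    arch_expr = np.stack(
        [expr[:, labels == t].mean(axis=1) for t in tissue_names]
    )
    d_topic = cdist(arch_topic, arch_topic)
    d_expr = cdist(arch_expr, arch_expr)
    per_tissue = {}
    for i, t in enumerate(tissue_names):
        others = [j for j in range(len(tissue_names)) if j != i]
        rho = spearmanr(d_topic[i, others], d_expr[i, others]).statistic
        per_tissue[str(t)] = float(rho)
    series = pd.Series(per_tissue, name="spearman")
    return {
        "per_tissue": series,
        "mean": float(series.mean()),
        "topic_distances": d_topic,
        "expression_distances": d_expr,
        "tissues": [str(t) for t in tissue_names],
    }


def distinctiveness(scores: np.ndarray, topic: int | None = None) -> np.ndarray:
    """Bregman distinctiveness of each gene for one topic (or all).

    For gene g and topic k the score is
    ``min_{l != k} t_kg * log(t_kg / t_lg) + t_lg - t_kg`` with the
    conventions 0·log 0 = 0 and t_lg = 0 giving an infinite candidate
    (kept only if every candidate is infinite).  This is the Bregman
    divergence of the negative entropy, hence non-negative, and zero
    exactly when the nearest alternative topic carries the same
    probability.  ``scores`` is genes x K (any non-negative gene-topic
    matrix: P(gene|topic) columns or P(topic|gene) rows).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be genes x topics")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    K = scores.shape[1]
    if K < 2:
        raise ValueError("distinctiveness needs at least 2 topics")
    topics = range(K) if topic is None else [topic]
    out = np.full((scores.shape[0], len(list(topics))), np.inf)
    topics = range(K) if topic is None else [topic]
    for col, k in enumerate(topics):
        a = scores[:, k]
        for l in range(K):
            if l == k:
                continue
            b = scores[:, l]
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratio = np.log(np.where(a == 0, 1.0, a)) - np.log(
                    np.where(b == 0, 1.0, b)
                )
                term = np.where(a == 0.0, b, a * log_ratio + b - a)
                term = np.where((b == 0.0) & (a > 0.0), np.inf, term)
            out[:, col] = np.minimum(out[:, col], term)
    return out[:, 0] if topic is not None else out


def top_distinctive_genes(
    result: TopicModelResult,
    k: int,
    n: int = 20,
    scores: np.ndarray | None = None,
) -> list[str]:
    """The n genes with the largest distinctiveness for topic k.

    By default scores come from phi (the P(gene|topic) reading of the
    gene-topic matrix); pass ``scores`` to rank a P(topic|gene) matrix
    instead.  Ties break by gene id; an all-zero signal is warned.
    """
    mat = result.phi if scores is None else np.asarray(scores)
    d = distinctiveness(mat, topic=k)
    genes = np.asarray(result.gene_ids)
    finite = np.where(np.isfinite(d), d, np.nanmax(d[np.isfinite(d)], initial=0.0) + 1.0)
    order = np.lexsort((genes, -finite))
    chosen = order[: min(n, len(genes))]
    if np.all(d[chosen] == 0):
        warnings.warn("all selected genes have zero distinctiveness", UserWarning)
    return genes[chosen].tolist()


def percentile_gene_list(
    theta_gt: np.ndarray,
    topic: int,
    gene_ids: list[str],
    q: float = 0.99,
) -> list[str]:
    """Genes whose P(topic|gene) exceeds the topic's q-quantile.

    ``q = 0`` returns every gene with a positive score.
    """
    col = np.asarray(theta_gt)[:, topic]
    threshold = np.quantile(col, q) if q > 0 else 0.0
    genes = np.asarray(gene_ids)
    return genes[col > threshold].tolist()
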