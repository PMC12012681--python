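"""Synthetic expression corpora with planted tissue/topic structure.

Real tissue transcriptomes have a few robust statistical signatures:
power-law distributed expression levels, a hierarchical tissue ->
sub-tissue organization, expression programs shared by every tissue
alongside tissue-enriched programs, housekeeping genes expressed
everywhere with low dispersion, and (orthogonally) a healthy/diseased
axis.  This module plants all of those features explicitly so that
every downstream stage — topic inference, clustering evaluation,
latent-space statistics, fold-in classification — can be tested against
a known ground truth without downloading any data.

The generative model is a topic mixture: each tissue owns a probability
vector over K topics (common topics carry mass in every tissue); each
topic owns a Zipf-tailed probability vector over genes.  A sample draws
a library size (Poisson by default), jitters its tissue mixture with a
symmetric Dirichlet, then draws each transcript by topic-then-gene.
The per-transcript topic draws are recorded per sample as ground-truth
half-edge assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .partition_metrics import PartitionLabels
from .topic_inference import CountMatrix

__all__ = [
    "PlantedStructure",
    "SyntheticCorpus",
    "planted_structure",
    "generate_corpus",
    "generate_hierarchical_corpus",
    "expected_tissue_distance_matrix",
]


@dataclass
class PlantedStructure:
    """Ground truth for a synthetic corpus.

    ``topic_tissue_mixture`` is tissues x K (rows sum to 1);
    ``topic_gene_weights`` is K x genes (rows sum to 1), with a Zipf
    tail of exponent ``zipf_s``.  ``status_effect`` multiplies the
    ``status_topics`` entries of a diseased sample's mixture before
    renormalization (1.0 = no status axis).
    """

    n_tissues: int
    n_samples_per_tissue: int
    n_genes: int
    n_topics: int
    n_common_topics: int
    topic_tissue_mixture: np.ndarray
    topic_gene_weights: np.ndarray
    subtissues_per_tissue: int = 1
    library_size_mean: float = 2000.0
    fixed_library_size: bool = False
    housekeeping_fraction: float = 0.1
    housekeeping_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    status_effect: float = 1.0
    status_topics: tuple = ()
    diseased_fraction: float = 0.0
    jitter_concentration: float = 50.0
    subtissue_perturbation: float = 0.1
    zipf_s: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        mix = np.asarray(self.topic_tissue_mixture, dtype=float)
        wts = np.asarray(self.topic_gene_weights, dtype=float)
        if self.n_topics < 1 or self.n_genes < 1:
            raise ValueError("need at least one topic and one gene")
        if mix.shape != (self.n_tissues, self.n_topics):
            raise ValueError("topic_tissue_mixture has wrong shape")
        if wts.shape != (self.n_topics, self.n_genes):
            raise ValueError("topic_gene_weights has wrong shape")
        if np.any(mix < 0) or np.any(wts < 0):
            raise ValueError("negative probabilities in planted structure")
        if not np.allclose(mix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("mixture rows must sum to 1")
        if not np.allclose(wts.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("topic_gene_weights rows must sum to 1")
        if self.n_common_topics > 0 and np.any(
            mix[:, : self.n_common_topics] <= 0
        ):
            raise ValueError("every tissue must carry mass on common topics")
        hk = np.asarray(self.housekeeping_genes, dtype=int)
        if hk.size and self.n_common_topics > 0:
            common_w = wts[: self.n_common_topics, hk]
            if np.any(common_w.sum(axis=0) <= 0):
                raise ValueError(
                    "housekeeping genes must have weight in a common topic"
                )

    @property
    def tissue_ids(self) -> list[str]:
        return [f"tissue_{t}" for t in range(self.n_tissues)]


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its planted truth.

    ``true_topic_counts`` (samples x K) aggregates the per-transcript
    topic draws; divided by library size it is the realized
    P(topic|sample).  ``true_mixtures`` holds each sample's jittered
    mixture before sampling.
    """

    counts: CountMatrix
    tissue_labels: PartitionLabels
    subtissue_labels: PartitionLabels
    status_labels: PartitionLabels
    truth: PlantedStructure
    true_topic_counts: np.ndarray
    true_mixtures: np.ndarray

    def __post_init__(self):
        n = self.counts.n_samples
        for lab in (self.tissue_labels, self.subtissue_labels, self.status_labels):
            if len(lab) != n:
                raise ValueError("label vectors must have one entry per sample")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integer")

    @property
    def true_theta(self) -> np.ndarray:
        """Realized P(topic|sample) from the recorded half-edge draws."""
        totals = self.true_topic_counts.sum(axis=1, keepdims=True)
        return self.true_topic_counts / totals


def planted_structure(
    n_tissues: int = 10,
    n_samples_per_tissue: int = 50,
    n_genes: int = 2000,
    n_topics: int = 15,
    n_common_topics: int = 5,
    subtissues_per_tissue: int = 1,
    zipf_s: float = 1.1,
    common_mass: float = 0.3,
    library_size_mean: float = 2000.0,
    fixed_library_size: bool = False,
    housekeeping_fraction: float = 0.1,
    status_effect: float = 1.0,
    diseased_fraction: float = 0.0,
    jitter_concentration: float = 50.0,
    subtissue_perturbation: float = 0.1,
    seed: int = 0,
) -> PlantedStructure:
    """Construct a default planted structure.

    Gene base weights follow a Zipf law ``rank^(-zipf_s)`` (ranks are
    assigned to gene indices by a seeded permutation, so gene identity
    is decoupled from expression level).  The highest-weight
    ``housekeeping_fraction`` of genes are flagged housekeeping and
    assigned round-robin to the common topics; the remaining genes go
    round-robin to the tissue-enriched topics, so topic supports are
    disjoint but interleaved in expression level and the pooled corpus
    keeps the planted Zipf tail.  Each tissue spreads ``common_mass``
    uniformly over the common topics and the rest uniformly over its
    own enriched topics (assigned round-robin across tissues).
    """
    if n_common_topics < 1 or n_common_topics > n_topics:
        raise ValueError("need 1 <= n_common_topics <= n_topics")
    rng = np.random.default_rng(seed)

    ranks = np.arange(1, n_genes + 1, dtype=float)
    base = ranks ** (-zipf_s)
    perm = rng.permutation(n_genes)
    gene_weight = np.empty(n_genes)
    gene_weight[perm] = base  # gene perm[r] has rank r+1

    n_hk = int(round(housekeeping_fraction * n_genes))
    by_weight = np.argsort(-gene_weight, kind="stable")
    hk_genes = by_weight[:n_hk]
    other_genes = by_weight[n_hk:]

    n_specific = n_topics - n_common_topics
    topic_genes: list[list[int]] = [[] for _ in range(n_topics)]
    for i, g in enumerate(hk_genes):
        topic_genes[i % n_common_topics].append(int(g))
    if n_specific > 0:
        for i, g in enumerate(other_genes):
            topic_genes[n_common_topics + i % n_specific].append(int(g))
    else:
        for i, g in enumerate(other_genes):
            topic_genes[i % n_common_topics].append(int(g))

    weights = np.zeros((n_topics, n_genes))
    for k, genes in enumerate(topic_genes):
        if not genes:
            raise ValueError(
                f"topic {k} has no genes; increase n_genes or reduce n_topics"
            )
        w = gene_weight[genes]
        weights[k, genes] = w / w.sum()

    mixture = np.zeros((n_tissues, n_topics))
    mixture[:, :n_common_topics] = common_mass / n_common_topics
    if n_specific > 0:
        owners = [[] for _ in range(n_tissues)]
        for i in range(n_specific):
            owners[i % n_tissues].append(n_common_topics + i)
        for t in range(n_tissues):
            if owners[t]:
                mixture[t, owners[t]] = (1 - common_mass) / len(owners[t])
            else:  # tissue without an enriched topic: all mass on common
                mixture[t, :n_common_topics] = 1.0 / n_common_topics
    else:
        mixture[:, :n_common_topics] = 1.0 / n_common_topics
    mixture = mixture / mixture.sum(axis=1, keepdims=True)

    structure = PlantedStructure(
        n_tissues=n_tissues,
        n_samples_per_tissue=n_samples_per_tissue,
        n_genes=n_genes,
        n_topics=n_topics,
        n_common_topics=n_common_topics,
        topic_tissue_mixture=mixture,
        topic_gene_weights=weights,
        subtissues_per_tissue=subtissues_per_tissue,
        library_size_mean=library_size_mean,
        fixed_library_size=fixed_library_size,
        housekeeping_fraction=housekeeping_fraction,
        housekeeping_genes=hk_genes,
        status_effect=status_effect,
        status_topics=(n_common_topics - 1,) if status_effect != 1.0 else (),
        diseased_fraction=diseased_fraction,
        jitter_concentration=jitter_concentration,
        subtissue_perturbation=subtissue_perturbation,
        zipf_s=zipf_s,
        seed=seed,
    )
    structure.validate()
    return structure


def _status_shift(mixture: np.ndarray, structure: PlantedStructure) -> np.ndarray:
    if structure.status_effect == 1.0 or not structure.status_topics:
        return mixture
    shifted = mixture.copy()
    shifted[list(structure.status_topics)] *= structure.status_effect
    return shifted / shifted.sum()


def _jitter(mixture: np.ndarray, conc: float, rng) -> np.ndarray:
    """Symmetric Dirichlet jitter restricted to the mixture's support."""
    if conc <= 0 or not np.isfinite(conc):
        return mixture
    out = np.zeros_like(mixture)
    support = mixture > 0
    out[support] = rng.dirichlet(conc * mixture[support])
    return out


def _generate(
    structure: PlantedStructure,
    sample_mixtures: np.ndarray,
    tissue_of_sample: list[str],
    subtissue_of_sample: list[str],
) -> SyntheticCorpus:
    structure.validate()
    rng = np.random.default_rng(structure.seed)
    n_samples = sample_mixtures.shape[0]
    K, G = structure.n_topics, structure.n_genes

    # orthogonal status axis: alternate within each tissue for balance
    status = np.array(["healthy"] * n_samples, dtype=object)
    if structure.diseased_fraction > 0:
        period = max(int(round(1.0 / structure.diseased_fraction)), 1)
        for t in sorted(set(tissue_of_sample)):
            idx = [i for i, x in enumerate(tissue_of_sample) if x == t]
            for j, i in enumerate(idx):
                if j % period == period - 1 or structure.diseased_fraction >= 1:
                    status[i] = "diseased"

    counts = np.zeros((G, n_samples), dtype=np.int64)
    topic_counts = np.zeros((n_samples, K), dtype=np.int64)
    mixtures = np.zeros((n_samples, K))
    weights = np.asarray(structure.topic_gene_weights, dtype=float)
    for i in range(n_samples):
        mix = sample_mixtures[i]
        if status[i] == "diseased":
            mix = _status_shift(mix, structure)
        mix = _jitter(mix, structure.jitter_concentration, rng)
        mixtures[i] = mix
        if structure.fixed_library_size:
            lib = int(round(structure.library_size_mean))
        else:
            lib = int(rng.poisson(structure.library_size_mean))
        lib = max(lib, 1)
        z = rng.multinomial(lib, mix)
        topic_counts[i] = z
        for k in np.nonzero(z)[0]:
            counts[:, i] += rng.multinomial(z[k], weights[k])

    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    gene_ids = [f"G{g:05d}" for g in range(G)]
    sample_arr = np.asarray(sample_ids)
    return SyntheticCorpus(
        counts=CountMatrix(counts, gene_ids, sample_ids),
        tissue_labels=PartitionLabels(sample_arr, np.asarray(tissue_of_sample, dtype=object)),
        subtissue_labels=PartitionLabels(sample_arr, np.asarray(subtissue_of_sample, dtype=object)),
        status_labels=PartitionLabels(sample_arr, status),
        truth=structure,
        true_topic_counts=topic_counts,
        true_mixtures=mixtures,
    )


def generate_corpus(structure: PlantedStructure) -> SyntheticCorpus:
    """Draw a corpus at tissue resolution (one sub-tissue per tissue)."""
    structure.validate()
    mix = np.asarray(structure.topic_tissue_mixture, dtype=float)
    tissue_of_sample: list[str] = []
    rows = []
    for t in range(structure.n_tissues):
        for _ in range(structure.n_samples_per_tissue):
            tissue_of_sample.append(structure.tissue_ids[t])
            rows.append(mix[t])
    return _generate(
        structure,
        np.asarray(rows),
        tissue_of_sample,
        list(tissue_of_sample),
    )


def subtissue_mixtures(structure: PlantedStructure) -> np.ndarray:
    """Per-(tissue, sub-tissue) mixtures used by the hierarchical corpus.

    Sub-tissue j of a tissue shifts mass onto its designated sub-topic
    (the j-th common topic) and off its siblings' sub-topics with a
    zero-sum additive perturbation, so the parent mixture is exactly
    the mean of its children.  The magnitude is clipped (with a
    warning) to keep mixtures non-negative.
    """
    S = structure.subtissues_per_tissue
    if S < 2:
        raise ValueError("hierarchical corpus needs subtissues_per_tissue >= 2")
    if structure.n_common_topics < S:
        raise ValueError(
            "need at least subtissues_per_tissue common topics to act as "
            "sub-topics"
        )
    mix = np.asarray(structure.topic_tissue_mixture, dtype=float)
    designated = list(range(S))  # the first S common topics
    out = np.zeros((structure.n_tissues, S, structure.n_topics))
    for t in range(structure.n_tissues):
        parent = mix[t]
        delta = structure.subtissue_perturbation
        # child subtracts delta/S from each sibling sub-topic
        max_delta = S * parent[designated].min()
        if delta > max_delta:
            warnings.warn(
                f"subtissue_perturbation clipped from {delta} to {max_delta}",
                UserWarning,
            )
            delta = max_delta
        basis_mean = np.zeros(structure.n_topics)
        basis_mean[designated] = 1.0 / S
        for j in range(S):
            v = -basis_mean.copy()
            v[designated[j]] += 1.0
            child = parent + delta * v
            child = np.clip(child, 0.0, None)
            out[t, j] = child / child.sum()
    return out


def generate_hierarchical_corpus(structure: PlantedStructure) -> SyntheticCorpus:
    """Draw a corpus whose tissues split into perturbed sub-tissues."""
    structure.validate()
    child = subtissue_mixtures(structure)
    S = structure.subtissues_per_tissue
    rows, tissue_of_sample, subtissue_of_sample = [], [], []
    for t in range(structure.n_tissues):
        for i in range(structure.n_samples_per_tissue):
            j = i % S
            rows.append(child[t, j])
            tissue_of_sample.append(structure.tissue_ids[t])
            subtissue_of_sample.append(f"{structure.tissue_ids[t]}/sub_{j}")
    return _generate(
        structure, np.asarray(rows), tissue_of_sample, subtissue_of_sample
    )


def expected_tissue_distance_matrix(structure: PlantedStructure) -> np.ndarray:
    """Euclidean distances between tissues' expected gene-frequency vectors.

    The expected frequency vector of a tissue is its topic mixture
    times the topic-gene weight matrix; the resulting matrix is the
    ground truth for archetype distance-preservation tests.
    """
    structure.validate()
    freq = np.asarray(structure.topic_tissue_mixture) @ np.asarray(
        structure.topic_gene_weights
    )
    return squareform(pdist(freq, metric="euclidean"))
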