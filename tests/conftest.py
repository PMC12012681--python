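import dataclasses

import numpy as np
import pytest

import topiclens as tl


@pytest.fixture(scope="session")
def two_block_structure():
    """Two tissues with disjoint single topics over disjoint gene sets."""
    n_genes = 40
    weights = np.zeros((2, n_genes))
    weights[0, :20] = 1.0 / 20
    weights[1, 20:] = 1.0 / 20
    return tl.PlantedStructure(
        n_tissues=2,
        n_samples_per_tissue=15,
        n_genes=n_genes,
        n_topics=2,
        n_common_topics=0,
        topic_tissue_mixture=np.array([[1.0, 0.0], [0.0, 1.0]]),
        topic_gene_weights=weights,
        library_size_mean=300.0,
        jitter_concentration=50.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def two_block_corpus(two_block_structure):
    return tl.generate_corpus(two_block_structure)


@pytest.fixture(scope="session")
def small_structure():
    """4 tissues, 8 topics (4 common), with an active status axis."""
    return tl.planted_structure(
        n_tissues=4,
        n_samples_per_tissue=15,
        n_genes=400,
        n_topics=8,
        n_common_topics=4,
        library_size_mean=1000.0,
        status_effect=3.0,
        diseased_fraction=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_structure):
    return tl.generate_corpus(small_structure)


@pytest.fixture(scope="session")
def small_fit(small_corpus):
    cfg = tl.GibbsConfig(K=8, n_sweeps=60, burn_in=30, seed=5)
    return tl.lda_gibbs_fit(small_corpus.counts, cfg)


@pytest.fixture(scope="session")
def planted_adapter(small_structure, small_corpus):
    """Half-edge adapter built from the planted hard gene memberships."""
    weights = small_structure.topic_gene_weights
    gene_blocks = {
        g: int(np.argmax(weights[:, i]))
        for i, g in enumerate(small_corpus.counts.gene_ids)
    }
    return tl.external_membership_adapter(
        None, gene_blocks, small_corpus.counts, model_name="planted"
    )


def chain_structure(seed=21):
    """3-tissue chain: A close to B, B close to C, A far from C."""
    n_genes = 300
    weights = np.zeros((3, n_genes))
    weights[0, :100] = 1.0 / 100
    weights[1, 100:200] = 1.0 / 100
    weights[2, 200:] = 1.0 / 100
    mixture = np.array(
        [
            [0.9, 0.1, 0.0],
            [0.5, 0.5, 0.0],
            [0.1, 0.3, 0.6],
        ]
    )
    return tl.PlantedStructure(
        n_tissues=3,
        n_samples_per_tissue=20,
        n_genes=n_genes,
        n_topics=3,
        n_common_topics=0,
        topic_tissue_mixture=mixture,
        topic_gene_weights=weights,
        library_size_mean=1000.0,
        seed=seed,
    )


def all_partitions(n_items: int, max_blocks: int):
    """Restricted-growth enumeration of set partitions into <= max_blocks."""
    out = []

    def grow(prefix, used):
        if len(prefix) == n_items:
            out.append(tuple(prefix))
            return
        for b in range(min(used + 1, max_blocks - 1) + 1):
            grow(prefix + [b], max(used, b))

    grow([0], 0)
    return out
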