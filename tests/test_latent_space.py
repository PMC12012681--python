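"""Topic-space statistics: profiles, z-scores, distinctiveness, archetypes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import topiclens as tl
from topiclens.latent_space import distinctiveness, percentile_gene_list
from topiclens.partition_metrics import PartitionLabels
from topiclens.topic_inference import CountMatrix, TopicModelResult

from conftest import chain_structure


def make_result(theta, gene_ids=None, phi=None, membership=None):
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[1]
    if phi is None:
        n_genes = len(gene_ids) if gene_ids else 4
        phi = np.full((n_genes, K), 1.0 / n_genes)
    gene_ids = gene_ids or [f"g{i}" for i in range(phi.shape[0])]
    return TopicModelResult(
        theta=theta,
        phi=phi,
        gene_ids=gene_ids,
        sample_ids=[f"s{i}" for i in range(theta.shape[0])],
        gene_topic_membership=membership,
    )


def tissue_labels(result, labels):
    return PartitionLabels(np.asarray(result.sample_ids), np.asarray(labels, dtype=object))


class TestTopicTissueDistribution:
    def test_identical_thetas_center_to_zero(self):
        theta = np.tile([0.3, 0.7], (6, 1))
        result = make_result(theta)
        prof = tl.topic_tissue_distribution(
            result, tissue_labels(result, ["a"] * 3 + ["b"] * 3)
        )
        assert np.allclose(prof.P_topic_tissue, [0.3, 0.7])
        assert np.allclose(prof.centered, 0.0)

    def test_two_sample_tissue_profile_is_mean(self):
        result = make_result([[1.0, 0.0], [0.0, 1.0]])
        prof = tl.topic_tissue_distribution(
            result, tissue_labels(result, ["t", "t"])
        )
        assert np.allclose(prof.P_topic_tissue, [0.5, 0.5])

    def test_centered_values_sum_to_zero_per_topic(self, small_fit, small_corpus):
        prof = tl.topic_tissue_distribution(small_fit, small_corpus.tissue_labels)
        assert np.abs(prof.centered_samples.sum(axis=0)).max() < 1e-10

    def test_planted_profile_matches_mixture(self, planted_adapter, small_corpus):
        prof = tl.topic_tissue_distribution(
            planted_adapter, small_corpus.tissue_labels
        )
        truth = small_corpus.truth
        # average of healthy and status-shifted mixtures per tissue
        from topiclens.synthetic_corpus import _status_shift

        for i, t in enumerate(prof.tissues):
            ti = truth.tissue_ids.index(t)
            mix = truth.topic_tissue_mixture[ti]
            expected = 0.5 * (mix + _status_shift(mix, truth))
            tv = 0.5 * np.abs(prof.P_topic_tissue[i] - expected).sum()
            assert tv < 0.1


class TestTopicZscore:
    def test_constant_topic_scores_zero(self):
        theta = np.tile([0.5, 0.5], (6, 1))
        result = make_result(theta)
        prof = tl.topic_tissue_distribution(
            result, tissue_labels(result, ["a"] * 3 + ["b"] * 3)
        )
        with pytest.warns(UserWarning, match="zero variance"):
            prof, flagged = tl.topic_zscore(prof)
        assert np.allclose(prof.z_scores, 0.0)
        assert flagged.empty

    def test_sign_symmetry(self, small_fit, small_corpus):
        prof = tl.topic_tissue_distribution(small_fit, small_corpus.tissue_labels)
        prof, _ = tl.topic_zscore(prof)
        z = prof.z_scores.copy()
        prof.centered = -prof.centered
        prof.centered_samples = -prof.centered_samples
        prof2, _ = tl.topic_zscore(prof)
        assert np.allclose(prof2.z_scores, -z)

    def test_tissue_exclusive_topic_flagged_only_there(
        self, planted_adapter, small_corpus
    ):
        truth = small_corpus.truth
        prof = tl.topic_tissue_distribution(
            planted_adapter, small_corpus.tissue_labels
        )
        prof, flagged = tl.topic_zscore(prof, threshold=3.0)
        # each tissue owns exactly one exclusive topic in this structure
        exclusive = {
            t: int(np.argmax(truth.topic_tissue_mixture[i]))
            for i, t in enumerate(truth.tissue_ids)
        }
        for tissue, topic in exclusive.items():
            rows = flagged[flagged.topic == topic]
            assert rows.tissue.tolist() == [tissue]


class TestRankAbundance:
    def test_uniform_profile_is_flat(self):
        theta = np.full((4, 5), 0.2)
        result = make_result(theta)
        prof = tl.topic_tissue_distribution(
            result, tissue_labels(result, ["a", "a", "b", "b"])
        )
        ra = tl.rank_abundance(prof)
        assert np.allclose(ra.to_numpy(), 0.2)

    def test_single_topic_tissue_curve(self):
        result = make_result([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        prof = tl.topic_tissue_distribution(result, tissue_labels(result, ["t", "t"]))
        ra = tl.rank_abundance(prof)
        assert ra["t"].tolist() == [1.0, 0.0, 0.0]


class TestDistinctiveness:
    def test_equal_probability_scores_zero(self):
        d = distinctiveness(np.array([[0.3, 0.3], [0.1, 0.1]]))
        assert np.allclose(d, 0.0)

    def test_hand_computed_value(self):
        d = distinctiveness(np.array([[0.2, 0.1]]), topic=0)
        assert d[0] == pytest.approx(0.2 * np.log(2) - 0.1)
        assert d[0] == pytest.approx(0.0386, abs=5e-4)

    def test_zero_alternative_gives_infinite_candidate(self):
        d = distinctiveness(np.array([[0.2, 0.0]]), topic=0)
        assert np.isinf(d[0])
        # but a finite alternative wins the min
        d = distinctiveness(np.array([[0.2, 0.0, 0.2]]), topic=0)
        assert d[0] == 0.0

    def test_single_topic_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            distinctiveness(np.array([[0.5], [0.5]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scores=hnp.arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(2, 5)),
            elements=st.floats(0, 1, allow_nan=False),
        )
    )
    def test_nonnegative_and_matches_bruteforce(self, scores):
        d = distinctiveness(scores)
        assert np.all(d >= 0)
        G, K = scores.shape
        for g in range(G):
            for k in range(K):
                cands = []
                for l in range(K):
                    if l == k:
                        continue
                    a, b = scores[g, k], scores[g, l]
                    if a == 0:
                        cands.append(b)
                    elif b == 0:
                        cands.append(np.inf)
                    else:
                        cands.append(a * (np.log(a) - np.log(b)) + b - a)
                assert d[g, k] == pytest.approx(min(cands))


class TestGeneLists:
    def test_top_distinctive_recovers_exclusive_genes(
        self, planted_adapter, small_corpus
    ):
        truth = small_corpus.truth
        k = truth.n_common_topics  # first tissue-enriched topic
        planted = set(
            np.asarray(small_corpus.counts.gene_ids)[
                truth.topic_gene_weights[k] > 0
            ]
        )
        top = tl.top_distinctive_genes(planted_adapter, k, n=20)
        assert set(top) <= planted

    def test_n_beyond_gene_count_returns_all(self):
        result = make_result(np.eye(2), gene_ids=["g0", "g1", "g2"],
                             phi=np.array([[0.5, 0.2], [0.3, 0.3], [0.2, 0.5]]))
        assert len(tl.top_distinctive_genes(result, 0, n=10)) == 3

    def test_shared_genes_warn_zero_signal(self):
        phi = np.full((3, 2), 1 / 3)
        result = make_result(np.eye(2), gene_ids=["a", "b", "c"], phi=phi)
        with pytest.warns(UserWarning, match="zero distinctiveness"):
            top = tl.top_distinctive_genes(result, 0, n=2)
        assert top == ["a", "b"]  # tie-broken lexically

    def test_percentile_list_uniform_random_scores(self):
        rng = np.random.default_rng(0)
        theta_gt = rng.uniform(size=(1000, 2))
        genes = [f"g{i}" for i in range(1000)]
        lst = percentile_gene_list(theta_gt, 0, genes, q=0.99)
        assert 5 <= len(lst) <= 15  # ~1% of genes

    def test_percentile_q_zero_returns_positive_scores(self):
        theta_gt = np.array([[0.0, 1.0], [0.4, 0.6], [0.8, 0.2]])
        lst = percentile_gene_list(theta_gt, 0, ["a", "b", "c"], q=0.0)
        assert lst == ["b", "c"]

    def test_exclusive_topic_recovered_at_99th_percentile(
        self, planted_adapter, small_corpus
    ):
        truth = small_corpus.truth
        scores = tl.gene_topic_scores(planted_adapter)
        k = truth.n_common_topics
        planted = set(
            np.asarray(planted_adapter.gene_ids)[
                truth.topic_gene_weights[k][
                    [small_corpus.counts.gene_ids.index(g) for g in planted_adapter.gene_ids]
                ]
                > 0
            ]
        )
        lst = set(percentile_gene_list(scores.theta_gt, k, planted_adapter.gene_ids, q=0.99))
        assert lst <= planted


class TestTopicGeneFrequencyCorrelation:
    def test_expression_bands_correlate_strongly(self, small_corpus):
        counts = small_corpus.counts
        freq = counts.values.sum(axis=1) / counts.values.sum()
        edges = np.quantile(freq, np.linspace(0, 1, 9)[1:-1])
        bands = np.digitize(freq, edges)
        blocks = {g: int(bands[i]) for i, g in enumerate(counts.gene_ids)}
        result = tl.external_membership_adapter(None, blocks, counts)
        corr = tl.topic_gene_frequency_correlation(result, counts)
        assert corr["spearman"] > 0.9

    def test_permuted_model_memberships_decorrelate(self, small_fit, small_corpus):
        """Shuffling gene->topic memberships while keeping the model's theta
        breaks the frequency coupling (the decorrelated regime)."""
        import dataclasses

        counts = small_corpus.counts
        member = np.argmax(tl.gene_topic_scores(small_fit).theta_gt, axis=1)
        rng = np.random.default_rng(3)
        null = []
        for _ in range(40):
            shuffled = dataclasses.replace(
                small_fit, gene_topic_membership=rng.permutation(member)
            )
            null.append(
                tl.topic_gene_frequency_correlation(shuffled, counts)["spearman"]
            )
        null = np.asarray(null)
        lo, hi = np.quantile(null[1:], [0.025, 0.975])
        assert lo <= null[0] <= hi
        assert abs(np.mean(null)) < 0.5

    def test_single_topic_correlation_undefined(self):
        counts = CountMatrix(np.array([[3, 1], [1, 3]]), ["a", "b"], ["s1", "s2"])
        result = tl.external_membership_adapter(None, {"a": 0, "b": 0}, counts)
        with pytest.warns(UserWarning, match="fewer than 2"):
            corr = tl.topic_gene_frequency_correlation(result, counts)
        assert np.isnan(corr["spearman"])


@pytest.fixture(scope="module")
def chain_fit():
    st = chain_structure()
    corpus = tl.generate_corpus(st)
    fit = tl.lda_gibbs_fit(
        corpus.counts,
        tl.GibbsConfig(K=3, n_sweeps=80, burn_in=40, seed=2),
    )
    return st, corpus, fit


class TestArchetypeDistancePreservation:
    def test_identity_embedding_preserves_distances_exactly(self, small_corpus):
        counts = small_corpus.counts
        freq = counts.sample_frequencies().T  # samples x genes
        result = TopicModelResult(
            theta=freq,
            phi=np.eye(counts.n_genes),
            gene_ids=counts.gene_ids,
            sample_ids=counts.sample_ids,
            model_name="identity",
        )
        out = tl.archetype_distance_preservation(
            result,
            counts,
            small_corpus.tissue_labels,
            expression_transform="raw",
            normalize_samples=True,
        )
        assert np.allclose(out["per_tissue"].to_numpy(), 1.0)

    def test_chain_corpus_preserves_distance_ranking(self, chain_fit):
        st, corpus, fit = chain_fit
        out = tl.archetype_distance_preservation(
            fit, corpus.counts, corpus.tissue_labels
        )
        assert out["mean"] == pytest.approx(1.0)
        d = out["topic_distances"]
        expected = tl.expected_tissue_distance_matrix(st)
        i, j, k = 0, 1, 2  # tissues sorted lexically = construction order
        assert (d[i, j] < d[i, k]) == (expected[i, j] < expected[i, k])
        assert (d[j, k] < d[i, k]) == (expected[j, k] < expected[i, k])

    def test_scrambled_archetypes_destroy_correlation(self, chain_fit):
        """Permuting the topic-space archetypes only wipes out the agreement."""
        import itertools

        from scipy.stats import spearmanr

        _, corpus, fit = chain_fit
        out = tl.archetype_distance_preservation(
            fit, corpus.counts, corpus.tissue_labels
        )
        d_topic, d_expr = out["topic_distances"], out["expression_distances"]
        n = d_topic.shape[0]
        perm_scores = []
        for p in itertools.permutations(range(n)):
            if p == tuple(range(n)):
                continue
            dp = d_topic[np.ix_(p, p)]
            for i in range(n):
                others = [j for j in range(n) if j != i]
                perm_scores.append(
                    spearmanr(dp[i, others], d_expr[i, others]).statistic
                )
        assert abs(np.mean(perm_scores)) < 0.5
        assert np.mean(perm_scores) < out["mean"]

    def test_fewer_than_three_tissues_rejected(self):
        result = make_result(np.eye(2))
        counts = CountMatrix(
            np.ones((4, 2)), [f"g{i}" for i in range(4)], result.sample_ids
        )
        with pytest.raises(ValueError, match=">= 3 tissues"):
            tl.archetype_distance_preservation(
                result, counts, tissue_labels(result, ["a", "b"])
            )
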