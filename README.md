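# topiclens

Topic modeling for transcriptomics: explore the latent topic space of
gene-by-sample expression matrices, score clusterings against known
annotations with a random-partition-normalized NMI, characterize the
topic space, and classify unseen samples after fold-in projection.

## Who this is for

Computational biologists who want to treat RNA-seq samples the way text
mining treats documents: a gene-by-sample matrix 𝒜 (TPM/FPKM or
counts) is read as a bag of words, with genes as words, samples as
documents, and expression as edge multiplicity in a bipartite
sample–gene network.  A topic model compresses this network into

* θ — samples × K, θ_sk = P(topic k | sample s), rows sum to 1;
* ϕ — genes × K, ϕ_gk = P(gene g | topic k), columns sum to 1.

The package provides a self-contained, seedable collapsed-Gibbs LDA
(symmetric priors α = β = 1/K) and an adapter that converts hard gene
block memberships exported by external tools (nested stochastic block
models, WGCNA modules, topic mapping) into the same θ/ϕ by counting
half-edges.  On top of either model it computes:

* **Clustering evaluation** — homogeneity h = 1 − H(C|K)/H(C),
  completeness C = 1 − H(K|C)/H(K), their harmonic mean (the
  V-measure/NMI), the asymmetric NMI(X,Y) = I(X,Y)/H(X) for comparing
  two methods, and **NMI\*** — the score divided by its mean under
  size-preserving random partitions, because random partitions do not
  score zero.
* **Latent-space structure** — P(topic|tissue) profiles, centered
  deviations P̄ with z-scores flagging tissue-enriched topics,
  rank-abundance curves, the topic-frequency/gene-frequency coupling,
  archetype distance preservation (Spearman agreement of inter-tissue
  distances between expression space and topic space), and marker gene
  lists ranked by the distinctiveness score
  D^g[K] = min_{l≠k} θ_kg log(θ_kg/θ_lg) + θ_lg − θ_kg.
* **Concordance** — exact hypergeometric tests on gene-list overlaps
  and pairwise NMI matrices between methods, on the gene or sample side.
* **Fold-in classification** — unseen samples are projected by
  P(topic|sample) = Σ_g P(topic|gene)·P(gene|sample) without refitting,
  then classified by a one-hidden-layer (100 ReLU) network or a 5-NN
  baseline.
* **A synthetic corpus generator** with planted tissue/topic structure
  (Zipf-tailed expression, common + tissue-enriched topics,
  housekeeping genes, a healthy/diseased axis, optional sub-tissue
  hierarchy and single-cell-like sparsity), so the whole pipeline is
  testable end to end with known ground truth.

See `docs/methods.md` for the model, the conventions, and the
generator's assumptions.

## Worked example

Simulate a corpus with 5 tissues, fit LDA, and score the clusters:

```sh
topiclens simulate --tissues 5 --samples-per-tissue 20 --genes 500 \
    --topics 8 --common-topics 3 --library-size 1000 --seed 1 \
    --out demo/corpus
topiclens fit --expr demo/corpus/counts.tsv --model lda --k 8 \
    --sweeps 100 --burn-in 50 --seed 2 --out demo/model
topiclens evaluate --truth demo/corpus/metadata.tsv \
    --pred demo/model/clusters.tsv --null-reps 1000 --seed 3
```

which prints

```
wrote corpus (500 genes x 100 samples) to demo/corpus
fitted lda_gibbs(K=8): 8 topics, 5 argmax clusters -> demo/model
homogeneity	completeness	nmi	null_mean	null_std	nmi_star
1.0	1.0	1.0	0.05467413567146991	0.019920275923581685	18.290183973074136
```

Reading the output: the argmax of θ produced 5 clusters (3 of the 8
topics are shared background programs and are never maximal), the
clusters match the 5 planted tissues exactly (h = C = NMI = 1), and
random partitions of the same shape score 0.055 ± 0.020, so the fit
sits 18× above its random baseline (NMI* = 18.3).

The same steps are available as library calls
(`topiclens.generate_corpus`, `topiclens.lda_gibbs_fit`,
`topiclens.v_measure`, `topiclens.random_partition_null`, ...), and the
remaining subcommands cover the rest of the pipeline: `latent`
(profiles, z-scores, marker lists), `compare` (cross-method NMI),
`project` (fold-in), `classify` (topic-space classifier).

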