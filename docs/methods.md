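# Methods

## The model

`topiclens` treats a gene-by-sample expression matrix 𝒜 as a bag of
words: genes are words, samples are documents, and the expression value
𝒜_gs is the multiplicity of the gene–sample edge in a bipartite
network (each unit of weight is a *half-edge* on both sides).  A topic
model summarizes this network by two stochastic matrices:

* θ, samples × K, with θ_sk = P(topic k | sample s), rows summing to 1;
* ϕ, genes × K, with ϕ_gk = P(gene g | topic k), columns summing to 1.

Two routes produce these matrices.

**Collapsed Gibbs LDA** (`topic_inference.lda_gibbs_fit`).  Latent
Dirichlet allocation with symmetric priors α = β = 1/K, the natural
choice when nothing is known about topic balance.  Each expression unit
is one token; token t in sample s carrying gene g is resampled from

    p(z_t = k) ∝ (n_sk + α) · (n_gk + β) / (n_k + Nβ)

with its own assignment removed, where n_sk, n_gk, n_k are the current
assignment counts and N is the number of genes.  θ and ϕ are the
Dirichlet-smoothed posterior means (n_sk + α)/(n_s + Kα) and
(n_gk + β)/(n_k + Nβ) averaged over post-burn-in sweeps.  Defaults:
200 sweeps, 100 burn-in, fixed integer seed (runs are bit-reproducible).
Real-valued TPM/FPKM input is rounded to integer token counts with a
warning.  The kernel is JIT-compiled; a 500-sample × 2000-gene corpus
with ~2000 counts per sample fits in under ten seconds on one core.

**Half-edge adapter** (`external_membership_adapter`).  Hard gene→topic
memberships exported by external tools (nested block models, WGCNA
modules, topic-mapping output) are converted to θ and ϕ by counting
half-edges: P(topic|sample) is the fraction of the sample's expression
weight on the topic's genes; P(gene|topic) is the gene's share of the
topic's total weight.  Genes missing from the membership map are dropped
with a warning (external tools routinely drop genes), or rejected on
request.

Hard sample clusters come from the argmax of θ rows, ties to the lowest
topic index; a topic that is never maximal yields no cluster, so the
cluster count can be below K.

## Evaluation metrics

Clustering quality against a reference partition C uses the V-measure:
homogeneity h = 1 − H(C|K)/H(C), completeness C = 1 − H(K|C)/H(K), and
their harmonic mean.  Comparisons between two arbitrary partitions use
the asymmetric NMI(X, Y) = I(X, Y)/H(X).  All entropies are natural-log;
every reported quantity is a ratio of entropies, so the base cancels.
Degenerate conventions: a zero-entropy reference scores 1 (0/0 → 1);
NMI(X, Y) with H(X) = 0 is 1 if Y is also a single cluster, else 0.

A random partition of the same shape does not score zero, and the
residual grows with the cluster count.  Observed scores are therefore
divided by the mean score of random partitions preserving the observed
cluster-size multiset (implemented as uniform permutations of the
observed assignment); the ratio is NMI*.  Each partition gets its own
null (1000 replicates by default) rather than interpolating the null
across cluster counts — direct nulls are cheap at this scale and
strictly more accurate.  The per-replicate ratios are also returned, as
the intrinsic variability of the normalization.

Gene-list overlaps between methods use the exact hypergeometric pmf
P(k) = C(K,k)·C(N−K,n−k)/C(N,n) over the universe of genes processed by
*both* methods; the pointwise probability is the headline number and
the upper tail P(≥k) is reported alongside, since enrichment testing
conventionally uses the tail.  Integer-exact arithmetic is used up to
N = 2000, log-space survival functions beyond.

## Latent-space statistics

* **Tissue profiles.**  P(topic|tissue) is the within-tissue mean of θ
  (the sum over a tissue's samples, renormalized).  Centered deviations
  P̄(topic|sample) = P(topic|sample) − mean_s P(topic|s) sum to zero
  over samples by construction; per tissue they are summarized by
  z = mean_t(P̄) / (sd_all(P̄)/√n_t), flagged above 3 by default.
* **Frequency coupling.**  For each topic, the mean per-sample
  normalized frequency of its member genes is correlated (Spearman and
  Pearson — the appropriate choice is left to the reader, both are
  reported) with the topic's frequency f_t = mean_s θ_st.  Half-edge
  topics are tied to the word distribution and correlate strongly;
  probabilistic models whose θ is decoupled from any hard gene grouping
  do not.
* **Archetypes.**  A tissue archetype is the within-tissue mean θ row.
  Per tissue, the euclidean distances to all other archetypes are
  rank-correlated with the same distances computed on within-tissue
  mean expression (log_b(x+1)-transformed by default, with a raw
  option, since distance structure in expression space is usually read
  on the log scale).  A mean Spearman of 1 means the low-dimensional
  projection preserves the tissue hierarchy exactly.
* **Distinctiveness.**  D^g[K] = min_{l≠k} θ_kg·log(θ_kg/θ_lg) + θ_lg − θ_kg
  is the Bregman divergence of the negative entropy between a gene's
  probability under topic k and its nearest alternative: non-negative,
  zero exactly at equal probabilities, with 0·log 0 = 0 and a zero
  alternative giving an infinite candidate.  Topic marker lists are the
  top-20 genes by this score (ties by gene id); an alternative
  percentile rule keeps genes above the 99th percentile of
  P(topic|gene).  P(topic|gene) is not part of the LDA parameterization
  and is obtained by Bayes inversion of ϕ with empirical topic weights
  f_t (uniform prior available); base and prior changes only rescale
  scores and leave rankings unchanged.

## Fold-in and classification

A new sample never seen during fitting is projected by
P(topic|sample) = Σ_g P(topic|gene)·P(gene|sample): its expression,
restricted to the modeled genes and normalized within that set, is
multiplied by the genes × topics matrix and the row renormalized.  For
hard-membership models P(topic|gene) is the membership indicator and
the projection of a training sample reproduces its half-edge θ exactly
(an algebraic identity, tested to machine precision).

The design matrix X of θ rows is normalized per feature:
X̄ = (X − mean)/(0.5·(max − min)), statistics from the training set
only; constant features map to 0.  Note the mean-centered, half-range
scaled values lie in [−2, 2], not [−1, 1], unless the feature mean
equals its midrange; a `per_sample` flag reproduces the row-wise
reading of the same formula for comparison.  The classifier is a
single-hidden-layer network (100 ReLU units) trained by SGD with a
softmax output for tissues or a single logistic output for binary
status, on a 95/5 train/test split with 25% of the training slice used
for validation-based early stopping.  Learning rate 0.05 and a 1000
epoch cap are package defaults (these hyperparameters are otherwise
unconstrained); everything is seeded.  A 5-nearest-neighbor euclidean
vote under the same split protocol serves as the expression-space
baseline.  The topic model is never refitted for held-out data.

## The synthetic corpus generator

The generator plants the statistical signatures the pipeline is meant
to detect; it emulates the *structure* of tissue transcriptomes, not
any particular dataset.

* **Power-law expression.**  Gene base weights follow a Zipf law
  rank^(−s) with s = 1.1 by default (bulk expression levels are
  heavy-tailed with an exponent near 1); ranks are assigned to gene ids
  by a seeded permutation.  Topic supports are disjoint but interleaved
  in expression level, so the pooled corpus keeps the planted tail
  (checked by fitting the log–log rank–frequency slope over the top
  decade of ranks).
* **Common vs tissue-enriched topics.**  Each tissue spreads 30% of its
  mixture uniformly over the common topics (present in every tissue)
  and the rest over its own enriched topics, assigned round-robin.
* **Housekeeping genes.**  The top 10% of genes by base weight are
  flagged housekeeping and placed in the common topics: expressed in
  every sample, high level, low relative dispersion.
* **Sampling.**  A sample draws a library size (Poisson, mean 2000 by
  default, mirroring sequencing-depth variability; a fixed mode exists
  for exact tests), jitters its tissue mixture with a Dirichlet of
  concentration 50 × mixture restricted to the mixture's support (a
  modest within-tissue variability; there is no accepted generative
  value, so it is a documented, configurable choice), then draws each
  transcript topic-then-gene.  Per-transcript topic draws are recorded
  per sample, so the realized P(topic|sample) is known exactly.
* **Status axis.**  Diseased samples multiply a designated topic subset
  (the last common topic by default) by status_effect = 3 and
  renormalize — a single shifted expression program, orthogonal to
  tissue identity because disease status is balanced within every
  tissue.
* **Hierarchy.**  Sub-tissue j of a tissue adds a zero-sum perturbation
  toward its designated sub-topic (the j-th common topic), so the
  parent mixture is exactly the mean of its children and the magnitude
  is clipped to keep mixtures non-negative.
* **Single-cell mode.**  A small library size (~1000) induces sparsity
  by sampling alone; no separate zero-inflation mechanism is modeled.

What the generator does *not* emulate: batch effects, gene–gene
correlation beyond topic co-membership, isoform structure, ambient
contamination.  Tests passing on this generator show that the pipeline
recovers planted mixtures, hierarchies, and status axes under
multinomial sampling noise — not that any particular biological dataset
has such structure.

## Problem sizes and numerical choices

The end-to-end checks run on a planted corpus of 10 tissues × 50
samples, 2000 genes, 15 topics (5 common), ~2000 counts per sample,
with a 10 × 20-sample corpus of unseen samples for fold-in and
classification — large enough that clustering nulls and AUCs are
stable, small enough to run on a laptop core in well under a minute.
Nulls use 1000 size-preserving shuffles.  Sweep-averaged θ/ϕ are
renormalized at the end to absorb floating-point drift; tolerances are
1e-8 on stochasticity invariants and machine-precision assertions where
an identity is algebraic (fold-in on hard memberships, Eq-style
centering).  Ties everywhere break deterministically (lowest topic
index, lexical gene id).

## Known limitations

* The Gibbs sampler is a single chain; no convergence diagnostics
  beyond the final training log-likelihood are reported.
* The adapter consumes one exported membership level at a time; model
  selection across levels or runs (e.g. by description length) is the
  exporting tool's job.
* Hierarchical inference itself (nested block models) is out of scope;
  only its exported memberships are consumed.
* The generator's disjoint topic supports make planted marker lists
  unambiguous; real expression programs overlap, and marker recovery
  there will be correspondingly softer.
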