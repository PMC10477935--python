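# Methods

## The problem

Findings in one model organism rarely transfer to another by sequence
homology alone: proteins with similar pathway roles need not be the closest
sequence matches. `etna` treats cross-species functional transfer as a
*joint network embedding* problem. Each species' protein–protein interaction
(PPI) network is embedded by an autoencoder; the two latent spaces are then
tied together by cross-training over sequence-derived ortholog anchor pairs.
The output is a single latent space in which cosine similarity between any
gene of species A and any gene of species B estimates functional
relatedness — bidirectionally, with no choice of source or target species.

## Model

### Per-species embedding

A network `G = (V, E)` with `n = |V|` vertices is represented not by its
adjacency matrix `A` but by the closed-form random-walk matrix

    R = (vol(G) / T) * (Σ_{i=1..T} (D⁻¹A)^i) * D⁻¹
    M = max(log(R / b), 0)   elementwise, structural zeros kept at 0

with degree matrix `D`, volume `vol(G) = Σ_i deg(i)`, context window `T`
(default 10) and negative-sampling parameter `b` (default 1). `M[i, j]`
weights the paths of length ≤ T between vertices `i` and `j`, so a row of
`M` describes a vertex's multi-hop neighborhood, not just its direct
partners. The elementwise log is undefined at 0 and negative for small
entries; the truncation `max(log(x/b), 0)` keeps `M` nonnegative with the
reachability sparsity pattern intact. `M` is materialized dense; the
intended regime (up to ~20k vertices after preprocessing) fits in memory.

Each species' autoencoder maps a row `m_i` through a 1024-unit hidden layer
to a 128-dimensional latent `z_i`, and decodes through an independent
1024-unit hidden layer back to an `n`-vector of logits. Hidden layers use a
leaky rectifier with negative slope 0.1. **The latent layer itself is
linear.** This matters: a rectified latent pushes all coordinates positive,
which collapses the cosine-similarity score distribution into a narrow cone
(we observed all-pairs cosine ≈ 0.87 ± 0.03 with a rectified latent, i.e.
essentially no discrimination). Since cosine similarity *is* the method's
output statistic, the latent must carry both signs.

The embedding objective is

    L_embed = α·L_high + γ·L_1st + λ·L2 + ω·L_norm

- `L_high` — binary cross-entropy between `σ(decoder logits)` and `M`
  min-max scaled into [0, 1]. The cross-entropy is **normalized by rows,
  not entries**: each vertex contributes the *sum* of its `n`
  reconstruction terms. This is the scale on which the recommended weights
  balance. Under a per-entry mean, `α·L_high ≈ 10` versus `λ·L2 ≈ 700` on a
  300-vertex problem, the weight penalty dominates, and the latent provably
  collapses to zero (we measured ‖z‖ → 0.000 and reconstruction AUROC 0.50
  after 100 epochs). With row normalization the reconstruction term
  dominates, as intended — it is the term designed to carry the signal.
  The per-entry form remains available (`loss_high(..., normalization="entry")`)
  as a descriptive metric.
- `L_1st = −(1/2|E|) Σ_{ij} A_ij log(clamp(cos(z_i, z_j), 1e−8, 1))` —
  adjacent vertices are pulled together. Only reported edges contribute:
  absent edges in PPI data are unreliable negatives. The clamp keeps the
  log defined for non-positive cosines; the loss is invariant to positive
  rescaling of any row.
- `L2` — sum of squared weight-matrix entries, biases excluded.
- `L_norm = Σ_i ‖z_i‖²` — guards against exploding latent norms.

Defaults: α=100, γ=5, λ=1, ω=1 (and φ=50 below). These are the recommended
starting values for a new species pair; per-species weight sets are
accepted.

### Cross-training alignment

Given ortholog anchors Θ ⊂ V × V′, the alignment objective is

    L_cross = φ · Σ_{(i,i′)∈Θ} [ BCE(σ(De_B(En_A(m_i))), m′_i′)
                               + BCE(σ(De_A(En_B(m′_i′))), m_i) ]

If a gene and its ortholog play the same role, species A's encoder should
place the gene where species B's decoder can reconstruct the *ortholog's*
neighborhood, and vice versa — the translation analogy from NLP. Alignment
epochs update **encoders only**: the alignment should happen in latent
space, not reconstruction space. Per anchor, the BCE is the mean over the
target row's entries, and the anchor sum is not normalized (φ absorbs
scale); this keeps `L_cross` roughly 10–20% of `L_embed` per step at both
the intended real-data scale and the synthetic scale, matching the design
intent that reconstruction dominates.

One **training block** = one embedding epoch per species + one alignment
epoch. Default 10 blocks (use ~20 for sparse, anchor-poor pairs). The final
score matrix is `S = cos(Z, Z′)`, all cross-species pairs.

### Exact bidirectionality

All computation inside `fit_joint` runs in a canonical order of the two
networks keyed by their content hashes, with every random stream seeded by
(master seed, stream name, network hash). `fit_joint(A, B)` and
`fit_joint(B, A)` therefore execute *identical arithmetic*, and their score
matrices are bit-exact transposes — bidirectionality is structural, not
approximate.

## Optimization

Everything is plain numpy with hand-written backpropagation (the
environment provides no deep-learning framework); gradients are validated
against central finite differences to 1e−4 relative error in the test
suite. The optimizer is Adam, lr 2e−3, minibatches of 16 rows (embedding)
or 16 anchors (alignment), gradient clipping off, divergence guard at 1e6.

Three optimization choices deserve justification because they differ from
an obvious default:

- **Batch size 16, not 128.** The number of gradient updates per epoch is
  `n / batch`. At real-data scale (n ≈ 15k) batch 128 gives ~120 updates
  per epoch; on a 300-vertex benchmark it gives 3, and ten blocks of 3
  steps cannot train the model. Batch 16 restores a per-epoch update count
  in the intended regime. Both are config.
- **No gradient clipping.** With Adam's per-coordinate normalization, a
  global-norm clip of 5 made every step direction-only and equalized the
  embedding and alignment step sizes, neutralizing φ; embeddings stayed
  near initialization (score SD ≈ 0.03). Clipping remains available in
  config but defaults off.
- **Separate Adam states per phase.** Cross gradients are on a much larger
  scale than embedding gradients. Sharing second-moment estimates across
  phases shrinks the embedding steps ~50× after the first alignment epoch;
  with separate states the planted-correspondence recovery on the shipped
  benchmark rose from median percentile ≈ 85 to ≈ 92–95.

L2 enters as an explicit penalty (not optimizer weight decay), scaled by
|batch|/n per step so one epoch applies it once in expectation.

## Preprocessing

Self-loops are dropped at parse time. Preprocessing then iterates to a
fixpoint: remove degree-0 vertices (the model input would be a zero row and
`D⁻¹` undefined), and collapse groups of vertices with identical neighbor
sets to one uniformly random seeded representative — with topology-only
input such vertices are indistinguishable, and which one is kept is
arbitrary by construction. The neighbor-set test excludes the vertex
itself, so two adjacent vertices with the same external neighbors also
collapse. Every removal is logged in a replayable report; anchors whose
genes were collapsed are dropped and logged. Anchor genes get no exemption
from collapsing.

## Evaluation stack

- **Co-annotation standard.** Biological-process GO annotations, restricted
  to low-throughput experimental evidence (EXP, IDA, IMP, IGI, IEP; IPI
  excluded to avoid circularity with PPI data), propagated through is_a /
  part_of. A slim set keeps terms with 10–100 annotated genes *in each
  species separately* (config; the union convention is also defensible),
  plus an optional curated list. A cross-species pair is positive iff the
  two genes share a slim term; unannotated genes are excluded rather than
  counted negative.
- **AUPRC over random** = log₂(AUPRC / prior), with AUPRC as
  step-interpolated average precision (scikit-learn's convention; the
  trapezoidal variant is not monotone-invariant). 0 is random, 1 is
  two-fold enrichment.
- **Top-k Jaccard** uses full annotation profiles, ranking pairs
  score-descending with a deterministic (score, idA, idB) tie-break,
  optionally after removing anchor pairs.
- **Gene-set matching.** For a term annotated in both species, the observed
  statistic is the mean of `S` over setA × setB, standardized against the
  global matrix mean (t-score with the block SD / √block-size). The z-score
  compares that t against 100 replicates drawn from 10 degree-quantile bins
  per species, matching set sizes. The exact background-connectivity
  correction of the original gene-set matching literature is not
  reconstructible from first principles here; this interpretation is
  config-overridable (bins, replicates) and calibrates to mean ≈ 0, SD ≈ 1
  on random sets (tested).
- **Gene-stratified folds.** Genes (not pairs) are assigned to folds;
  anchored orthologs are merged into connected components first, so an
  ortholog pair can never span folds; pairs whose genes land in different
  folds are excluded. A leakage audit in the SL evaluator raises if a test
  gene appears in training.
- **SL transfer.** Balanced standards subsample non-interacting pairs among
  genes that appear in ≥1 positive pair. Features are the sum of the two
  embedding rows (order-invariant); the classifier is an RBF-kernel SVM
  (C=1, kernel width by median heuristic on squared distances). Metrics are
  averaged over folds; per-fold decision scores are never pooled into one
  ranking because separately fitted SVMs are not on a common scale (pooling
  biased null AUROC to ≈ 0.39).
- **Top-percentile graph.** The ⌊p% · n·n′⌋ highest entries as a bipartite
  edge list, same tie-break, optional min-degree pruning for display.

## Synthetic world

The generator emulates the two-species setting without external downloads:

- A planted-partition **core** (default 300 genes, 3 modules, p_in=0.15,
  p_out=0.02 → mean degree ≈ 18, within-module degree ≈ 15) stands in for
  conserved pathway structure. Values chosen once: dense enough that a
  topology-only method has signal, modular because modules simultaneously
  support the alignment, co-annotation and SL tasks.
- Species A = core + 10% species-specific vertices (2 + Poisson(2) random
  attachments each); species B = relabeled core with each edge rewired with
  probability 5% (one endpoint redrawn, every rewire logged) + its own
  specific part. Anchors: a seeded half of the true map.
- Annotations: each term (default 30, sizes 10–100) draws 80% of its genes
  from one home module; membership mirrors across the true map except for
  5% label flips; a trivial two-level ontology (term → module parent →
  root) closes propagation.
- SL-like labels: within-module pairs as positives, mirrored across the
  true map; between-module negatives, balanced 1:1.

What a green test establishes: the full pipeline — preprocessing, NetMF,
training, alignment, scoring, every evaluator — recovers a *planted*
correspondence under controlled noise. What it does not establish: real
interactomes have heavy-tailed degrees, assortativity and ascertainment
bias that the planted-partition core does not reproduce (a
duplication-divergence-style generator is deliberately out of scope), and
real anchor sets carry paralog ambiguity. Benchmark numbers here are not
forecasts of performance on BioGRID-scale data.

## Numerical choices and degenerate inputs

- Cosine clamp 1e−8 in `L_1st`; zero-norm embedding rows raise with the
  vertex named.
- BCE is always computed in the stable logits form
  `max(x,0) − x·y + log1p(exp(−|x|))`.
- Min-max scaling of `M` to [0, 1] for BCE targets (binarization was
  evaluated and performed worse on held-out recovery).
- Constant score matrices make the gene-set z undefined; the result is
  flagged degenerate rather than raised.
- All rankings break ties by (−score, idA, idB) for bit-reproducible
  output.
- Determinism is promised on fixed hardware at one BLAS thread; the
  bidirectionality guarantee is thread-independent because both argument
  orders execute the same canonical computation.

## Known limitations

- No sparse/low-rank NetMF path: memory is O(n²).
- The alignment quality degrades gracefully but measurably with anchor
  noise; no robust-anchor weighting is implemented (BLAST-bitscore-weighted
  anchors are a known extension).
- Hyperparameter search is a plain seeded random-search hook over the
  published log-scale ranges (α in [1, 10³], others in [0.1, 10²]);
  Bayesian optimization is intentionally not included.
- Two species only; multi-species alignment is future work.
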