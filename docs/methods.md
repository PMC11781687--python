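# Methods

## Problem and model

`asgcl` predicts binary drug response (sensitive vs resistant) for cancer
cell-line/drug pairs.  Inputs are three omics layers per cell line (gene
expression, copy-number variation, somatic mutation), a binary molecular
fingerprint matrix per drug, and a partially observed response matrix
A ∈ {0,1}^{m×n}.  The model treats cell lines and drugs as the two sides of
a bipartite "sensitivity graph" whose edges are the observed sensitive
pairs, and learns node embeddings with three jointly optimized objectives.

### Feature subspace

Each entity gets a *linear* and a *nonlinear* representation in a shared
d-dimensional space, summed elementwise:

* linear: `LF = ω · diag(n) · X W`, where `n_i = 1/(deg_i + 1) + 1` is a
  degree-derived row normalization from the response matrix (entries in
  (1, 2]), `W` a learnable projection and `ω` a learnable scalar;
* nonlinear: one round of symmetric-normalized propagation
  `act(Â X W')` over an intra-entity similarity graph.  The similarity
  graph construction is not pinned down by the approach this reimplements,
  so the package uses Pearson top-k (k = 10 by default) symmetrized by max
  and binarized — the standard recipe for omics similarity networks — and
  exposes k.

The fused features of all m + n nodes form the node matrix of the
heterogeneous graph.  The subspace is trained *jointly* with the rest of
the model (one computational graph); nothing is precomputed except the
constant products `Â X`.

### GraphMorpher: adaptive augmentation

Per training iteration, two stochastic views of each graph are drawn:

* feature masking: per-dimension importance `M_N[i] = Σ_v |X[v,i]| F(v)`
  with F the eigenvector centrality; mask probability
  `P_i = min(ρ_N (M_max − M_i)/(M_max − μ), T_N)`; dimensions are zeroed
  across all nodes by independent Bernoulli draws;
* edge pruning: per-edge weight `M_L = log((F_i + F_j)/2 + ε)`, the same
  probability form with (ρ_L, T_L), one coin per undirected edge.

Defaults ρ_N = 0.2, ρ_L = 0.3, T_N = 0.3, T_L = 0.4.  Degenerate weights
(M_max = μ) yield probability 0 rather than NaN.  Centrality is computed
by power iteration (tolerance 1e-8, ≤ 10⁴ iterations, additive ε = 1e-12
for isolated nodes) on A + I: a bipartite adjacency has eigenvalues in ±
pairs, so the unshifted iteration oscillates, while the unit shift leaves
eigenvectors unchanged and makes the Perron eigenvalue strictly dominant.
The importance weights are interpreted per *feature dimension* for masking
and per *node* (centrality directly) for edge weights — the only reading
that types both formulas; node-wise masking is intentionally not offered.

The resistance graph is the complement of the sensitivity graph's
bipartite blocks (an involution; within-partition entries stay zero).

### Objectives

All three losses share one GCN encoder
`H = act(D̃^{-1/2}(A+I)D̃^{-1/2} X W)` with K = 1 and a leaky-rectifier
activation (slope 0.2):

* **supervised** — sigmoid inner-product scores for observed training
  pairs, mean binary cross-entropy, probabilities clipped at 1e-7;
* **node-level contrastive** — InfoNCE between the masked and the pruned
  view of the same graph; positives are the same node across views,
  negatives all other nodes in both views (k = i excluded from both
  negative sums, otherwise the positive would be double-counted); cosine
  similarity at temperature τ = 0.5 after a two-layer MLP projection head;
  the sensitivity- and resistance-side losses are averaged;
* **graph-level contrastive** — a deep-infomax style bilinear
  discriminator `σ(hᵀ W_V V)` against the sigmoid mean-pool summary of
  each graph; sensitivity-graph nodes are positives for their own summary,
  resistance-graph nodes negatives, and the direction is symmetrized with
  the resistance summary.

The printed contrastive objectives are agreement scores to be maximized;
the implemented losses are their negations, so the total
`α·sup + β·node + γ·graph` (α, β, γ = 0.4, 0.4, 0.2, validated to sum
to 1) is minimized by Adam at learning rate 5e-4.

Because no deep-learning framework is part of the dependency set, the
package ships a compact reverse-mode autodiff core (`asgcl._tensor`,
float64 numpy) with exactly the operations the model needs, plus an Adam
implementation; gradients are verified against finite differences in the
test suite.

## Evaluation protocol

Observed pairs are split by stratified k-fold CV (default k = 5).  Per
fold the sensitivity adjacency is rebuilt from *training positives only*;
labeled negatives and all held-out pairs never become edges (asserted at
runtime).  A 10% stratified carve-out of the training pairs drives early
stopping on validation AUC (defaults: patience 50 within 1000 epochs; the
epoch budget is not specified by the reference method, so early stopping
is the package's choice).  The decision threshold for confusion-based
metrics is 0.5.  AUC is the Mann-Whitney statistic with ties at 1/2; AP is
the step-wise precision-recall sum with stable tie-breaking; MCC is 0 when
a denominator factor vanishes; accuracy is the standard
(TP+TN)/(TP+TN+FP+FN).

Label binarization supports the two public-screen conventions.  The
per-drug threshold mode compares strictly (ties → resistant) and the
comparison direction is an explicit config field: `below` (low IC50 =
sensitive, the pharmacological convention, default) or `above`.  The
z-score mode standardizes log10(IC50) over all observed entries jointly
(population SD; per-drug scope by flag) and labels z < −0.8 sensitive.
The threshold table is assumed to be on the same scale as the response
table.

For unscreened pairs, `predict_missing_ranked` scores only unobserved
entries and ranks drugs by the median predicted sensitivity, highest
first.

## Synthetic data

The generator plants a recoverable low-rank structure: U (m×r) and V (n×r)
standard normal, `P(sensitive) = σ(s·⟨u_i, v_j⟩ + b)`, omics layers
`U P + noise` with independent random projections, fingerprints
`1[V P_d + noise > 0]`.  The standard fixture is m = 120, n = 40, r = 4,
s = 3, b = −1, noise SD 0.5, feature dims (200, 64), seed 7 — about 2,000
sensitive pairs at ~43% prevalence, trainable in seconds per fold on one
CPU.  It emulates table shapes and a planted association only; it does not
emulate real omics covariance, fingerprint chemistry, batch effects or the
heavy class imbalance of real screens, so passing tests demonstrate
correct mechanics and signal recovery, not clinical performance.

## Problem sizes and numerical choices

* Fixture-scale runs (`fixture_train_config`) use a 64-dim shared space,
  24-dim embeddings, up to 400 epochs with patience 50; the reference-scale
  defaults (224-dim shared space, hidden sizes 962→224→24) remain the
  config defaults for real-sized tables.
* All arithmetic is float64 and single-threaded deterministic: identical
  seeds reproduce fold splits, Bernoulli draws (per-epoch seeds are
  `seed + epoch`) and loss trajectories bitwise.
* Degenerate inputs: constant feature rows get similarity 0; an empty
  training graph triggers a warning, not an error; zero-variance response
  matrices cannot be z-scored and raise.

## Known limitations

* On the planted low-rank fixture the supervised signal alone is strong;
  the measured benefit of the contrastive terms and of moderate-vs-heavy
  augmentation is directionally positive at the evaluation seeds (0–4)
  but within seed-to-seed noise.  The fixture validates mechanics, not
  the size of the contrastive effect reported on real screens.
* The GAT encoder option is provided for completeness but is not covered
  by the end-to-end guarantees; GCN with K = 1 is the supported setting.
* Continuous IC50 regression is out of scope: the scoring head is the
  binary sigmoid inner-product classifier that the losses define.
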