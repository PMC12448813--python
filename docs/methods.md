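# Methods

`kglink` predicts unknown microbe–drug associations from two inputs: a
binary interaction matrix `A ∈ {0,1}^{M×N}` (microbes × drugs) whose ones
are validated associations, and a biomedical knowledge graph
`G = {(h, r, t)}` together with an alignment mapping every microbe and drug
to a KG entity. The model combines collaborative filtering (nodes that
share interaction partners behave alike) with relational context from the
KG, and is regularised by two contrastive objectives.

## Model

**Layered graph construction.** For every anchor node `u` (a microbe or a
drug) two layered structures are built.

* *Local graph*: the layer-0 entity set `E_u^0` contains the aligned
  entities of `u`'s direct interaction partners plus `u`'s own aligned
  entity (so isolated nodes still have a layer-0 representation). Layer
  `l ≥ 1` collects every KG triple whose head lies in `E_u^{l−1}`; the
  layer's entity set is the set of retained tails.
* *Non-local graph*: seeded instead by the aligned entities of `u`'s
  high-order partners — for a microbe, the drugs interacted with by
  microbes that share at least one drug with `u`, minus `u`'s own drugs
  (the drug side is the mirror image). The propagation rule is identical.

Propagation follows edge direction head → tail; a config flag
(`undirected`) adds explicit inverse relations at load time for graphs
that need reverse traversal. Because the number of triples per layer is
unbounded on dense graphs, each layer is uniformly subsampled without
replacement to a per-anchor, per-layer budget (default 64 triples),
seeded and deterministic. An empty frontier simply yields empty deeper
layers.

**Embeddings.** Entity and relation vectors (default dimension 64) are
pretrained with the translational model: `f(h,r,t) = ‖e_h + e_r − e_t‖`
is minimised on true triples and maximised on corrupted ones through the
margin hinge `Σ max(0, γ + f(pos) − f(neg))` (margin 1.0, L2 norm, one
negative per positive, entity renormalisation each epoch — canonical
settings for this model family). The pretrained table *initialises* the
trainable embeddings; it is not frozen. The pretraining learning curve
reported by `pretrain(..., return_history=True)` is the hinge loss on a
fixed, seeded corruption set evaluated after each epoch, which makes the
curve a deterministic measure of optimisation progress rather than a
noisy per-batch average.

**Layer encoding.** Each layer's triple set is encoded into one vector by
multi-head scaled dot-product attention. Per triple `i`, the concatenated
head and relation embeddings form the query `q_i = W_q [e_h ∥ e_r]`, and
the tail embedding forms key and value (`k_i = W_k e_t`, `v_i = W_v e_t`);
the per-head projections to dimension `d_h = dim / H` (default `H = 4`
heads) are learned jointly with the rest of the model — the query lives in
a `2·dim` space and the key in a `dim` space, so some projection is
required before a dot product is defined. Attention runs over all triples
of the layer as both queries and keys; the per-query head outputs are
mean-pooled over the query axis, heads are concatenated, and an output
projection `W_O` maps back to `dim`. This is the simplest set-to-vector
reduction consistent with aggregating tail-entity information, and it is
permutation-invariant by construction. Layer 0 (which has entities but no
triples) is encoded as the mean of its entity embeddings. Empty layers
encode to the zero vector so all anchors keep identical shapes. The
attention-free ablation (`no_att`) replaces attention with the unweighted
mean of tail embeddings.

**Prediction.** The final representation of a node is the concatenation of
its `L+1` local and `L+1` non-local layer vectors (`L = 3` by default,
giving `2·(L+1)·dim` dimensions), and the association score is
`ŷ_{m,d} = σ(e_m · e_d)`.

**Objectives.** Three terms:

1. *Supervised*: mean binary cross-entropy over the training positives and
   an equal number of uniformly sampled unknown pairs, resampled each
   epoch (computed on logits via the softplus identity for stability).
2. *Intra-graph contrastive*: within each context, InfoNCE with the
   layer-0 vector as anchor, the adjacent layer (layer 1) as positive and
   randomly sampled non-adjacent layers (`l ≥ 2`, one by default) as
   negatives; summed over microbes, drugs and both contexts.
3. *Inter-graph contrastive*: for every layer `k`, local layer `k` is the
   anchor, non-local layer `k` the positive, and the remaining non-local
   layers the negatives; summed over layers and nodes.

Similarity is the raw dot product scaled by temperature τ = 0.1. The total
loss is `L_pred + w_intra·L_intra + w_inter·L_inter` with default weights
1e-5 each. In mini-batch training the contrastive sums run over the
anchors present in the batch. The `no_intra` / `no_inter` ablations zero
the corresponding term.

**Training protocol.** Adam with learning rate 0.1 (an unusually large
value for Adam, but it is the protocol default and the config exposes it),
64 positive pairs per batch each matched with 64 sampled negatives, up to
200 epochs, early stopping when validation AUC fails to improve for 10
consecutive epochs, seed 42. The validation set is 10% of the training
positives plus an equal number of sampled unknown pairs; validation
positives are excluded from both the supervised loss and the interaction
matrix used for graph construction, so the early-stopping signal is a true
hold-out.

**Evaluation.** Balanced 5-fold cross-validation: known positives are
shuffled and partitioned into five test sets, each paired with an equal
number of unknown pairs sampled once per fold (fixed by seed). Each fold's
test positives are zeroed out of the interaction matrix before graph
construction and negative sampling — without this mask the test labels
leak into the collaborative-filtering seed sets. Metrics are AUC (tie-aware
trapezoidal ROC area, equal to the normalised Mann–Whitney statistic) and
AUPR with step-interpolated precision (right-constant between recall
steps), which avoids the optimism of trapezoidal PR interpolation.
Candidate ranking scores a query node against all counterparts, excludes
its known positives, and returns the top-k (default 20) with ties broken
by counterpart index.

## Synthetic benchmark

The generator plants a recoverable signal. Factors `U (M×r)`, `V (N×r)`
are standard normal with rank `r = 4`; entry `(i,j)` is Bernoulli with
probability `σ(s·U_i·V_j + b)`, signal scale `s = 2` (logit spread of
roughly ±4, a strongly separable but not deterministic signal, in line
with the near-separable curated association matrices the method targets),
and `b` solved by bisection so the expected density is exactly the target
(default 5%, matching the sparsity regime of curated microbe–drug
collections). The companion KG has one entity per microbe and drug plus
300 attribute entities carrying random unit latent directions; each node
links to the 6 attribute entities most aligned with its factor vector
(relation drawn uniformly from 5 types), emitted in both directions so
directed propagation can traverse node–attribute–node paths. A fraction
`attribute_noise` (default 0.1) of links is rewired uniformly; at 1.0 the
KG carries no signal, which the tests verify by mutual information against
a permuted control. The defaults (100 microbes × 200 drugs) are the
benchmark used throughout the test-suite.

What the benchmark does *not* emulate: real chemical structure or
taxonomy, heterogeneous relation semantics, hub-dominated degree
distributions, and systematic reporting bias in which pairs get tested.
Passing the recovery tests therefore shows that the implementation can
extract a planted low-rank + relational signal end-to-end, not that it
reproduces performance on curated datasets.

## Problem sizes and numerical choices

The recovery and ablation measurements run the full 5-fold protocol on the
default benchmark with embedding dimension 32, at most 30 epochs, and a
per-layer budget of 16 triples, in float32 — sizes chosen so the whole
evaluation runs on a single CPU core in minutes. The label-shuffled
control is evaluated on the first two folds per seed (its check is a mean
across seeds against the chance band). Training is pure numpy on a small
reverse-mode autodiff core written for this package; gradients are
unit-tested against central finite differences, and the batched training
forward is asserted equivalent (to 1e-9 in float64) to the per-anchor
reference implementations of the encoder and the contrastive losses.
TransE pretraining depends only on the KG, so cross-validation computes it
once and shares it across folds. Scores are clipped to logits in ±30
before the sigmoid so probabilities stay strictly inside (0, 1) in
float64; BCE clips probabilities at 1e-12. All randomness flows from
per-purpose `SeedSequence` streams, making every command reproducible
bit-for-bit under a fixed seed.

## Known limitations

* The printed learning rate (0.1 with Adam) makes embeddings move
  aggressively; early stopping usually halts training well before the
  epoch cap. Smaller rates may behave better on real data.
* Contrastive weights of 1e-5 make the self-supervised terms gentle
  regularisers; their measurable effect on the synthetic benchmark is
  small compared with seed-to-seed variation.
* Uniform negative sampling treats all unknown pairs as negative; on real
  data some "negatives" are untested positives.
* The per-layer triple budget trades variance for tractability on dense
  graphs; with very small budgets deep layers become noisy subsamples.
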