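# kglink

Knowledge-graph-augmented prediction of microbe–drug associations.

Antibiotic-resistance research needs to know which microbes respond to
which drugs, but validated microbe–drug associations are scarce and
imbalanced. `kglink` is for computational biologists who have (a) a binary
microbe × drug association matrix and (b) a biomedical knowledge graph
whose entities can be aligned with those microbes and drugs, and who want
ranked candidate associations with a properly cross-validated estimate of
ranking quality.

## Model

Given the adjacency matrix `A ∈ {0,1}^{M×N}` and a knowledge graph
`G = {(h, r, t)}`, the model learns a scoring function
`ŷ_{m,d} = σ(e_mᵀ e_d)` where each node representation concatenates
multi-layer embeddings from two per-node graphs:

* a **local graph** — layer 0 holds the KG entities of the node's direct
  interaction partners (first-order collaborative-filtering signal) plus
  the node's own entity; deeper layers follow KG triples head → tail;
* a **non-local graph** — seeded by high-order partners (drugs of
  microbes that share a drug with the anchor, and mirrored for drugs),
  propagated the same way.

Entity/relation embeddings are pretrained with the translational
objective `‖e_h + e_r − e_t‖ → 0` and refined end-to-end. Each layer's
triple set is encoded by multi-head scaled dot-product attention (query
`[e_h ∥ e_r]`, key/value `e_t`, per-head projections, query-mean pooling).
Training minimises

    L = L_BCE + w_intra · L_intra + w_inter · L_inter

where the contrastive terms are InfoNCE at temperature τ = 0.1: within a
graph, layer 0 contrasts against its adjacent layer (positives) versus
non-adjacent layers (negatives); across graphs, matching local/non-local
layers are positives and mismatched layers negatives. Evaluation is
balanced 5-fold cross-validation (held-out positives plus equally many
sampled unknown pairs; test positives are masked out of the matrix during
graph construction so no label leaks into the CF signals), reporting AUC
and AUPR.

No download is required: `kglink.synthetic` generates interaction matrices
with a planted low-rank logistic signal and knowledge graphs whose
attribute entities encode the same latent factors, so the whole pipeline
is testable and its signal-recovery behaviour measurable offline.

## Worked example

```python
from kglink import MicrobeDrugAssociationModel, ModelConfig, SyntheticSpec, make_benchmark
from kglink.transe import TransEConfig

kg, interactions, alignment, positives = make_benchmark(SyntheticSpec())
config = ModelConfig(embed_dim=32, max_epochs=30, layer_budget=16, seed=42,
                     transe=TransEConfig(dim=32, epochs=30))
model = MicrobeDrugAssociationModel(kg, interactions, alignment, config)

cv = model.cross_validate()
print(cv.summary())

results = model.fit()
for p in results.rank_candidates("m0", k=3):
    print(interactions.microbe_labels[p.microbe],
          interactions.drug_labels[p.drug], round(p.score, 3))
```

prints

```
Balanced 5-fold cross-validation
========================================
fold       AUC      AUPR
   0    0.8474    0.8546
   1    0.8602    0.8488
   2    0.8461    0.8432
   3    0.8464    0.8457
   4    0.8733    0.8822
mean    0.8547    0.8549
m0 d4 0.649
m0 d74 0.575
m0 d11 0.567
```

The CV table shows per-fold and mean AUC/AUPR of the balanced 5-fold
protocol on the synthetic benchmark (1005 planted positives among 20 000
pairs): a mean AUC of 0.855 means the model ranks a held-out true
association above a random unknown pair about 85% of the time. The ranked
list contains the strongest novel candidates for microbe `m0` — drugs not
already linked to it in the training data, ordered by predicted
association probability.

The same pipeline is scriptable from the shell:

```bash
kglink simulate --out-dir data --seed 42
kglink cv       --kg data/kg.tsv --interactions data/interactions.tsv \
                --alignment data/alignment.tsv --out-dir runs/cv --seed 42
kglink train    --kg data/kg.tsv --interactions data/interactions.tsv \
                --alignment data/alignment.tsv --out-dir runs/state --seed 42
kglink predict  --state-dir runs/state --query m0 -k 20 --out-dir runs/top20
```

Every command writes a `manifest.json` with the config snapshot, input
digests, seed and wall times; reruns with the same seed reproduce
byte-identical outputs.

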