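# pcfkit

Predicting the **product carbon footprint (PCF)** of organic chemicals —
cradle-to-gate greenhouse-gas emissions in kg CO₂-equivalents per kg of
product — directly from molecular structure.

Measured PCF data exist for only a few hundred chemicals, locked inside
licensed life-cycle databases and confidential industry records, while
hundreds of thousands of chemicals are on the market. Structure-based
prediction fills that gap at the early design stage, when no process data
exist yet. `pcfkit` is a toolkit for that workflow, aimed at LCA
practitioners and cheminformaticians:

- **datakit** — curation of SMILES/PCF tables (purity, metals, mixtures,
  polymers, inorganics), duplicate averaging, Murcko-scaffold analysis, and
  seeded random/scaffold 80/10/10 splits.
- **abt_model** — an *atom-bond transformer* regressor: directed-bond
  message passing, multi-head self-attention over bonds (encoder), atom
  aggregation, atom self-attention biased by interatomic matrices (decoder),
  mean pooling, fusion with ~200 molecular descriptors, feed-forward head.
- **baselines** — the nine classical references,
  {ANN, RF, SVM} × {MACCS, RDKit-path, ECFP4} fingerprints, tuned by 5-fold
  grid search.
- **hyperopt** — Gaussian-process Bayesian optimization of the four model
  hyperparameters over their discrete lattices.
- **adomain** — applicability domain: a query is in-domain when its mean
  Euclidean ECFP4 distance to its k = 5 nearest training molecules is at
  most T = Ȳ + Z·σ (Z = 0.5) fitted on the training set.
- **interpret** — attention-based attribution: decoder attention collapsed
  to per-atom weights, aggregated over substructures, rendered as shaded
  2-D depictions.
- **synthdata** — synthetic benchmark datasets whose targets follow a known
  additive group-contribution model, so learnability and attribution can be
  tested against ground truth without licensed data.

## The model

A molecule is a graph G = (V, E). Each directed bond (i→j) starts from

    h⁰_ij = ReLU(W_in · [x_i ‖ e_ij])

and is refined for T rounds of message passing

    hᵗ⁺¹_ij = ReLU(h⁰_ij + W_m · Σ_{k ∈ N(i)\j} hᵗ_ki),

then passes a transformer encoder block (6-head self-attention + FFN, each
sublayer with residual connection and layer normalization). Atom states are
the sums of incoming bond states plus a projection of the raw atom features.
A decoder block applies atom self-attention whose pre-softmax logits carry
the additive bias

    λ · (A + s(D) + s(C)),

where A, D, C are the adjacency, topological-distance and Coulomb matrices,
s is per-molecule min–max scaling, and λ is the tunable interatomic scaler.
The mean-pooled atom states are concatenated with standardized molecular
descriptors and mapped to the scalar PCF by a feed-forward head. Training
minimizes mean-squared error with Adam and keeps the weights of the epoch
with the lowest validation RMSE. The four tuned hyperparameters are the
message-passing depth T ∈ [1,10], λ ∈ [0,0.5], dropout ∈ [0,0.5], and the
hidden width ∈ {100,150,…,3000}.

The network runs on a small NumPy reverse-mode autodiff core
(`pcfkit._autodiff`), so the package needs no deep-learning framework.

## Worked example

```python
import numpy as np
from pcfkit import datakit, synthdata
from pcfkit.abt_model import ModelConfig, train
from pcfkit.evaluate import rmse

gen = synthdata.SynthConfig(n_molecules=600, noise_sd=0.3, seed=0)
raw, truth = synthdata.make_dataset(gen)
ds = datakit.merge_duplicates(datakit.curate(raw.records).dataset)
print(len(ds), datakit.count_unique_scaffolds(ds))
# 334 8        <- unique chemicals and Murcko scaffolds after curation

tr, va, te = datakit.split(ds, datakit.SplitSpec(seed=0))
model = train(tr, va, ModelConfig(hidden_dim=200, mp_iterations=3,
                                  epochs=40, patience=12, seed=0))
preds = model.predict_many(te.smiles)
print(round(rmse(te.targets, preds), 3))
# 0.354        <- held-out RMSE, close to the injected noise floor (0.3)
```

The held-out RMSE of 0.354 kg CO₂-equiv/kg means the transformer has
recovered the additive substructure contributions almost down to the
irreducible noise injected by the generator; predicting the training mean
instead gives 2.10. The same pipeline applies unchanged to a real curated
`smiles,pcf` table.

The command-line interface mirrors the library
(`pcfkit synth | curate | split | train | tune | predict | benchmark |
ad-fit | ad-screen | attribute`); every command writes a JSON run manifest
beside its output.

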