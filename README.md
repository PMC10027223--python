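# combosyn

Predicting the synergy of drug combinations across cancer cell lines from
multi-channel graph-autoencoder embeddings.

## The problem

High-throughput combination screens measure, for many (drug A, drug B,
cell line) triples, a synergy score — the departure of the observed combined
effect from a non-interaction reference (Loewe additivity, Bliss
independence, ZIP or HSA). Screens cover only a small corner of the
combinatorial space, so computational models are used to rank untested
combinations. Synergy is strongly context-dependent: the same pair can be
synergistic in one cell line and antagonistic in another, yet combination
behaviour is also partly conserved across cellular contexts. `combosyn`
models both sides of that split explicitly.

## The model

Per synergy type, scores are classed by literature cutoffs — {0, 30} for
Loewe, {−3.37, 3.68} for Bliss, {−3.02, 3.87} for HSA, {−4.48, 2.64} for
ZIP; strictly above the upper cutoff is *synergistic*, strictly below the
lower cutoff *antagonistic*, otherwise *additive*. The combinations measured
in cell line *r* then form three undirected graphs over a global drug index
with adjacency matrices A<sub>r|t</sub>, t ∈ {syn, add, ant}.

A relational graph encoder updates drug embeddings per cell line,

```
h_i^(l+1) = ReLU( Σ_t Σ_{j∈N_{i,r|t}} (α_{r|t}/|N_{i,r|t}|) W_{r|t}^(l) h_j^(l)
                  + W_{0,r}^(l) h_i^(l) ),        h_i^(0) = fingerprint(i)
```

with learnable channel attentions α<sub>r|t</sub>; a layer attention
β<sub>r</sub><sup>(l)</sup> fuses layers 1..L into the **cell-line-specific
embedding** h<sup>spe</sup><sub>i,r</sub>, and a cell-line attention
α<sub>r</sub> fuses those across cell lines into the **cell-line-common
embedding** h<sup>com</sup><sub>i</sub> = Σ<sub>r</sub> α<sub>r</sub>
h<sup>spe</sup><sub>i,r</sub>. Bilinear decoders

```
Â_{r|t}(i,j) = σ( h_i D_{r|t} W_r D_{r|t} h_jᵀ )
```

reconstruct each channel from the specific embeddings, and a second family
of decoders (shared W, per-cell-line diagonals) reconstructs every cell
line's graphs from the common embeddings. All parameters are trained
jointly with Adam on the summed masked mean-squared reconstruction error
over the measured pairs (Loss = Loss<sup>com</sup> + Σ<sub>r</sub>
Loss<sup>spe</sup><sub>r</sub>). A three-hidden-layer network with batch
normalization then predicts synergy scores (or the synergistic class) from
the concatenation of both drugs' fingerprints, specific and common
embeddings, plus cell-line features; predictions are averaged over both
drug orderings, making them exactly symmetric.

Because no deep-learning framework is assumed, the models run on a small
reverse-mode autodiff tape over numpy (`combosyn._autodiff`); gradients are
verified against finite differences in the test suite.

## Worked example

```python
from combosyn import (SimConfig, generate_dataset, featurize_drugs,
                      MultiChannelGraphAutoencoder, stratified_kfold,
                      run_cross_validation)
from combosyn.simulate import generate_cell_features

cfg = SimConfig(n_drugs=32, n_cell_lines=4, seed=0)   # planted low-rank truth
dataset, truth = generate_dataset(cfg)
fingerprints = featurize_drugs(None, dataset.drugs, n_bits=64, seed=0)

model = MultiChannelGraphAutoencoder(embedding_dim=16, epochs=300,
                                     learning_rate=5e-3, seed=0)
model.fit(dataset, fingerprints)

plan = stratified_kfold(dataset, k=3, seed=0)
report = run_cross_validation(
    dataset, plan, fingerprints, generate_cell_features(cfg, width=16),
    embed_config={"embedding_dim": 16, "epochs": 500, "learning_rate": 5e-3,
                  "weight_decay": 5e-4, "seed": 0},
    predictor_config={"hidden_sizes": (128, 64, 32), "epochs": 120, "seed": 0})
```

Output:

```
1984 records, 32 drugs, 4 cell lines
total loss 5.999 -> 2.992
specific embeddings: 4 x (32, 16), common: (32, 16)
pooled RMSE 28.50  PCC 0.520
```

The simulated panel draws scores on the Loewe scale (class thresholds 0 and
30), so an RMSE of 28.5 with pooled Pearson correlation 0.52 means the
3-fold stratified cross-validation recovers about half of the planted
signal's ordering from graphs and embeddings alone — on a panel two orders
of magnitude smaller than a real screen.

The same pipeline is scriptable from the shell:

```sh
combosyn simulate --out data/ --n-drugs 16 --n-cell-lines 3 --seed 0
combosyn train    --data data/ --out run/ --channels all --features all
combosyn evaluate --data data/ --out eval/ --strategy stratified --k 10
combosyn predict  --data data/ --model run/ --pairs pairs.csv --out preds.csv
```

Four cross-validation protocols are built in: stratified k-fold,
leave-one-drug-out, leave-one-cell-line-out and leave-drug-pairs-out (a
cell line never seen in training has no specific embeddings; the common
embeddings substitute for them). Ablation switches mirror the model's
variants: `--channels {syn,syn+add,syn+ant,all}` controls which graph
channels feed the encoder, `--features {fin,spe,com,all}` which feature
blocks feed the predictor.

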