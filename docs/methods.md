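# Methods

## Data model

A synergy dataset is a set of (drug_a, drug_b, cell_line, score) records
with an unordered, self-pair-free drug pair per record and at most one
record per (pair, cell line). Scores live on one of four scales (Loewe,
Bliss, ZIP, HSA) and are classed by fixed cutoffs — {0, 30}, {−3.37, 3.68},
{−4.48, 2.64}, {−3.02, 3.87} respectively — with strict inequalities:
scores exactly at a cutoff are additive. Duplicate measurements of a triple
are an error by default; an opt-in flag mean-aggregates them.

Per cell line the records become three binary, symmetric, zero-diagonal
adjacency matrices over the global (lexicographically ordered) drug index,
one per class. Exactly one channel carries a 1 for every measured pair;
unmeasured pairs are 0 in all three. During cross-validation the graphs
are built from training records only, so held-out labels cannot leak into
the encoder input.

Drug features are hashed circular (Morgan) fingerprints, radius 2, 256 bits
by default (configurable), computed with RDKit from SMILES. Datasets
without structures use seeded random binary rows instead — the graphs, not
the chemistry, carry the combination signal, and random near-orthogonal
rows act as node identifiers.

## Embedding model

The encoder treats the three class graphs of a cell line as a relational
graph. Layer update for drug *i* in cell line *r*:

    h_i^(l+1) = ReLU( Σ_t Σ_{j ∈ N_{i,r|t}} (α_{r|t} / |N_{i,r|t}|) W_{r|t}^(l) h_j^(l)
                      + W_{0,r}^(l) h_i^(l) )

Neighbour sums are degree-normalized per channel; drugs with no neighbours
in a channel receive no contribution from it (no division by zero), and a
fully isolated drug is encoded by the self-weight chain alone. The first
layer maps the fingerprint width d₀ to the embedding width d; later layers
are d→d. Layer outputs 1..L are fused by a per-cell-line layer attention
(the layer-0 fingerprint is not part of the fusion; it re-enters the
predictor separately). Cell-line-specific embeddings are fused across cell
lines by a cell-line attention into the common embeddings.

Decoding is bilinear with a per-channel diagonal: score(i,j) =
σ(h_i D W D h_jᵀ). Since this form is not symmetric for general W while
adjacency is, the decoded score is the mean over both orderings. The
specific pathway uses one W_r per cell line with channel diagonals D_{r|t};
the common pathway uses one global W with its own per-cell-line channel
diagonals — the two decoder families share no parameters.

The reconstruction loss for a cell line scores **every measured pair
against each channel's 0/1 target**: a pair is a positive for its own class
channel and a negative for the other two, and unmeasured pairs carry no
loss. Taking the support to be only each channel's own edges would make a
constant-1 decoder optimal; the chosen support is the smallest
non-degenerate alternative that uses observed data only (no negative
sampling). Each channel term is normalized by the number of measured pairs
of that cell line. The training objective is the common-pathway loss plus
the sum of per-cell-line specific losses, optimized jointly.

Attention scalars (channel, layer, cell line) are free trainable
parameters initialized at uniform averages (1/#channels, 1/L, 1/R); an
optional flag replaces them by softmax-normalized weights. All weight
matrices and diagonals are Xavier-uniform initialized; training is
full-batch Adam. An optional L2 penalty (`weight_decay`) on weights and
diagonals — attentions exempt — counters edge memorization on small dense
graphs; it is off by default and enabled in the structure-recovery
benchmark (5e-4).

Defaults: d = 128, L = 3, learning rate 1e-3, 500 epochs, seed 42. The
benchmarks and tests run smaller widths (d = 8–32) and adjusted learning
rates, chosen as reasonable for panels of tens of drugs; all are exposed.

Both the autoencoder and the predictor run on an in-package reverse-mode
autodiff tape over numpy float64 (`combosyn._autodiff`). The tape supports
exactly the primitives the models need, and its gradients — and the joint
objective's gradients — are tested against central finite differences.

## Predictor

Input per ordered triple: [fp(a) | h_spe(a,r) | h_com(a) | fp(b) |
h_spe(b,r) | h_com(b) | cell(r)], total width 2(d₀+2d)+c. Feature blocks
are maskable for ablations (fingerprints only / + specific / + common /
all); cell-line feature columns are z-scored with training-set statistics,
while binary fingerprints and learned embeddings pass through unscaled.

The network has three hidden layers (default 2048/1024/512) with batch
normalization, ReLU and dropout 0.5, a linear output trained with MSE for
regression or a sigmoid output with binary cross-entropy for
synergistic-vs-rest classification (positives = synergistic class;
probability threshold 0.5). Training inserts each pair in both drug
orderings; prediction averages the two orderings, so predictions are
exactly order-invariant. A 10% validation split with patience-20 early
stopping (best weights restored) is on by default and can be disabled for
exact-epoch runs. Batch normalization needs ≥ 2 rows, so stray size-1
batches are skipped during training and inference always uses running
statistics.

For a cell line absent from embedding training (leave-one-cell-line-out)
the common embeddings substitute for the missing specific block, flagged in
the API.

## Evaluation protocols and metrics

* **Stratified k-fold** — within each cell line, each of the three classes
  is shuffled and dealt round-robin into k subsets; fold f's test set
  concatenates subset f of every stratum, so per-stratum test counts differ
  by at most one. Strata smaller than k warn and still deal round-robin.
* **Leave-one-drug-out** — one fold per drug; all records containing it are
  test (each record therefore appears in two drugs' test folds).
* **Leave-one-cell-line-out** — one fold per cell line.
* **Leave-drug-pairs-out** — unordered pairs are split into k groups; a
  fold's pairs are held out across all cell lines.

Regression metrics: MSE, RMSE, Pearson correlation, and a 95% confidence
interval of the MSE across folds using the t-distribution on fold MSEs
(configurable to a normal approximation; the interval construction is a
package choice). Classification: AUC, AUPR, accuracy, F1, Cohen's kappa,
via scikit-learn. Degenerate cases (zero variance, single-class truth)
report NaN with a warning rather than failing. Cross-validation reports
per-fold metrics, their mean ± sd, pooled metrics over concatenated test
predictions, and an optional per-cell-line table; a failing fold is logged
and marked incomplete instead of aborting the run.

## Synthetic data generator

Each drug carries a common latent u_i ~ N(0, I_q) and per-cell-line latents
v_{i,r} ~ N(0, I_q); the noiseless signal of a pair is the convex mix
share·⟨u_i,u_j⟩ + (1−share)·⟨v_{i,r},v_{j,r}⟩. Scores are scale·signal +
Gaussian noise, where the noise sd is a stated fraction of the scaled
signal sd (default 0.5) and the scale starts at (high−low)/sd(signal) and
is rescaled geometrically (up to 100 attempts) until all three classes are
populated — failure raises with advice. A density parameter subsamples the
unordered pairs observed per cell line. Defaults: 16 drugs, 3 cell lines,
rank 3, share 0.5, full density, Loewe thresholds.

Dot-product latents were chosen because the bilinear decoders are exactly
this model class at the share extremes while remaining model-agnostic in
between. Cell-line feature rows are a fixed random linear projection of the
effective latent field share·u + (1−share)·v_r, so cell lines with
identical structure get identical features. Structures come from a
deterministic ≥200-entry list of simple valid SMILES (substituted linear
chains) — syntactically valid chemistry for exercising fingerprints, with
no pretense of drug-likeness.

What the generator does *not* emulate: dose–response surfaces and the
derivation of the four synergy formulas from viability data, realistic
chemical similarity structure, assay noise heteroscedasticity, and the
exact class imbalance of specific public screens (the threshold mechanism
reproduces imbalance qualitatively). Passing benchmarks therefore show the
pipeline recovers planted bilinear structure under noise and partial
observation — not field performance on screen data.

## Benchmarks (scripts/acceptance.py)

* **Loss reduction** — 12 drugs × 3 cell lines, d=16, 300 epochs: the joint
  objective falls by well over half from initialization with a finite trace.
* **Structure recovery** — 80 drugs × 8 cell lines (an O'Neil-scale drug
  count with a reduced panel), generator defaults, one stratified 20% fold
  of pairs per cell line held out; d=32, 1000 epochs, lr 5e-3, weight decay
  5e-4. The trained synergistic-channel decoder ranks held-out synergistic
  vs non-synergistic pairs at AUC ≈ 0.8 across seeds; an untrained model
  sits at chance. Graph sizes here were set so that both in-cell-line and
  cross-cell-line information are non-trivial; with very small panels the
  binarized labels carry too little signal for any method.
* **Shared-structure contrast** — 16 drugs × 6 cell lines, d=8, 500 epochs,
  matched configs: converged common-pathway loss is consistently lower at
  share=1 than share=0, confirming the common pathway captures exactly the
  cross-cell-line component.
* **Pipeline cross-validation** — 32 drugs × 4 cell lines, stratified
  3-fold, both tasks, reporting pooled RMSE/PCC and AUC/AUPR.

## Known limitations

Full-batch training over dense N×N decodes is O(R·N²·d) per epoch —
appropriate for panels up to a few hundred drugs, not for mini-batched
training at larger scales. The autodiff tape is deliberately minimal (no
broadcasting beyond what the models use, no GPU). Attention scalars are
unconstrained by default and can go negative; the softmax flag trades that
freedom for interpretability. Replicate handling (mean aggregation) and the
common-for-specific substitution in leave-one-cell-line-out are pragmatic
choices where screen-processing conventions vary.
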