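"""Downstream synergy predictor: feature assembly and a 3-hidden-layer network.

Each (drug_a, drug_b, cell_line) triple is represented by the concatenation

    [ fp(a) | h_spe(a, r) | h_com(a) | fp(b) | h_spe(b, r) | h_com(b) | cell(r) ]

of the drugs' molecular fingerprints, cell-line-specific embeddings and
cell-line-common embeddings, followed by the cell line's feature vector
(length 2*(d0 + 2d) + c in total). The network has three hidden layers with
batch normalization, ReLU and dropout; a linear output trained with MSE for
score regression, or a sigmoid output with binary cross-entropy for
synergistic-vs-rest classification.

The feature blocks are maskable for ablations: ``fin`` keeps fingerprints
only, ``spe`` adds specific embeddings, ``com`` adds common embeddings,
``all`` keeps everything. Because synergy is symmetric in the two drugs,
every training pair is inserted in both drug orderings and a prediction is
the mean over both orderings, which makes predictions exactly
order-invariant.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._autodiff import Adam, Tensor, xavier_uniform
from .data import FingerprintMatrix, SynergyDataset
from .embedding import EmbeddingSet

__all__ = ["FEATURE_MASKS", "feature_width", "assemble_features",
           "FeatureAssembler", "SynergyPredictor", "train_predictor"]

#: Feature-block masks for the ablation variants; all include fingerprints.
FEATURE_MASKS = {
    "fin": frozenset({"fin"}),
    "spe": frozenset({"fin", "spe"}),
    "com": frozenset({"fin", "com"}),
    "all": frozenset({"fin", "spe", "com"}),
}


def _resolve_mask(mask) -> frozenset:
    if isinstance(mask, str):
        try:
            return FEATURE_MASKS[mask]
        except KeyError:
            raise ValueError(f"unknown feature mask {mask!r}; "
                             f"choose from {sorted(FEATURE_MASKS)}") from None
    return frozenset(mask)


def feature_width(d0: int, d: int, c: int, mask="all") -> int:
    """Total feature length: per drug the unmasked blocks, plus cell features."""
    mask = _resolve_mask(mask)
    per_drug = (d0 if "fin" in mask else 0) \
        + (d if "spe" in mask else 0) + (d if "com" in mask else 0)
    return 2 * per_drug + c


def assemble_features(pair, embeddings: EmbeddingSet,
                      fingerprints: FingerprintMatrix,
                      cell_features: dict[str, np.ndarray],
                      drug_index: dict[str, int], mask="all") -> np.ndarray:
    """Concatenated feature vector for one ordered (drug_a, drug_b, cell_line)."""
    mask = _resolve_mask(mask)
    drug_a, drug_b, cell = pair
    for d in (drug_a, drug_b):
        if d not in drug_index:
            raise KeyError(f"unknown drug: {d!r}")
    if cell not in cell_features:
        raise KeyError(f"unknown cell line: {cell!r}")
    H_spe, _ = embeddings.specific_or_common(cell)
    blocks = []
    for d in (drug_a, drug_b):
        i = drug_index[d]
        if "fin" in mask:
            blocks.append(fingerprints.F[i])
        if "spe" in mask:
            blocks.append(H_spe[i])
        if "com" in mask:
            blocks.append(embeddings.common[i])
    blocks.append(cell_features[cell])
    return np.concatenate(blocks)


class FeatureAssembler:
    """Builds feature matrices for record sets; z-scores cell features on fit.

    Cell-line feature columns are standardized with statistics from the
    training cell lines; fingerprints and embeddings are binary/learned and
    pass through unscaled.
    """

    def __init__(self, embeddings: EmbeddingSet, fingerprints: FingerprintMatrix,
                 cell_features: "dict[str, np.ndarray] | None", mask="all"):
        self.embeddings = embeddings
        self.fingerprints = fingerprints
        self.raw_cell_features = cell_features or {}
        self.mask = _resolve_mask(mask)
        self._mu = self._sd = None

    def fit(self, train_cell_lines) -> "FeatureAssembler":
        if self.raw_cell_features:
            rows = np.array([self.raw_cell_features[c] for c in train_cell_lines
                             if c in self.raw_cell_features])
            self._mu = rows.mean(axis=0)
            sd = rows.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        return self

    def _cell_vector(self, cell: str) -> np.ndarray:
        if not self.raw_cell_features:
            return np.zeros(0)
        v = self.raw_cell_features[cell]
        if self._mu is not None:
            v = (v - self._mu) / self._sd
        return v

    def transform_pairs(self, pairs, dataset: SynergyDataset,
                        both_orders: bool = True) -> np.ndarray:
        """Feature matrix for ordered triples; optionally both orderings stacked.

        With ``both_orders`` the output has 2 * len(pairs) rows: the given
        ordering first, then all swapped orderings.
        """
        cell_features = {c: self._cell_vector(c)
                         for c in {p[2] for p in pairs}}
        rows = [assemble_features(p, self.embeddings, self.fingerprints,
                                  cell_features, dataset.drug_index, self.mask)
                for p in pairs]
        if both_orders:
            rows += [assemble_features((b, a, c), self.embeddings,
                                       self.fingerprints, cell_features,
                                       dataset.drug_index, self.mask)
                     for a, b, c in pairs]
        return np.array(rows)


class SynergyPredictor(BaseEstimator, RegressorMixin):
    """Three-hidden-layer network with batch normalization and dropout.

    ``task="regression"`` trains with MSE on a linear output;
    ``task="classification"`` with binary cross-entropy on a sigmoid output.
    A 10% validation split with patience-based early stopping is on by
    default (``early_stopping=False`` runs the exact epoch count).
    """

    def __init__(self, hidden_sizes=(2048, 1024, 512), dropout: float = 0.5,
                 learning_rate: float = 1e-3, epochs: int = 200,
                 batch_size: int = 128, seed: int = 42,
                 task: str = "regression", early_stopping: bool = True,
                 validation_fraction: float = 0.1, patience: int = 20):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.task = task
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience

    # -- internals ------------------------------------------------------------
    def _init(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.hidden_sizes, 1]
        P = {}
        for i in range(len(sizes) - 1):
            P[f"W{i}"] = Tensor(xavier_uniform((sizes[i], sizes[i + 1]), rng),
                                requires_grad=True)
            P[f"b{i}"] = Tensor(np.zeros(sizes[i + 1]), requires_grad=True)
            if i < len(self.hidden_sizes):   # batch norm on hidden layers only
                P[f"g{i}"] = Tensor(np.ones(sizes[i + 1]), requires_grad=True)
                P[f"be{i}"] = Tensor(np.zeros(sizes[i + 1]), requires_grad=True)
        self._running = {f"m{i}": np.zeros(sizes[i + 1]) for i in range(len(self.hidden_sizes))}
        self._running.update({f"v{i}": np.ones(sizes[i + 1]) for i in range(len(self.hidden_sizes))})
        return P

    def _forward(self, P, X: Tensor, train: bool, rng=None) -> Tensor:
        eps = 1e-5
        h = X
        n_hidden = len(self.hidden_sizes)
        for i in range(n_hidden):
            z = h @ P[f"W{i}"] + P[f"b{i}"]
            if train and z.shape[0] > 1:
                mu = z.mean(axis=0, keepdims=True)
                var = ((z - mu) ** 2).mean(axis=0, keepdims=True)
                self._running[f"m{i}"] = (0.9 * self._running[f"m{i}"]
                                          + 0.1 * mu.data.ravel())
                self._running[f"v{i}"] = (0.9 * self._running[f"v{i}"]
                                          + 0.1 * var.data.ravel())
                zhat = (z - mu) * ((var + eps) ** -0.5)
            else:
                zhat = ((z - self._running[f"m{i}"])
                        * ((Tensor(self._running[f"v{i}"]) + eps) ** -0.5))
            z = zhat * P[f"g{i}"] + P[f"be{i}"]
            h = z.relu()
            if train and self.dropout > 0:
                keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * Tensor(keep)
        out = h @ P[f"W{n_hidden}"] + P[f"b{n_hidden}"]
        return out

    def _loss(self, pred: Tensor, y: np.ndarray) -> Tensor:
        yt = Tensor(y.reshape(-1, 1))
        if self.task == "classification":
            p = pred.sigmoid()
            eps = 1e-9
            return -(yt * (p + eps).log()
                     + (1.0 - yt) * (1.0 - p + eps).log()).mean()
        return ((pred - yt) ** 2).mean()

    # -- API ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature and target row counts differ")
        rng = np.random.default_rng(self.seed)
        P = self._init(X.shape[1], rng)
        opt = Adam(P.values(), lr=self.learning_rate)

        idx = rng.permutation(X.shape[0])
        if self.early_stopping and X.shape[0] >= 10:
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
        else:
            val_idx, tr_idx = np.array([], dtype=int), idx
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        self.loss_trace_ = []
        best_val, best_state, stale = np.inf, None, 0
        for epoch in range(self.epochs):
            order = rng.permutation(Xtr.shape[0])
            epoch_loss, nb = 0.0, 0
            for start in range(0, Xtr.shape[0], self.batch_size):
                batch = order[start:start + self.batch_size]
                if batch.size < 2 and Xtr.shape[0] > 2:
                    continue  # batch norm needs >= 2 rows
                opt.zero_grad()
                pred = self._forward(P, Tensor(Xtr[batch]), train=True, rng=rng)
                loss = self._loss(pred, ytr[batch])
                val = float(loss.data)
                if not np.isfinite(val):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                loss.backward()
                opt.step()
                epoch_loss += val
                nb += 1
            self.loss_trace_.append(epoch_loss / max(nb, 1))
            if val_idx.size:
                vpred = self._forward(P, Tensor(Xval), train=False)
                vloss = float(self._loss(vpred, yval).data)
                if vloss < best_val - 1e-9:
                    best_val, stale = vloss, 0
                    best_state = ({k: v.data.copy() for k, v in P.items()},
                                  {k: v.copy() for k, v in self._running.items()})
                else:
                    stale += 1
                    if stale > self.patience:
                        break
        if best_state is not None:
            for k, v in best_state[0].items():
                P[k].data = v
            self._running = best_state[1]
        self.params_ = P
        self.n_features_in_ = X.shape[1]
        return self

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        out = self._forward(self.params_, Tensor(X), train=False)
        return out.data.ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores (regression) or synergistic-class probabilities (classification)."""
        raw = self._raw_predict(X)
        if self.task == "classification":
            return 1.0 / (1.0 + np.exp(-np.clip(raw, -60, 60)))
        return raw

    def predict_pairs(self, X_both_orders: np.ndarray) -> np.ndarray:
        """Order-invariant predictions from a both-orderings feature matrix.

        Expects the layout produced by ``FeatureAssembler.transform_pairs``
        (first all pairs in the given order, then all swapped); returns the
        per-pair mean of the two orderings.
        """
        if X_both_orders.shape[0] % 2:
            raise ValueError("both-orderings matrix must have an even row count")
        half = X_both_orders.shape[0] // 2
        p = self.predict(X_both_orders)
        return 0.5 * (p[:half] + p[half:])


def train_predictor(train_features: np.ndarray, train_targets: np.ndarray,
                    **config) -> SynergyPredictor:
    """Functional wrapper: fit a :class:`SynergyPredictor`."""
    return SynergyPredictor(**config).fit(train_features, train_targets)
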