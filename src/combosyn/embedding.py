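"""Multi-channel graph autoencoder for cell-line-specific and -common drug embeddings.

Per cell line the three class graphs (synergistic / additive / antagonistic)
are treated as a relational graph. A relational-GCN-style encoder updates
drug embeddings layer by layer,

    h_i^{(l+1)} = ReLU( sum_t sum_{j in N_{i,t}} (alpha_t / |N_{i,t}|) W_t^{(l)} h_j^{(l)}
                        + W_0^{(l)} h_i^{(l)} ),

with a learnable per-channel attention ``alpha_t`` ("specific attention").
A layer attention ``beta^{(l)}`` fuses layers 1..L into the cell-line-specific
embedding h^spe. A cell-line attention ("common attention") fuses specific
embeddings across cell lines into the common embedding h^com. Bilinear
decoders sigmoid(h_i D W D h_j^T) reconstruct each channel, once per cell
line from the specific embeddings (decoder parameters W_r, D_{r|t}) and once
from the common embeddings (shared W, per-cell-line D'_{r|t}); the training
objective sums masked mean-squared reconstruction errors over the measured
pairs of every cell line plus the common pathway.

All parameters are trained jointly with Adam from Xavier-uniform
initialization; attentions start at uniform averages and are free scalars
(an optional flag applies a softmax normalization instead).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Adam, Tensor, xavier_uniform
from .data import CellLineGraphSet, FingerprintMatrix, SynergyDataset, build_cell_line_graphs

__all__ = [
    "CHANNEL_MASKS", "EncoderParams", "SpecificDecoderParams", "CommonParams",
    "EmbeddingSet", "encoder_layer", "fuse_layers", "bilinear_decode",
    "reconstruction_loss", "common_fuse", "total_loss",
    "MultiChannelGraphAutoencoder", "train_embeddings",
]

#: Ablation channel masks: which of the three graph channels feed the model.
CHANNEL_MASKS = {
    "syn": (0,),
    "syn+add": (0, 1),
    "syn+ant": (0, 2),
    "all": (0, 1, 2),
}


# ---------------------------------------------------------------------------
# Functional (numpy) surface — also the reference the estimator is tested
# against.
# ---------------------------------------------------------------------------

@dataclass
class EncoderParams:
    """Encoder weights for one cell line.

    ``channel_weights[l][t]`` is W_t at layer l (first layer d0 -> d, later
    d -> d), ``self_weights[l]`` the self-loop weight, ``channel_attention``
    the per-channel alpha scalars, ``layer_attention`` the per-layer betas.
    """

    channel_weights: list[dict[int, np.ndarray]]
    self_weights: list[np.ndarray]
    channel_attention: dict[int, float]
    layer_attention: np.ndarray


@dataclass
class SpecificDecoderParams:
    bilinear: np.ndarray                 # W_r, d x d, shared across channels
    diagonals: dict[int, np.ndarray]     # D_{r|t}, length d per channel


@dataclass
class CommonParams:
    cell_attention: np.ndarray           # alpha_r, length R
    bilinear: np.ndarray                 # global W, d x d
    diagonals: dict[str, dict[int, np.ndarray]]  # D'_{r|t} keyed by cell line


@dataclass
class EmbeddingSet:
    """Fitted drug embeddings: one specific matrix per cell line plus the common one."""

    specific: dict[str, np.ndarray]
    common: np.ndarray
    drugs: list[str]

    def specific_or_common(self, cell_line: str) -> tuple[np.ndarray, bool]:
        """Specific embedding for ``cell_line``; falls back to the common one.

        Returns ``(matrix, substituted)`` — substitution happens for cell
        lines absent from training (leave-one-cell-line-out)."""
        if cell_line in self.specific:
            return self.specific[cell_line], False
        return self.common, True


def _normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Row-normalize an adjacency matrix; isolated rows stay zero."""
    deg = A.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(deg > 0, A / deg, 0.0)
    return out


def encoder_layer(graphs: CellLineGraphSet, H_prev: np.ndarray,
                  params: EncoderParams, layer: int) -> np.ndarray:
    """One encoder update (matrix form) for the given layer index (0-based)."""
    if H_prev.shape[0] != graphs.n_drugs:
        raise ValueError("H_prev row count does not match the drug index")
    Z = H_prev @ params.self_weights[layer]
    for t, W in params.channel_weights[layer].items():
        An = _normalized_adjacency(graphs.A[t])
        Z = Z + params.channel_attention[t] * (An @ (H_prev @ W))
    return np.maximum(Z, 0.0)


def fuse_layers(H_layers: Sequence[np.ndarray], beta: Sequence[float]) -> np.ndarray:
    """Layer-attention fusion h^spe = sum_l beta^(l) h^(l) over layers 1..L."""
    if len(H_layers) != len(beta):
        raise ValueError(f"{len(H_layers)} layer outputs but {len(beta)} attention weights")
    out = np.zeros_like(H_layers[0])
    for b, H in zip(beta, H_layers):
        out = out + b * H
    return out


def bilinear_decode(H_left: np.ndarray, H_right: np.ndarray,
                    Dvec: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Symmetrized bilinear edge scores sigmoid(h_i D B D h_j^T).

    The raw bilinear form is not symmetric for general B; the returned
    score is the mean over both orderings so reconstructed adjacency is
    exactly symmetric.
    """
    if not (np.isfinite(Dvec).all() and np.isfinite(B).all()):
        raise ValueError("non-finite decoder parameters")
    raw = (H_left * Dvec) @ B @ (H_right * Dvec).T
    raw = 1.0 / (1.0 + np.exp(-np.clip(raw, -60, 60)))
    return 0.5 * (raw + raw.T)


def reconstruction_loss(graphs: CellLineGraphSet,
                        scores: Mapping[int, np.ndarray]) -> float:
    """Masked MSE over the measured pairs, summed across active channels.

    Every measured pair of the cell line is scored against each channel's
    0/1 target: a pair is a positive for its own class channel and a
    negative for the other two. Unmeasured pairs carry no loss.
    """
    mask = graphs.pair_mask()
    count = mask.sum()
    if count == 0:
        return 0.0
    loss = 0.0
    for t, S in scores.items():
        loss += float((mask * (graphs.A[t] - S) ** 2).sum()) / count
    return loss


def common_fuse(H_spe: Sequence[np.ndarray], alpha_cell: Sequence[float]) -> np.ndarray:
    """Cell-line-attention fusion h^com = sum_r alpha_r h^spe_r."""
    if len(H_spe) != len(alpha_cell):
        raise ValueError(f"{len(H_spe)} embeddings but {len(alpha_cell)} attention weights")
    out = np.zeros_like(H_spe[0])
    for a, H in zip(alpha_cell, H_spe):
        out = out + a * H
    return out


def total_loss(loss_com: float, losses_spe: Sequence[float]) -> float:
    """Joint objective: common-pathway loss plus the sum of per-cell-line losses."""
    return float(loss_com) + float(np.sum(losses_spe))


# ---------------------------------------------------------------------------
# Trainable estimator
# ---------------------------------------------------------------------------

class MultiChannelGraphAutoencoder(BaseEstimator):
    """Jointly trains specific and common drug embeddings on the class graphs.

    Parameters
    ----------
    embedding_dim : int
        Width d of the drug embeddings.
    n_layers : int
        Encoder depth L; layers 1..L are fused by the layer attention.
    learning_rate, epochs : float, int
        Adam step size and number of full-batch epochs.
    channels : str
        One of ``"syn"``, ``"syn+add"``, ``"syn+ant"``, ``"all"`` — which
        graph channels the encoder and the reconstruction loss use.
    attention_softmax : bool
        If True, the channel / layer / cell-line attentions are softmax
        normalized; by default they are free trainable scalars.
    weight_decay : float
        Optional L2 penalty on the weight matrices and decoder diagonals
        (attention scalars are exempt); 0 disables it.
    seed : int
        Seeds Xavier initialization; training is full-batch, so runs with
        the same seed are reproducible.

    Attributes
    ----------
    embeddings_ : EmbeddingSet
    loss_trace_ : list of dict with keys ``total``, ``common``, ``specific``
    params_ : dict mapping parameter keys to Tensors
    """

    def __init__(self, embedding_dim: int = 128, n_layers: int = 3,
                 learning_rate: float = 1e-3, epochs: int = 500,
                 channels: str = "all", attention_softmax: bool = False,
                 weight_decay: float = 0.0, seed: int = 42):
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.channels = channels
        self.attention_softmax = attention_softmax
        self.weight_decay = weight_decay
        self.seed = seed

    # -- parameter setup ------------------------------------------------------
    def _active_channels(self) -> tuple[int, ...]:
        try:
            return CHANNEL_MASKS[self.channels]
        except KeyError:
            raise ValueError(f"unknown channel mask {self.channels!r}; "
                             f"choose from {sorted(CHANNEL_MASKS)}") from None

    def _init_params(self, cell_lines: Sequence[str], d0: int,
                     rng: np.random.Generator) -> dict:
        d, L = self.embedding_dim, self.n_layers
        chans = self._active_channels()
        P: dict[tuple, Tensor] = {}

        def param(key, array):
            P[key] = Tensor(array, requires_grad=True)

        for r in cell_lines:
            for l in range(L):
                din = d0 if l == 0 else d
                for t in chans:
                    param(("enc_W", r, t, l), xavier_uniform((din, d), rng))
                param(("enc_W0", r, l), xavier_uniform((din, d), rng))
            for t in chans:
                param(("alpha", r, t), np.float64(1.0 / len(chans)))
            param(("beta", r), np.full(L, 1.0 / L))
            param(("dec_W", r), xavier_uniform((d, d), rng))
            for t in chans:
                param(("dec_D", r, t), xavier_uniform((d,), rng))
                param(("com_D", r, t), xavier_uniform((d,), rng))
        param(("alpha_cell",), np.full(len(cell_lines), 1.0 / len(cell_lines)))
        param(("com_W",), xavier_uniform((d, d), rng))
        return P

    # -- forward --------------------------------------------------------------
    def _attention_weights(self, raw: list[Tensor]) -> list[Tensor]:
        if not self.attention_softmax:
            return raw
        exps = [t.exp() for t in raw]
        total = exps[0]
        for e in exps[1:]:
            total = total + e
        return [e / total for e in exps]

    def _forward(self, P: dict, graph_sets: dict[str, CellLineGraphSet],
                 A_norm: dict, masks: dict, H0: Tensor):
        """Full forward pass; returns (loss, loss_com, per-cell losses, H_spe, H_com)."""
        chans = self._active_channels()
        cell_lines = list(graph_sets)
        H_spe: dict[str, Tensor] = {}
        for r in cell_lines:
            alphas = self._attention_weights([P[("alpha", r, t)] for t in chans])
            H_prev, H_layers = H0, []
            for l in range(self.n_layers):
                Z = H_prev @ P[("enc_W0", r, l)]
                for a, t in zip(alphas, chans):
                    Z = Z + a * (A_norm[(r, t)] @ (H_prev @ P[("enc_W", r, t, l)]))
                H_prev = Z.relu()
                H_layers.append(H_prev)
            beta_vec = P[("beta", r)]
            fused = None
            for l in range(self.n_layers):
                # scalar slice of the beta vector via a one-hot dot product
                b = (beta_vec * Tensor(np.eye(self.n_layers)[l])).sum()
                term = b * H_layers[l]
                fused = term if fused is None else fused + term
            if self.attention_softmax:
                # renormalize fused combination with softmax over layers
                exps = beta_vec.exp()
                fused = None
                wsum = exps.sum()
                for l in range(self.n_layers):
                    b = (exps * Tensor(np.eye(self.n_layers)[l])).sum() / wsum
                    term = b * H_layers[l]
                    fused = term if fused is None else fused + term
            H_spe[r] = fused

        alpha_cell = P[("alpha_cell",)]
        if self.attention_softmax:
            exps = alpha_cell.exp()
            alpha_terms = [(exps * Tensor(np.eye(len(cell_lines))[k])).sum() / exps.sum()
                           for k in range(len(cell_lines))]
        else:
            alpha_terms = [(alpha_cell * Tensor(np.eye(len(cell_lines))[k])).sum()
                           for k in range(len(cell_lines))]
        H_com = None
        for a, r in zip(alpha_terms, cell_lines):
            term = a * H_spe[r]
            H_com = term if H_com is None else H_com + term

        def decode(H, Dvec, B):
            HD = H * Dvec
            raw = (HD @ B @ HD.T).sigmoid()
            return 0.5 * (raw + raw.T)

        loss_spe, loss_com = {}, None
        for r in cell_lines:
            mask, count = masks[r]
            if count == 0:
                loss_spe[r] = Tensor(0.0)
                continue
            lr_spe = None
            for t in chans:
                S = decode(H_spe[r], P[("dec_D", r, t)], P[("dec_W", r)])
                term = ((Tensor(mask) * (Tensor(graph_sets[r].A[t]) - S) ** 2).sum()
                        * (1.0 / count))
                lr_spe = term if lr_spe is None else lr_spe + term
                Sc = decode(H_com, P[("com_D", r, t)], P[("com_W",)])
                cterm = ((Tensor(mask) * (Tensor(graph_sets[r].A[t]) - Sc) ** 2).sum()
                         * (1.0 / count))
                loss_com = cterm if loss_com is None else loss_com + cterm
            loss_spe[r] = lr_spe
        if loss_com is None:
            loss_com = Tensor(0.0)
        total = loss_com
        for r in cell_lines:
            total = total + loss_spe[r]
        return total, loss_com, loss_spe, H_spe, H_com

    # -- fit ------------------------------------------------------------------
    def fit(self, dataset: SynergyDataset, fingerprints: FingerprintMatrix,
            train_records: Sequence[int] | None = None):
        """Train on the graphs built from ``train_records`` (default: all records)."""
        rng = np.random.default_rng(self.seed)
        cell_lines = [c for c in dataset.cell_lines
                      if dataset.records_in(c, train_records)]
        if not cell_lines:
            raise ValueError("no training records in any cell line")
        graph_sets = {r: build_cell_line_graphs(dataset, r, train_records)
                      for r in cell_lines}
        chans = self._active_channels()
        A_norm = {(r, t): Tensor(_normalized_adjacency(graph_sets[r].A[t]))
                  for r in cell_lines for t in chans}
        masks = {}
        for r in cell_lines:
            m = graph_sets[r].pair_mask()
            masks[r] = (m, float(m.sum()))

        H0 = Tensor(fingerprints.F)
        P = self._init_params(cell_lines, fingerprints.n_bits, rng)
        opt = Adam(P.values(), lr=self.learning_rate)
        trace = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            total, lcom, lspe, H_spe, H_com = self._forward(
                P, graph_sets, A_norm, masks, H0)
            val = float(total.data)
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            trace.append({"total": val, "common": float(lcom.data),
                          "specific": {r: float(l.data) for r, l in lspe.items()}})
            objective = total
            if self.weight_decay:
                # L2 on weight matrices and diagonals; attentions stay free
                for key, p in P.items():
                    if key[0] not in ("alpha", "beta", "alpha_cell"):
                        objective = objective + self.weight_decay * (p ** 2).sum()
            objective.backward()
            opt.step()

        _, lcom, lspe, H_spe, H_com = self._forward(P, graph_sets, A_norm, masks, H0)
        self.params_ = P
        self._H0_, self._A_norm_, self._masks_ = H0, A_norm, masks
        self.cell_lines_ = cell_lines
        self.graph_sets_ = graph_sets
        self.loss_trace_ = trace
        self.embeddings_ = EmbeddingSet(
            specific={r: H_spe[r].data.copy() for r in cell_lines},
            common=H_com.data.copy(), drugs=list(dataset.drugs))
        self.final_loss_ = {"total": float((lcom.data + sum(l.data for l in lspe.values()))),
                            "common": float(lcom.data),
                            "specific": {r: float(l.data) for r, l in lspe.items()}}
        return self

    # -- decoding fitted scores ----------------------------------------------
    def decode_channel(self, cell_line: str, channel: int = 0,
                       pathway: str = "specific") -> np.ndarray:
        """Reconstructed edge-probability matrix for one cell line and channel."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        P = self.params_
        if pathway == "specific":
            H = self.embeddings_.specific[cell_line]
            D = P[("dec_D", cell_line, channel)].data
            B = P[("dec_W", cell_line)].data
        else:
            H = self.embeddings_.common
            D = P[("com_D", cell_line, channel)].data
            B = P[("com_W",)].data
        return bilinear_decode(H, H, D, B)

    def initial_scores(self, dataset: SynergyDataset,
                       fingerprints: FingerprintMatrix, cell_line: str,
                       channel: int = 0,
                       train_records: Sequence[int] | None = None) -> np.ndarray:
        """Decoder scores of an untrained model (fresh Xavier init), for baselines."""
        clone = MultiChannelGraphAutoencoder(**self.get_params())
        clone.epochs = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clone.fit(dataset, fingerprints, train_records)
        return clone.decode_channel(cell_line, channel)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path):
        """Write parameters (npz) plus a JSON manifest with shapes and config."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {"|".join(map(str, k)): v.data for k, v in self.params_.items()}
        np.savez(path / "params.npz", **arrays)
        manifest = {
            "config": self.get_params(),
            "cell_lines": self.cell_lines_,
            "drugs": self.embeddings_.drugs,
            "shapes": {k: list(v.shape) for k, v in arrays.items()},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(path / "embeddings.npz", common=self.embeddings_.common,
                 **{f"spe|{r}": m for r, m in self.embeddings_.specific.items()})

    def export_embeddings_tsv(self, outdir: str | Path):
        """One TSV per cell line plus one for the common embeddings."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for r, M in self.embeddings_.specific.items():
            pd.DataFrame(M, index=self.embeddings_.drugs).to_csv(
                outdir / f"embedding_specific_{r}.tsv", sep="\t")
        pd.DataFrame(self.embeddings_.common, index=self.embeddings_.drugs).to_csv(
            outdir / "embedding_common.tsv", sep="\t")


def train_embeddings(dataset: SynergyDataset, fingerprints: FingerprintMatrix,
                     train_records: Sequence[int] | None = None,
                     **config) -> MultiChannelGraphAutoencoder:
    """Functional wrapper: fit a :class:`MultiChannelGraphAutoencoder`."""
    return MultiChannelGraphAutoencoder(**config).fit(
        dataset, fingerprints, train_records)
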