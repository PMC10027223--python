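"""Synthetic multi-cell-line synergy benchmarks with planted structure.

The generator emulates the decomposition the embedding model assumes: every
drug i carries a common latent u_i shared across cell lines and a
cell-line-specific latent v_{i,r}, and the noiseless synergy signal of a
pair in cell line r is the convex mix

    signal(i, j, r) = share * <u_i, u_j> + (1 - share) * <v_{i,r}, v_{j,r}>.

Scores are scale * signal + Gaussian noise; the scale is chosen (and
rescaled if needed) so that all three classes are populated under the
synergy-type thresholds. ``share = 1`` makes every cell line identical,
``share = 0`` fully cell-line-specific. Because the scores are latent dot
products, the planted structure matches the bilinear decoder's model class
at the extremes while remaining model-agnostic in between.

The noise level is specified relative to the signal: ``noise_sd_frac = 0.5``
means the additive noise sd is half the sd of the scaled signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .data import (DEFAULT_THRESHOLDS, SynergyDataset, SynergyRecord,
                   SynergyType, ThresholdTable, classify_synergy)

__all__ = ["SimConfig", "generate_dataset", "generate_cell_features",
           "generate_structures", "candidate_smiles"]


@dataclass(frozen=True)
class SimConfig:
    n_drugs: int = 16
    n_cell_lines: int = 3
    rank: int = 3                 # latent dimension q of the planted factors
    share: float = 0.5            # fraction of signal common across cell lines
    noise_sd_frac: float = 0.5    # noise sd as a fraction of the signal sd
    density: float = 1.0          # fraction of unordered pairs measured per cell line
    synergy_type: SynergyType = SynergyType.LOEWE
    thresholds: ThresholdTable = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 4 or self.n_cell_lines < 1 or self.rank < 1:
            raise ValueError("need n_drugs >= 4, n_cell_lines >= 1, rank >= 1")
        if not 0.0 <= self.share <= 1.0:
            raise ValueError("share must lie in [0, 1]")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")


def _drug_id(i: int) -> str:
    return f"drug_{i:03d}"


def _cell_id(r: int) -> str:
    return f"cell_{r}"


def generate_dataset(config: SimConfig) -> tuple[SynergyDataset, dict]:
    """Draw a synergy dataset with planted low-rank structure.

    Returns the dataset and a ground-truth dict with the latent factors,
    the chosen scale and the full noiseless signal tensor.
    """
    rng = np.random.default_rng(config.seed)
    N, R, q = config.n_drugs, config.n_cell_lines, config.rank
    u = rng.standard_normal((N, q))
    v = rng.standard_normal((R, N, q))

    pairs = list(combinations(range(N), 2))
    signal = np.zeros((R, len(pairs)))
    for r in range(R):
        G_com = u @ u.T
        G_spe = v[r] @ v[r].T
        for p, (i, j) in enumerate(pairs):
            signal[r, p] = config.share * G_com[i, j] + (1 - config.share) * G_spe[i, j]
    noise_unit = rng.standard_normal(signal.shape)

    low, high = config.thresholds[config.synergy_type]
    sig_sd = signal.std()
    if sig_sd == 0:
        raise ValueError("degenerate configuration: zero signal variance")
    scale = (high - low) / sig_sd
    for _ in range(100):
        scores = scale * signal + config.noise_sd_frac * scale * sig_sd * noise_unit
        labels = np.array([[int(classify_synergy(s, config.synergy_type,
                                                 config.thresholds))
                            for s in row] for row in scores])
        counts = [np.sum(labels == t) for t in range(3)]
        if all(c > 0 for c in counts):
            break
        if counts[0] == 0 or counts[2] == 0:   # tails empty: spread the scores
            scale *= 1.5
        else:                                   # additive band empty: shrink
            scale /= 1.5
    else:
        raise ValueError("could not populate all three classes; "
                         "adjust thresholds or scale")

    n_obs = int(round(config.density * len(pairs)))
    records = []
    for r in range(R):
        chosen = rng.choice(len(pairs), size=n_obs, replace=False)
        for p in sorted(chosen):
            i, j = pairs[p]
            score = float(scores[r, p])
            records.append(SynergyRecord(
                _drug_id(i), _drug_id(j), _cell_id(r), score,
                config.synergy_type,
                classify_synergy(score, config.synergy_type, config.thresholds)))
    dataset = SynergyDataset(records, [_drug_id(i) for i in range(N)],
                             [_cell_id(r) for r in range(R)])
    truth = {"u": u, "v": v, "scale": scale, "pairs": pairs,
             "signal": signal, "scores": scores}
    return dataset, truth


def generate_cell_features(config: SimConfig, width: int = 32,
                           feature_noise_sd: float = 0.0) -> dict[str, np.ndarray]:
    """Cell-line feature rows correlated with the planted latent structure.

    Each cell line's effective latent field ``share*u + (1-share)*v_r`` is
    projected through a fixed random linear map; cell lines with identical
    latent structure (share = 1, zero noise) get identical rows.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    rng = np.random.default_rng(config.seed)
    N, R, q = config.n_drugs, config.n_cell_lines, config.rank
    u = rng.standard_normal((N, q))
    v = rng.standard_normal((R, N, q))          # same draws as generate_dataset
    proj_rng = np.random.default_rng(config.seed + 10_000)
    M = proj_rng.standard_normal((N * q, width)) / np.sqrt(N * q)
    out = {}
    for r in range(R):
        eff = config.share * u + (1 - config.share) * v[r]
        row = eff.ravel() @ M
        if feature_noise_sd > 0:
            row = row + proj_rng.normal(0, feature_noise_sd, size=width)
        out[_cell_id(r)] = row
    return out


def candidate_smiles() -> list[str]:
    """A deterministic list of >= 200 small valid SMILES strings.

    Linear carbon chains decorated with simple terminal groups — chemically
    plain but syntactically valid, enough to exercise fingerprinting.
    """
    suffixes = ["", "O", "N", "Cl", "F", "Br", "C(=O)O", "C(=O)N", "S", "C#N"]
    out = []
    for n in range(1, 21):
        for suf in suffixes:
            out.append("C" * n + suf)
    return out


def generate_structures(n_drugs: int, seed: int = 0) -> dict[str, str]:
    """Deterministically assign ``n_drugs`` distinct valid SMILES to drug ids."""
    pool = candidate_smiles()
    if n_drugs > len(pool):
        raise ValueError(f"at most {len(pool)} structures available, "
                         f"requested {n_drugs}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_drugs, replace=False)
    return {_drug_id(i): pool[c] for i, c in enumerate(chosen)}


def write_dataset_dir(config: SimConfig, outdir, cell_feature_width: int = 32):
    """Write a complete runnable dataset directory (tables as CSV/TSV)."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(config)
    rows = [{"drug_a": r.drug_a, "drug_b": r.drug_b, "cell_line": r.cell_line,
             "score": r.score} for r in dataset.records]
    pd.DataFrame(rows).to_csv(outdir / "synergy.csv", index=False)

    structures = generate_structures(config.n_drugs, config.seed)
    pd.DataFrame({"drug_id": list(structures), "smiles": list(structures.values())}
                 ).to_csv(outdir / "structures.tsv", sep="\t", index=False)

    feats = generate_cell_features(config, width=cell_feature_width)
    pd.DataFrame(feats).T.to_csv(outdir / "cell_features.tsv", sep="\t")

    pd.DataFrame(truth["u"], index=[_drug_id(i) for i in range(config.n_drugs)]
                 ).to_csv(outdir / "truth_common_latents.tsv", sep="\t")
    manifest = {
        "config": {k: (v.value if isinstance(v, SynergyType) else v)
                   for k, v in vars(config).items() if k != "thresholds"},
        "thresholds": {st.value: list(config.thresholds[st])
                       for st in SynergyType},
        "n_records": len(dataset.records),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dataset, truth


def with_share(config: SimConfig, share: float) -> SimConfig:
    """Copy of ``config`` with a different common-signal fraction."""
    return replace(config, share=share)
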