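"""Synergy tables, class thresholds, per-cell-line graphs and drug features.

A drug-combination screen is a set of (drug_a, drug_b, cell_line, score)
triples, where the score quantifies departure from a non-interaction
reference (Loewe additivity, Bliss independence, ZIP or HSA). Per synergy
type a pair of cutoffs splits combinations into three classes —
synergistic, additive and antagonistic — and the combinations measured in
one cell line then form three undirected graphs over a global drug index,
one graph per class. Those three adjacency matrices per cell line are the
input channels of the embedding model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynergyType", "Label", "ThresholdTable", "DEFAULT_THRESHOLDS",
    "SynergyRecord", "SynergyDataset", "CellLineGraphSet",
    "FingerprintMatrix", "classify_synergy", "load_synergy_table",
    "build_cell_line_graphs", "featurize_drugs",
]


class SynergyType(str, enum.Enum):
    LOEWE = "loewe"
    BLISS = "bliss"
    ZIP = "zip"
    HSA = "hsa"


class Label(enum.IntEnum):
    """Combination class; values index the graph channels 0..2."""

    SYNERGISTIC = 0
    ADDITIVE = 1
    ANTAGONISTIC = 2


@dataclass(frozen=True)
class ThresholdTable:
    """Per-synergy-type (low, high) score cutoffs.

    Scores strictly above ``high`` are synergistic, strictly below ``low``
    antagonistic, everything else (including the boundary values) additive.
    """

    cutoffs: Mapping[SynergyType, tuple[float, float]]

    def __post_init__(self):
        for st, (lo, hi) in self.cutoffs.items():
            if not lo < hi:
                raise ValueError(f"thresholds for {st}: low must be < high")

    def __getitem__(self, st: SynergyType) -> tuple[float, float]:
        return self.cutoffs[SynergyType(st)]


#: Literature cutoffs for the four synergy scales.
DEFAULT_THRESHOLDS = ThresholdTable({
    SynergyType.LOEWE: (0.0, 30.0),
    SynergyType.BLISS: (-3.37, 3.68),
    SynergyType.HSA: (-3.02, 3.87),
    SynergyType.ZIP: (-4.48, 2.64),
})


def classify_synergy(score: float, synergy_type: SynergyType,
                     thresholds: ThresholdTable = DEFAULT_THRESHOLDS) -> Label:
    """Assign the 3-way combination class for one synergy score."""
    if not np.isfinite(score):
        raise ValueError(f"non-finite synergy score: {score!r}")
    low, high = thresholds[synergy_type]
    if score > high:
        return Label.SYNERGISTIC
    if score < low:
        return Label.ANTAGONISTIC
    return Label.ADDITIVE


@dataclass(frozen=True)
class SynergyRecord:
    drug_a: str
    drug_b: str
    cell_line: str
    score: float
    synergy_type: SynergyType
    label: Label

    def pair(self) -> tuple[str, str]:
        """The unordered drug pair as a sorted tuple."""
        return tuple(sorted((self.drug_a, self.drug_b)))


@dataclass
class SynergyDataset:
    """All measured triples plus the global drug and cell-line indexes."""

    records: list[SynergyRecord]
    drugs: list[str]
    cell_lines: list[str]

    def __post_init__(self):
        self.drug_index = {d: i for i, d in enumerate(self.drugs)}
        self.cell_index = {c: i for i, c in enumerate(self.cell_lines)}

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    def records_in(self, cell_line: str,
                   subset: Iterable[int] | None = None) -> list[int]:
        """Indices of records measured in ``cell_line`` (within ``subset``)."""
        idx = range(len(self.records)) if subset is None else subset
        return [i for i in idx if self.records[i].cell_line == cell_line]

    @classmethod
    def from_records(cls, records: Sequence[SynergyRecord]) -> "SynergyDataset":
        drugs = sorted({d for r in records for d in (r.drug_a, r.drug_b)})
        cells = sorted({r.cell_line for r in records})
        return cls(list(records), drugs, cells)


@dataclass
class CellLineGraphSet:
    """Three symmetric N x N binary adjacency matrices for one cell line."""

    cell_line: str
    A: np.ndarray  # shape (3, N, N)
    measured_pairs: set = field(default_factory=set)  # unordered (i, j) index pairs

    @property
    def n_drugs(self) -> int:
        return self.A.shape[1]

    def pair_mask(self) -> np.ndarray:
        """Upper-triangular 0/1 mask over the measured unordered pairs."""
        m = np.zeros(self.A.shape[1:], dtype=np.float64)
        for i, j in self.measured_pairs:
            m[min(i, j), max(i, j)] = 1.0
        return m


@dataclass
class FingerprintMatrix:
    """Binary drug feature matrix, one row per drug in global index order."""

    F: np.ndarray
    n_bits: int
    provenance: str

    @property
    def width(self) -> int:
        return self.n_bits


def load_synergy_table(path: str | Path, synergy_type: SynergyType,
                       thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                       aggregate_duplicates: bool = False) -> SynergyDataset:
    """Read a CSV/TSV synergy table into a :class:`SynergyDataset`.

    The file needs columns ``drug_a, drug_b, cell_line, score``. Orderings
    of the same pair collapse to one record; duplicate triples raise unless
    ``aggregate_duplicates`` is set, in which case scores are averaged.
    Drug and cell-line indexes are sorted lexicographically.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"drug_a", "drug_b", "cell_line", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    synergy_type = SynergyType(synergy_type)
    seen: dict[tuple, list[float]] = {}
    for row in df.itertuples(index=False):
        a, b, c = str(row.drug_a), str(row.drug_b), str(row.cell_line)
        if a == b:
            raise ValueError(f"drug {a!r} paired with itself in cell line {c!r}")
        score = float(row.score)
        key = (min(a, b), max(a, b), c)
        seen.setdefault(key, []).append(score)

    records = []
    for (a, b, c), scores in seen.items():
        if len(scores) > 1 and not aggregate_duplicates:
            if max(scores) - min(scores) > 0:
                raise ValueError(
                    f"conflicting duplicate measurements for ({a}, {b}, {c}): {scores}")
        score = float(np.mean(scores))
        records.append(SynergyRecord(a, b, c, score, synergy_type,
                                     classify_synergy(score, synergy_type, thresholds)))
    records.sort(key=lambda r: (r.cell_line, r.drug_a, r.drug_b))
    if not records:
        return SynergyDataset([], [], [])
    return SynergyDataset.from_records(records)


def build_cell_line_graphs(dataset: SynergyDataset, cell_line: str,
                           include_records: Iterable[int] | None = None
                           ) -> CellLineGraphSet:
    """Build the three-channel adjacency matrices for one cell line.

    ``include_records`` restricts edges to a record subset (e.g. the
    training split), so held-out labels never leak into the graphs.
    """
    if cell_line not in dataset.cell_index:
        raise KeyError(f"unknown cell line: {cell_line!r}")
    N = dataset.n_drugs
    A = np.zeros((3, N, N), dtype=np.float64)
    pairs = set()
    for ridx in dataset.records_in(cell_line, include_records):
        rec = dataset.records[ridx]
        i, j = dataset.drug_index[rec.drug_a], dataset.drug_index[rec.drug_b]
        A[int(rec.label), i, j] = A[int(rec.label), j, i] = 1.0
        pairs.add((min(i, j), max(i, j)))
    return CellLineGraphSet(cell_line, A, pairs)


def _morgan_fingerprints(smiles_by_drug: Mapping[str, str], drugs: Sequence[str],
                         n_bits: int, radius: int) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    F = np.zeros((len(drugs), n_bits), dtype=np.float64)
    for row, drug in enumerate(drugs):
        if drug not in smiles_by_drug:
            raise KeyError(f"no structure for drug {drug!r}")
        mol = Chem.MolFromSmiles(smiles_by_drug[drug])
        if mol is None:
            raise ValueError(f"unparsable SMILES for drug {drug!r}: "
                             f"{smiles_by_drug[drug]!r}")
        fp = gen.GetFingerprint(mol)
        F[row, list(fp.GetOnBits())] = 1.0
    return F


def featurize_drugs(structures: Mapping[str, str] | None, drugs: Sequence[str],
                    n_bits: int = 256, radius: int = 2,
                    seed: int = 0) -> FingerprintMatrix:
    """Hashed circular (Morgan) fingerprints for the indexed drugs.

    With ``structures=None`` a seeded random binary matrix is produced
    instead, so datasets without chemistry still drive the full model.
    """
    if structures is None:
        rng = np.random.default_rng(seed)
        F = (rng.random((len(drugs), n_bits)) < 0.5).astype(np.float64)
        return FingerprintMatrix(F, n_bits, f"random(seed={seed})")
    F = _morgan_fingerprints(structures, drugs, n_bits, radius)
    return FingerprintMatrix(F, n_bits, f"morgan(radius={radius},bits={n_bits})")


def load_structures(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``drug_id <tab> smiles``."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug_id, smiles)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def load_cell_features(path: str | Path) -> pd.DataFrame:
    """Read a TSV cell-line feature matrix (rows = cell lines)."""
    return pd.read_csv(path, sep="\t", index_col=0)
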