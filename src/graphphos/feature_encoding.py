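"""Handcrafted per-residue sequence features: the L x 57 matrix.

Four blocks are concatenated in a fixed column order::

    [ one-hot (21) | physicochemical (5) | PSSM (20) | secondary structure (11) ]

One-hot covers the 20 standard residues in alphabetical one-letter order
plus a catch-all column for non-standard symbols.  The physicochemical
block is a 5-dimensional principal-component summary of amino-acid
properties (the Atchley five-factor solution by default, replaceable by
any published 5-dim set).  The PSSM block holds PSI-BLAST log-odds scores,
optionally squashed through a logistic to bound their dynamic range.  The
secondary-structure block is the SPOT-1D-single-style table: eight SS
class probabilities, solvent-accessible surface area and the two
half-sphere exposure counts.

Block ablation zero-fills disabled blocks so the matrix is always 57 wide
and downstream model shapes never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNKNOWN_COLUMN = 20

FEATURE_WIDTH = 57
BLOCK_SLICES = {
    "onehot": slice(0, 21),
    "phy": slice(21, 26),
    "pssm": slice(26, 46),
    "ss": slice(46, 57),
}
BLOCK_ORDER = ("onehot", "phy", "pssm", "ss")

SS_COLUMNS = ("G", "H", "I", "B", "E", "S", "T", "C", "ASA", "HSEU", "HSED")

# Atchley et al. (2005) five-factor solution: polarity/hydrophobicity,
# secondary-structure propensity, molecular size, codon composition,
# electrostatic charge.  Any published 5-dim PCA table is a drop-in.
ATCHLEY_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


class AlignmentError(ValueError):
    """Row counts of per-residue files disagree with the sequence length."""


class SchemaError(ValueError):
    """A required column is missing from a feature table."""


@dataclass
class PhyschemTable:
    """Mapping from one-letter codes to 5-dim property vectors."""

    table: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(ATCHLEY_FACTORS))
    unknown: tuple[float, ...] = (0.0,) * 5

    def __post_init__(self):
        missing = [aa for aa in AMINO_ACIDS if aa not in self.table]
        if missing:
            raise SchemaError(f"physicochemical table lacks residues: {missing}")
        for aa, vec in self.table.items():
            if len(vec) != 5 or not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for {aa} must be 5 finite numbers")

    def __getitem__(self, aa: str) -> tuple[float, ...]:
        return self.table.get(aa.upper(), self.unknown)

    @classmethod
    def from_csv(cls, path) -> "PhyschemTable":
        df = pd.read_csv(path)
        table = {str(row.iloc[0]).upper(): tuple(row.iloc[1:6]) for _, row in df.iterrows()}
        return cls(table=table)


@dataclass
class FeatureMatrix:
    """The assembled L x 57 handcrafted feature matrix."""

    protein_id: str
    values: np.ndarray
    block_slices: dict = field(default_factory=lambda: dict(BLOCK_SLICES))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != FEATURE_WIDTH:
            raise ValueError(f"feature matrix must be (L, {FEATURE_WIDTH}), "
                             f"got {self.values.shape}")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, name: str) -> np.ndarray:
        return self.values[:, self.block_slices[name]]


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def encode_onehot(sequence: str) -> np.ndarray:
    """L x 21 one-hot; column 20 is the catch-all for non-standard symbols."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    out = np.zeros((len(sequence), 21))
    for i, aa in enumerate(sequence.upper()):
        out[i, AA_INDEX.get(aa, UNKNOWN_COLUMN)] = 1.0
    return out


def encode_physchem(sequence: str, table: Optional[PhyschemTable] = None) -> np.ndarray:
    """L x 5 physicochemical principal-component vectors."""
    table = table or PhyschemTable()
    return np.array([table[aa] for aa in sequence.upper()], dtype=np.float64)


def logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def read_pssm(path, expected_length: int, transform: str = "logistic") -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into the L x 20 log-odds block.

    ``transform="logistic"`` squashes scores through 1/(1+e^-x);
    ``transform="raw"`` returns the integers unchanged.
    """
    if transform not in ("logistic", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # data rows: position, residue, >=20 integer log-odds
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1 \
                    and parts[1].isalpha():
                try:
                    rows.append([float(v) for v in parts[2:22]])
                except ValueError as exc:
                    raise ValueError(f"malformed PSSM row at line {lineno} "
                                     f"of {path}: {exc}") from None
    matrix = np.array(rows, dtype=np.float64)
    if matrix.shape[0] != expected_length:
        raise AlignmentError(
            f"PSSM {path} has {matrix.shape[0]} rows, expected {expected_length}")
    return logistic(matrix) if transform == "logistic" else matrix


def read_ss_features(path, expected_length: int, scale: bool = True) -> np.ndarray:
    """Read a SPOT-1D-single-style per-residue table into the L x 11 SS block.

    Columns are normalized to (G, H, I, B, E, S, T, C, ASA, HSEU, HSED);
    the three exposure columns are min-max scaled to [0, 1] per protein
    unless ``scale=False``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing = [c for c in SS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"SS table {path} missing column(s): {missing}")
    values = df[list(SS_COLUMNS)].to_numpy(dtype=np.float64)
    if values.shape[0] != expected_length:
        raise AlignmentError(
            f"SS table {path} has {values.shape[0]} rows, expected {expected_length}")
    if scale:
        for col in (8, 9, 10):  # ASA, HSEU, HSED
            lo, hi = values[:, col].min(), values[:, col].max()
            values[:, col] = 0.0 if hi == lo else (values[:, col] - lo) / (hi - lo)
    return values


def assemble_features(protein_id: str,
                      onehot: Optional[np.ndarray] = None,
                      phy: Optional[np.ndarray] = None,
                      pssm: Optional[np.ndarray] = None,
                      ss: Optional[np.ndarray] = None,
                      enabled_blocks: Optional[Iterable[str]] = None) -> FeatureMatrix:
    """Concatenate blocks into the fixed-order L x 57 matrix.

    Disabled blocks (feature ablation) are zero-filled so the width never
    changes; every enabled block must share the same row count.
    """
    blocks = {"onehot": onehot, "phy": phy, "pssm": pssm, "ss": ss}
    enabled = set(BLOCK_ORDER if enabled_blocks is None else enabled_blocks)
    unknown = enabled - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown block name(s): {sorted(unknown)}")

    lengths = {name: b.shape[0] for name, b in blocks.items()
               if name in enabled and b is not None}
    if not lengths:
        raise ValueError("at least one enabled block must be provided")
    if len(set(lengths.values())) > 1:
        raise AlignmentError(f"block row counts disagree: {lengths}")
    L = next(iter(lengths.values()))

    values = np.zeros((L, FEATURE_WIDTH))
    for name in BLOCK_ORDER:
        if name in enabled and blocks[name] is not None:
            sl = BLOCK_SLICES[name]
            block = np.asarray(blocks[name], dtype=np.float64)
            width = sl.stop - sl.start
            if block.shape != (L, width):
                raise AlignmentError(
                    f"block {name!r} must be ({L}, {width}), got {block.shape}")
            values[:, sl] = block
    return FeatureMatrix(protein_id=protein_id, values=values)


def features_for_sequence(protein_id: str, sequence: str,
                          pssm: Optional[np.ndarray] = None,
                          ss: Optional[np.ndarray] = None,
                          physchem_table: Optional[PhyschemTable] = None,
                          enabled_blocks: Optional[Iterable[str]] = None) -> FeatureMatrix:
    """One-call assembly from a sequence plus pre-read PSSM / SS blocks."""
    return assemble_features(
        protein_id,
        onehot=encode_onehot(sequence),
        phy=encode_physchem(sequence, physchem_table),
        pssm=pssm,
        ss=ss,
        enabled_blocks=enabled_blocks,
    )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_feature_matrices(path, matrices: Iterable[FeatureMatrix]) -> None:
    """NPZ container keyed by protein id."""
    np.savez_compressed(path, **{m.protein_id: m.values for m in matrices})


def load_feature_matrices(path) -> dict[str, FeatureMatrix]:
    with np.load(path) as data:
        return {pid: FeatureMatrix(protein_id=pid, values=data[pid]) for pid in data.files}
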