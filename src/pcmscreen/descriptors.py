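"""Compound and protein descriptor blocks for PCM feature matrices.

A PCM feature row is the concatenation of compound descriptor blocks
(ECFP fingerprints, physicochemical properties) and protein descriptor
blocks (residue-scale encodings compressed by autocross-correlation,
sequence composition). No cross-term (compound x protein product)
columns are generated: nonlinear learners pick up interactions on
their own and cross-terms are poorly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

__all__ = [
    "DescriptorBlock",
    "FeatureMatrix",
    "ZSCALES",
    "ecfp_fingerprint",
    "tanimoto",
    "physchem_block",
    "residue_scale_encoding",
    "acc_transform",
    "composition_block",
    "assemble_features",
]

#: 5-dimensional principal-property scales for the 20 standard residues
#: (z1 lipophilicity, z2 steric bulk/polarizability, z3 polarity,
#: z4/z5 electronic effects), as published for extended z-scale QSAM work.
ZSCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PHYSCHEM_NAMES = (
    "mol_weight",
    "clogp",
    "hbd",
    "hba",
    "rotatable_bonds",
    "tpsa",
    "ring_count",
    "heavy_atoms",
)


@dataclass(frozen=True)
class DescriptorBlock:
    """A named group of feature columns, either compound- or protein-side."""

    name: str
    kind: str  # "compound" | "protein"
    width: int

    def __post_init__(self) -> None:
        if self.kind not in ("compound", "protein"):
            raise ValueError(f"kind must be compound or protein, got {self.kind!r}")
        if self.width <= 0:
            raise ValueError("block width must be positive")


@dataclass
class FeatureMatrix:
    """Dense PCM design matrix with a map from block name to column range."""

    values: np.ndarray
    rows: list[tuple[str, str]]  # (compound smiles, target id)
    block_index: dict[str, tuple[int, int]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_index[name]
        return self.values[:, lo:hi]


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def ecfp_fingerprint(smiles: str, radius: int = 3, n_bits: int = 1024) -> np.ndarray:
    """Extended-connectivity fingerprint (ECFP) as a 0/1 uint8 vector.

    Defaults give the 1024-bit ECFP-6 (bond radius 3) used for screening
    similarity, novelty filtering, and clustering.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(_mol(smiles))
    return fp.astype(np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints.

    Two all-zero vectors are defined as maximally similar (1.0): both
    molecules are featureless at this fingerprint resolution.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def physchem_block(smiles: str) -> np.ndarray:
    """Fixed-order physicochemical property vector (see PHYSCHEM_NAMES)."""
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumRotatableBonds(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumRings(mol),
            mol.GetNumHeavyAtoms(),
        ],
        dtype=float,
    )


def residue_scale_encoding(
    aligned_sequences: Sequence[str],
    scale: Mapping[str, Sequence[float]] = ZSCALES,
) -> list[np.ndarray]:
    """Encode aligned sequences as per-position property matrices.

    Gap characters ('-' or '.') emit the neutral all-zero vector so that
    alignment columns with no residue contribute nothing.
    """
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) > 1:
        raise ValueError(f"sequences are not aligned to equal length: {sorted(lengths)}")
    width = len(next(iter(scale.values())))
    out = []
    for seq in aligned_sequences:
        mat = np.zeros((len(seq), width), dtype=float)
        for i, ch in enumerate(seq.upper()):
            if ch in ("-", "."):
                continue
            if ch not in scale:
                raise ValueError(f"unknown residue {ch!r} at position {i}")
            mat[i] = scale[ch]
        out.append(mat)
    return out


def acc_transform(matrix: np.ndarray, max_lag: int = 3) -> np.ndarray:
    """Autocross-correlation of a per-position property matrix.

    For every ordered property pair (j, k) and lag l in 1..max_lag the
    output holds the mean over positions i of the centered product
    (x[i,j] - mean_j) * (x[i+l,k] - mean_k). Centering uses per-property
    column means, so adding a constant to any property leaves the result
    unchanged. Output length is p^2 * max_lag for p properties.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D per-position matrix")
    n, p = x.shape
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n <= max_lag:
        raise ValueError(f"sequence length {n} must exceed max_lag {max_lag}")
    xc = x - x.mean(axis=0, keepdims=True)
    out = np.empty(p * p * max_lag, dtype=float)
    idx = 0
    for lag in range(1, max_lag + 1):
        # mean over the n-lag valid positions of centered lagged products
        prod = xc[:-lag].T @ xc[lag:] / (n - lag)
        out[idx : idx + p * p] = prod.ravel()
        idx += p * p
    return out


def composition_block(sequence: str, dipeptides: bool = True) -> np.ndarray:
    """Alignment-free residue composition (+ dipeptide composition) vector.

    Stands in for web-service protein descriptors: 20 residue frequencies
    followed, when ``dipeptides`` is true, by 400 dipeptide frequencies.
    """
    seq = sequence.upper().replace("-", "").replace(".", "")
    if not seq:
        raise ValueError("empty sequence")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    comp = np.zeros(20, dtype=float)
    for ch in seq:
        if ch not in aa_index:
            raise ValueError(f"unknown residue {ch!r}")
        comp[aa_index[ch]] += 1
    comp /= len(seq)
    if not dipeptides:
        return comp
    di = np.zeros((20, 20), dtype=float)
    for a, b in zip(seq, seq[1:]):
        di[aa_index[a], aa_index[b]] += 1
    if len(seq) > 1:
        di /= len(seq) - 1
    return np.concatenate([comp, di.ravel()])


def assemble_features(
    rows: Sequence[tuple[str, str]],
    compound_blocks: Mapping[str, Mapping[str, np.ndarray]],
    protein_blocks: Mapping[str, Mapping[str, np.ndarray]],
) -> FeatureMatrix:
    """Concatenate per-entity descriptor blocks into one design matrix.

    Parameters
    ----------
    rows
        (compound key, protein key) pairs, one per data point.
    compound_blocks, protein_blocks
        block name -> {entity key -> vector}. Compound blocks come first
        in column order, then protein blocks; ``block_index`` records the
        half-open column range of each block.
    """
    ordered: list[tuple[str, int, Mapping[str, np.ndarray]]] = []
    for name, table in compound_blocks.items():
        ordered.append((name, 0, table))
    for name, table in protein_blocks.items():
        ordered.append((name, 1, table))

    block_index: dict[str, tuple[int, int]] = {}
    col = 0
    widths: dict[str, int] = {}
    for name, _side, table in ordered:
        if not table:
            raise ValueError(f"block {name!r} has no entries")
        width = len(next(iter(table.values())))
        widths[name] = width
        block_index[name] = (col, col + width)
        col += width

    missing = [
        (name, key)
        for name, side, table in ordered
        for key in {r[side] for r in rows}
        if key not in table
    ]
    if missing:
        raise ValueError(f"missing descriptors for entities: {missing[:10]}")

    values = np.empty((len(rows), col), dtype=float)
    for i, (cmpd, prot) in enumerate(rows):
        parts = [
            np.asarray(table[(cmpd, prot)[side]], dtype=float)
            for _name, side, table in ordered
        ]
        values[i] = np.concatenate(parts) if parts else np.empty(0)
    return FeatureMatrix(values=values, rows=list(rows), block_index=block_index)
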