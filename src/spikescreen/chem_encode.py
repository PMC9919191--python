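"""SMILES standardization, binary fingerprints, similarity, class balancing.

Molecules arrive as SMILES strings with binary activity labels
(MoleculeNet-style CSV). They are standardized (functional-group
normalization, canonicalization) and encoded as fixed-length bit vectors:
the 166 public MACCS keys, or extended-connectivity (Morgan) fingerprints
of configurable radius and length. Dataset heterogeneity is measured by
the Jaccard-Tanimoto index, and class imbalance is corrected by
oversampling the minority class with replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty on malformed SMILES; parse failures are reported by us.
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"could not parse SMILES: {smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: a SMILES string and a binary activity label."""

    smiles: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class FingerprintDataset:
    """An n_samples x n_bits binary matrix with per-row class labels."""

    bits: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        if self.labels.shape != (self.bits.shape[0],):
            raise ValueError("labels length must equal the number of rows")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]


@dataclass
class LoadReport:
    """Accounting of a table load: rows kept and rows skipped with reasons."""

    n_loaded: int = 0
    n_skipped: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_loaded": self.n_loaded,
            "n_skipped": self.n_skipped,
            "skipped": [{"row": i, "reason": r} for i, r in self.skipped],
        }


def load_smiles_table(
    path,
    smiles_column: str = "smiles",
    label_column: str = "label",
) -> tuple[list[MoleculeRecord], LoadReport]:
    """Read a CSV of SMILES and binary labels into molecule records.

    Rows with a missing or non-binary label, or a missing SMILES cell, are
    skipped and counted in the returned :class:`LoadReport` rather than
    aborting the load. Row order is preserved.
    """
    df = pd.read_csv(path)
    for col in (smiles_column, label_column):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")

    records: list[MoleculeRecord] = []
    report = LoadReport()
    for i, (smi, lab) in enumerate(zip(df[smiles_column], df[label_column])):
        if pd.isna(smi) or (isinstance(smi, str) and not smi.strip()):
            report.skipped.append((i, "missing SMILES"))
            continue
        if pd.isna(lab):
            report.skipped.append((i, "missing label"))
            continue
        try:
            lab_int = int(float(lab))
        except (TypeError, ValueError):
            report.skipped.append((i, f"unparseable label {lab!r}"))
            continue
        if lab_int not in (0, 1):
            report.skipped.append((i, f"non-binary label {lab!r}"))
            continue
        records.append(MoleculeRecord(smiles=str(smi), label=lab_int))
    report.n_loaded = len(records)
    report.n_skipped = len(report.skipped)
    if report.n_skipped:
        logger.info(
            "loaded %d records, skipped %d rows", report.n_loaded, report.n_skipped
        )
    if not records:
        raise ValueError(f"no usable rows in {path}")
    return records, report


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def standardize_molecule(smiles: str) -> str:
    """Return the canonical standardized SMILES for a molecule.

    Cleanup (sanitization, removal of explicit hydrogens) and normalization
    of functional groups are applied before canonicalization, so chemically
    equivalent inputs map to one string. The operation is idempotent.
    """
    mol = _mol_from_smiles(smiles)
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.Normalize(mol)
    return Chem.MolToSmiles(mol)


def encode_maccs(smiles: str) -> np.ndarray:
    """Encode a SMILES string as the 166 public MACCS keys.

    RDKit emits a 167-bit vector whose bit 0 is a never-set placeholder;
    it is stripped so the output is exactly the 166 keyed bits.
    """
    mol = _mol_from_smiles(standardize_molecule(smiles))
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(fp.GetNumBits(), dtype=np.int8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr[1:]  # drop placeholder bit 0 -> length 166


def encode_ecfp(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Encode a SMILES string as a hashed extended-connectivity fingerprint."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_smiles(standardize_molecule(smiles))
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.int8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def encode_dataset(
    records: list[MoleculeRecord],
    fingerprint: str = "maccs",
    radius: int = 2,
    n_bits: int = 1024,
) -> tuple[FingerprintDataset, LoadReport]:
    """Fingerprint a list of records, skipping unparseable molecules."""
    if fingerprint not in ("maccs", "ecfp"):
        raise ValueError(f"unknown fingerprint type {fingerprint!r}")
    rows, labels = [], []
    report = LoadReport()
    for i, rec in enumerate(records):
        try:
            if fingerprint == "maccs":
                rows.append(encode_maccs(rec.smiles))
            else:
                rows.append(encode_ecfp(rec.smiles, radius=radius, n_bits=n_bits))
            labels.append(rec.label)
        except SmilesParseError as exc:
            report.skipped.append((i, str(exc)))
            logger.warning("skipping record %d: %s", i, exc)
    report.n_loaded = len(rows)
    report.n_skipped = len(report.skipped)
    if not rows:
        raise ValueError("no molecule could be fingerprinted")
    return FingerprintDataset(np.stack(rows), np.array(labels)), report


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard-Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Two all-zero vectors have an empty union; their similarity is defined
    as 0 and a warning is emitted.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn(
            "Tanimoto of two all-zero vectors is undefined; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def mean_pairwise_tanimoto(dataset: FingerprintDataset) -> float:
    """Mean Tanimoto similarity over all unordered distinct row pairs."""
    X = dataset.bits.astype(np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    # |a AND b| = a.b for binary rows; |a OR b| = |a| + |b| - |a AND b|
    inter = X @ X.T
    row_sums = X.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    iu = np.triu_indices(n, k=1)
    inter_p, union_p = inter[iu], union[iu]
    sims = np.zeros_like(inter_p)
    nz = union_p > 0
    sims[nz] = inter_p[nz] / union_p[nz]
    if (~nz).any():
        warnings.warn(
            "pairs of all-zero fingerprints counted as similarity 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(sims.mean())


def oversample_minority(
    records: list[MoleculeRecord], seed: int
) -> list[MoleculeRecord]:
    """Equalize class counts by sampling minority records with replacement.

    The returned list contains every input record plus uniformly drawn
    duplicates of minority-class records until both classes reach the
    original majority count. A balanced input is returned unchanged.
    """
    labels = np.array([r.label for r in records])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return list(records)
    minority = 1 if n_pos < n_neg else 0
    deficit = abs(n_neg - n_pos)
    pool = [r for r in records if r.label == minority]
    rng = np.random.default_rng(seed)
    extra = [pool[i] for i in rng.integers(0, len(pool), size=deficit)]
    return list(records) + extra


def oversample_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    """Index-level analogue of :func:`oversample_minority` for bit matrices.

    Returns indices into ``labels`` such that selecting them yields the
    original rows followed by with-replacement minority duplicates.
    """
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    base = np.arange(len(labels))
    if n_pos == n_neg:
        return base
    minority = 1 if n_pos < n_neg else 0
    pool = np.flatnonzero(labels == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(pool, size=abs(n_neg - n_pos), replace=True)
    return np.concatenate([base, extra])
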