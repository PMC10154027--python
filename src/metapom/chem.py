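"""Molecule standardization, circular fingerprints and pairwise distances.

The standardization filter keeps small, single-fragment HCNOS molecules —
the population of plausible odorants on which every downstream stage
(metabolic-distance correlation, pathway smoothness, co-occurrence) is run.
Three distance conventions are used throughout the pipeline:

* Tanimoto distance between bit (binary) circular fingerprints,
* L1 ("edit") distance between count circular fingerprints,
* correlation distance (1 − Pearson across coordinates) between embedding
  vectors that have been centered per dimension over the analysis population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements allowed by the standardization filter.
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "S"})

#: Molecules strictly heavier than this (average MW, daltons) are rejected.
MAX_MOL_WEIGHT = 500.0

#: Rejection reasons, in the order the rules are checked.
REJECT_REASONS = ("unparseable", "mixture", "single_atom", "disallowed_element", "too_heavy")


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule and its pass/fail provenance."""

    key: str
    smiles: str
    element_set: frozenset[str] = frozenset()
    heavy_atom_count: int = 0
    mol_weight: float = 0.0
    passed: bool = False
    reject_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.passed != (self.reject_reason is None):
            raise ValueError("passed must be true iff reject_reason is absent")


@dataclass(frozen=True)
class BitFingerprint:
    bits: np.ndarray
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        if int(self.bits.sum()) > self.n_bits:
            raise ValueError("popcount exceeds n_bits")


@dataclass(frozen=True)
class CountFingerprint:
    counts: np.ndarray
    dim: int
    radius: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def parse_and_standardize(smiles: str, key: Optional[str] = None) -> MoleculeRecord:
    """Parse a SMILES and apply the odorant standardization filter.

    Rules are checked in a fixed order and the first failure is recorded:
    unparseable, mixture (more than one disconnected fragment), single heavy
    atom, an element outside {H, C, N, O, S}, average molecular weight
    strictly above 500 Da.  Failures are encoded in the returned record,
    never raised.
    """
    if not smiles:
        raise ValueError("smiles must be a non-empty string")
    key = key if key is not None else smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return MoleculeRecord(key=key, smiles=smiles, passed=False, reject_reason="unparseable")

    canonical = Chem.MolToSmiles(mol)
    elements = {atom.GetSymbol() for atom in mol.GetAtoms()}
    if any(atom.GetTotalNumHs() > 0 for atom in mol.GetAtoms()):
        elements.add("H")
    heavy = mol.GetNumHeavyAtoms()
    weight = Descriptors.MolWt(mol)

    reason: Optional[str] = None
    if len(Chem.GetMolFrags(mol)) > 1:
        reason = "mixture"
    elif heavy == 1:
        reason = "single_atom"
    elif not elements <= ALLOWED_ELEMENTS:
        reason = "disallowed_element"
    elif weight > MAX_MOL_WEIGHT:
        reason = "too_heavy"

    return MoleculeRecord(
        key=key,
        smiles=canonical,
        element_set=frozenset(elements),
        heavy_atom_count=heavy,
        mol_weight=weight,
        passed=reason is None,
        reject_reason=reason,
    )


def standardize_dataset(
    smiles_list: Sequence[str],
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Partition SMILES into (kept, rejected) records, preserving order."""
    kept: list[MoleculeRecord] = []
    rejected: list[MoleculeRecord] = []
    for smi in smiles_list:
        rec = parse_and_standardize(smi)
        (kept if rec.passed else rejected).append(rec)
    return kept, rejected


def _mol_for(record: MoleculeRecord) -> Chem.Mol:
    if not record.passed:
        raise ValueError(f"molecule {record.key!r} failed standardization ({record.reject_reason})")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # pragma: no cover - passed records are parseable
        raise ValueError(f"cannot re-parse {record.smiles!r}")
    return mol


def count_fingerprint(record: MoleculeRecord, radius: int = 2, dim: int = 2048) -> CountFingerprint:
    """Hashed Morgan/circular count fingerprint (cFP) of a standardized molecule."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=dim)
    counts = np.asarray(gen.GetCountFingerprintAsNumPy(_mol_for(record)), dtype=np.int64)
    return CountFingerprint(counts=counts, dim=dim, radius=radius)


def bit_fingerprint(record: MoleculeRecord, radius: int = 2, n_bits: int = 2048) -> BitFingerprint:
    """Hashed Morgan/circular bit fingerprint (bFP): support indicator of the cFP."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.asarray(gen.GetFingerprintAsNumPy(_mol_for(record)), dtype=np.int8)
    return BitFingerprint(bits=bits, n_bits=n_bits, radius=radius)


def tanimoto_distance(a, b) -> float:
    """1 − Jaccard similarity of the two bit supports; 0 if both are empty."""
    va, na = _as_bits(a)
    vb, nb = _as_bits(b)
    if na != nb:
        raise ValueError(f"bit lengths differ: {na} != {nb}")
    inter = int(np.sum((va > 0) & (vb > 0)))
    union = int(np.sum((va > 0) | (vb > 0)))
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def cfp_edit_distance(a, b) -> float:
    """L1 distance between two count fingerprints of equal dimension."""
    va, da = _as_counts(a)
    vb, db = _as_counts(b)
    if da != db:
        raise ValueError(f"dimensions differ: {da} != {db}")
    return float(np.abs(va - vb).sum())


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − Pearson correlation of two vectors across their coordinates.

    Callers are expected to have centered the vectors per dimension over the
    analysis population (see :func:`center_rows`); the per-vector mean is
    still removed here as part of the Pearson formula.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("vectors must be equal-length 1-D with width >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt(np.dot(du, du))
    nv = np.sqrt(np.dot(dv, dv))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("correlation distance undefined for a constant vector")
    r = float(np.dot(du, dv) / (nu * nv))
    return 1.0 - max(-1.0, min(1.0, r))


def center_rows(table: np.ndarray) -> np.ndarray:
    """Subtract each column's mean over the molecule population (rows)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    return table - table.mean(axis=0, keepdims=True)


def _as_bits(fp) -> tuple[np.ndarray, int]:
    if isinstance(fp, BitFingerprint):
        return fp.bits, fp.n_bits
    arr = np.asarray(fp)
    return arr, arr.size


def _as_counts(fp) -> tuple[np.ndarray, int]:
    if isinstance(fp, CountFingerprint):
        return fp.counts, fp.dim
    arr = np.asarray(fp)
    return arr, arr.size
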