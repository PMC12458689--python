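"""Molecular representations and filter-based feature selection.

Five representations are supported: an extended 2D descriptor collection
(the full RDKit descriptor list), a compact 2D physicochemical/topological
collection (the 125 RDKit descriptors excluding fragment counts), 2048-bit
Morgan fingerprints of radius 2 and 3 (ECFP4 / ECFP6), and MACCS keys
(stored at width 167 with index 0 always unset, the RDKit convention).

Feature selection is a three-stage filter fitted on training data only:
drop features with missing values, drop low-variance features
(population variance < 0.1, on raw values), then scan features in their
native order and drop any whose absolute Pearson correlation with an
earlier retained feature reaches 0.9.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .errors import SelectionError, StructureError, UsageError

VARIANCE_CUTOFF = 0.1
PCC_CUTOFF = 0.9

_ALL_DESCRIPTORS = [name for name, _ in Descriptors._descList]
#: compact set: physicochemical/topological descriptors, no fragment counts
_COMPACT_DESCRIPTORS = [n for n in _ALL_DESCRIPTORS if not n.startswith("fr_")]


class RepresentationKind(str, Enum):
    DESC_EXTENDED_2D = "extended2d"
    DESC_COMPACT_2D = "compact2d"
    FP_MORGAN_R2_2048 = "ecfp4"
    FP_MORGAN_R3_2048 = "ecfp6"
    FP_MACCS = "maccs"

    @property
    def is_fingerprint(self) -> bool:
        return self in (
            RepresentationKind.FP_MORGAN_R2_2048,
            RepresentationKind.FP_MORGAN_R3_2048,
            RepresentationKind.FP_MACCS,
        )


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_compounds, n_features)
    names: list[str]
    kind: RepresentationKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise UsageError("values shape must match the feature-name list")
        if len(set(self.names)) != len(self.names):
            raise UsageError("duplicate feature names")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(self.values[:, indices], [self.names[i] for i in indices], self.kind)

    def rows(self, row_indices) -> "FeatureMatrix":
        return FeatureMatrix(self.values[np.asarray(row_indices, dtype=int)], self.names, self.kind)


def _mol(smiles: str, row: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"row {row}: unparsable SMILES {smiles!r}")
    return mol


def compute_representation(
    smiles_list: Sequence[str], kind: RepresentationKind
) -> FeatureMatrix:
    """Compute one molecular representation for a list of standardized SMILES.

    Deterministic per SMILES. Descriptor failures become missing values
    (NaN), never exceptions; unparsable SMILES raise a structure error
    naming the row.
    """
    kind = RepresentationKind(kind)
    mols = [_mol(s, i) for i, s in enumerate(smiles_list)]

    if kind in (RepresentationKind.DESC_EXTENDED_2D, RepresentationKind.DESC_COMPACT_2D):
        names = (
            _ALL_DESCRIPTORS
            if kind == RepresentationKind.DESC_EXTENDED_2D
            else _COMPACT_DESCRIPTORS
        )
        rows = np.empty((len(mols), len(names)), dtype=float)
        for i, mol in enumerate(mols):
            all_vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True)
            rows[i] = [all_vals[n] for n in names]
        rows[~np.isfinite(rows)] = np.nan
        return FeatureMatrix(rows, list(names), kind)

    if kind in (RepresentationKind.FP_MORGAN_R2_2048, RepresentationKind.FP_MORGAN_R3_2048):
        radius = 2 if kind == RepresentationKind.FP_MORGAN_R2_2048 else 3
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2048)
        rows = np.array([gen.GetFingerprintAsNumPy(m) for m in mols], dtype=float)
        rows = rows.reshape(len(mols), 2048)
        names = [f"morgan_r{radius}_{i}" for i in range(2048)]
        return FeatureMatrix(rows, names, kind)

    # MACCS: 167 bits, bit 0 unset by convention
    arrs = []
    for mol in mols:
        fp = MACCSkeys.GenMACCSKeys(mol)
        arrs.append(np.array(fp, dtype=float))
    rows = np.array(arrs).reshape(len(mols), 167)
    return FeatureMatrix(rows, [f"maccs_{i}" for i in range(167)], kind)


def morgan_bitvects(smiles_list: Sequence[str], radius: int = 2, n_bits: int = 2048):
    """RDKit explicit bit vectors (for Tanimoto / embedding utilities)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return [gen.GetFingerprint(_mol(s, i)) for i, s in enumerate(smiles_list)]


@dataclass
class SelectionReport:
    dropped_missing: list[str]
    dropped_low_variance: list[str]
    dropped_correlated: list[tuple[str, str]]  # (removed, kept partner)
    retained: list[str]

    def partition_ok(self, original: Sequence[str]) -> bool:
        removed = (
            self.dropped_missing
            + self.dropped_low_variance
            + [r for r, _ in self.dropped_correlated]
        )
        return sorted(removed + self.retained) == sorted(original)


def select_features(
    train: FeatureMatrix,
    variance_cutoff: float = VARIANCE_CUTOFF,
    pcc_cutoff: float = PCC_CUTOFF,
) -> tuple[np.ndarray, SelectionReport]:
    """Three-stage filter selection fitted on a training matrix.

    Returns the retained column indices (into the original matrix) and a
    report partitioning all original feature names. The retained index set
    is applied unchanged to any other matrix of the same kind.
    """
    X = train.values
    if X.shape[0] < 2:
        raise UsageError("feature selection needs at least two training rows")
    names = train.names

    has_missing = np.isnan(X).any(axis=0)
    dropped_missing = [names[j] for j in np.flatnonzero(has_missing)]
    stage1 = np.flatnonzero(~has_missing)

    var = X[:, stage1].var(axis=0)  # population variance on raw values
    low = var < variance_cutoff
    dropped_low_var = [names[stage1[j]] for j in np.flatnonzero(low)]
    stage2 = stage1[~low]

    dropped_corr: list[tuple[str, str]] = []
    if stage2.size:
        corr = np.corrcoef(X[:, stage2], rowvar=False)
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        kept_local: list[int] = []
        for j in range(stage2.size):
            partner = next(
                (k for k in kept_local if abs(corr[j, k]) >= pcc_cutoff), None
            )
            if partner is None:
                kept_local.append(j)
            else:
                dropped_corr.append((names[stage2[j]], names[stage2[partner]]))
        retained = stage2[kept_local]
    else:
        retained = stage2

    if retained.size == 0:
        raise SelectionError("feature selection removed every feature")

    report = SelectionReport(
        dropped_missing=dropped_missing,
        dropped_low_variance=dropped_low_var,
        dropped_correlated=dropped_corr,
        retained=[names[i] for i in retained],
    )
    return retained, report
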