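"""Curation of raw bioactivity records into standardized pActivity profiles.

Heterogeneous bioactivity tables (Ki / IC50 / Kd / EC50 values in nM with
"=" or ">" relation qualifiers, one row per measurement) are reduced to a
single pActivity value per (compound, target) pair:

1. structures are canonicalized and salt-stripped;
2. ">"-qualified records are kept only when they certify inactivity
   (value >= 10,000 nM, i.e. pActivity <= 5);
3. within each (compound, target) group, "=" records take precedence over
   ">" records, the highest-priority measure type (Ki > IC50 > Kd > EC50)
   is kept, replicates are averaged, and groups whose sample standard
   deviation reaches 20% of the mean are discarded as irreproducible;
4. the consensus concentration is converted to pActivity,
   -log10(molar) = 9 - log10(nM).
"""
from __future__ import annotations

import json
import math
import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import DomainError, StructureError, UsageError

RDLogger.DisableLog("rdApp.error")

INACTIVITY_THRESHOLD_NM = 10_000.0
SD_FRACTION = 0.20


class Target(str, Enum):
    S1R = "S1R"
    S2R = "S2R"


class Measure(str, Enum):
    KI = "Ki"
    IC50 = "IC50"
    KD = "Kd"
    EC50 = "EC50"


#: measure priority for duplicate resolution: lower index wins
MEASURE_PRIORITY = (Measure.KI, Measure.IC50, Measure.KD, Measure.EC50)


class Relation(str, Enum):
    EQUAL = "="
    GREATER = ">"


@dataclass(frozen=True)
class RawActivityRecord:
    """One measured bioactivity row."""

    smiles: str
    target: Target
    measure: Measure
    relation: Relation
    value_nM: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.smiles:
            raise UsageError("RawActivityRecord.smiles must be non-empty")
        if not (self.value_nM > 0):
            raise UsageError(f"value_nM must be positive, got {self.value_nM}")


@dataclass(frozen=True)
class CuratedRecord:
    """Consensus pActivity for one (compound, target) pair."""

    canonical_smiles: str
    target: Target
    pactivity: float
    n_merged: int
    is_bound: bool = False


class PointKind(str, Enum):
    SINGLE = "single"
    DOUBLE = "double"


@dataclass
class CompoundProfile:
    """Standardized compound with optional per-target pActivity values."""

    canonical_smiles: str
    pactivity_s1r: Optional[float] = None
    pactivity_s2r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pactivity_s1r is None and self.pactivity_s2r is None:
            raise UsageError("profile needs at least one pActivity value")

    @property
    def point_kind(self) -> PointKind:
        both = self.pactivity_s1r is not None and self.pactivity_s2r is not None
        return PointKind.DOUBLE if both else PointKind.SINGLE

    def pactivity(self, target: Target) -> Optional[float]:
        return self.pactivity_s1r if target == Target.S1R else self.pactivity_s2r


class _Discarded:
    """Sentinel for duplicate groups rejected by the 20%-SD rule."""

    _instance: "_Discarded | None" = None

    def __new__(cls) -> "_Discarded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCARDED"


DISCARDED = _Discarded()


def standardize_structure(smiles: str) -> str:
    """Canonical SMILES of the largest organic fragment of ``smiles``.

    Salt stripping keeps the fragment with the most heavy atoms; ties break
    toward more carbons, then the lexicographically smallest canonical
    SMILES. Stereochemistry is preserved; no tautomer canonicalization.
    Idempotent: standardizing the output returns itself.
    """
    if not smiles or not smiles.strip():
        raise StructureError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise StructureError(f"no fragments after parsing: {smiles!r}")
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    candidates = organic or list(frags)

    def sort_key(frag: Chem.Mol):
        n_heavy = frag.GetNumHeavyAtoms()
        n_carbon = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 6)
        return (-n_heavy, -n_carbon, Chem.MolToSmiles(frag))

    best = min(candidates, key=sort_key)
    out = Chem.MolToSmiles(best)
    if not out:
        raise StructureError(f"empty structure after salt stripping: {smiles!r}")
    return out


def to_pactivity(value_nM: float) -> float:
    """pActivity = -log10 of the molar concentration = 9 - log10(nM)."""
    if not (isinstance(value_nM, (int, float)) and math.isfinite(value_nM) and value_nM > 0):
        raise DomainError(f"value_nM must be a positive finite number, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def filter_raw_records(records: Sequence[RawActivityRecord]) -> list[RawActivityRecord]:
    """Keep "=" records of any value and ">" records certifying inactivity.

    A ">"-qualified record only carries information when its value is at
    or above the 10,000 nM inactivity threshold; lower-valued ">" records
    are dropped. Order-preserving.
    """
    return [
        r
        for r in records
        if r.relation == Relation.EQUAL
        or (r.relation == Relation.GREATER and r.value_nM >= INACTIVITY_THRESHOLD_NM)
    ]


def aggregate_duplicates(
    records: Sequence[RawActivityRecord],
) -> Union[CuratedRecord, _Discarded]:
    """Collapse replicate records for one (compound, target) into a consensus.

    Steps: (1) "=" records take precedence; a group with only ">" records
    keeps the single highest value (conservative bound, ``is_bound``);
    (2) only the highest-priority measure type present survives
    (Ki > IC50 > Kd > EC50); (3) survivors are averaged, and the group is
    DISCARDED when the sample SD reaches 20% of the mean; (4) the consensus
    is converted to pActivity. Permutation invariant.
    """
    if not records:
        raise UsageError("aggregate_duplicates requires a non-empty group")
    smiles = records[0].smiles
    target = records[0].target
    if any(r.smiles != smiles or r.target != target for r in records):
        raise UsageError("all records in a group must share one compound and target")

    equals = [r for r in records if r.relation == Relation.EQUAL]
    if equals:
        survivors = equals
        is_bound = False
    else:
        survivors = [max(records, key=lambda r: r.value_nM)]
        is_bound = True

    best_measure = min(survivors, key=lambda r: MEASURE_PRIORITY.index(r.measure)).measure
    survivors = [r for r in survivors if r.measure == best_measure]

    # sort so the consensus is bit-identical under input permutation
    values = sorted(r.value_nM for r in survivors)
    if len(values) > 1:
        mean = statistics.fmean(values)
        sd = statistics.stdev(values)
        if sd >= SD_FRACTION * mean:
            return DISCARDED
        consensus = mean
    else:
        consensus = values[0]

    return CuratedRecord(
        canonical_smiles=smiles,
        target=target,
        pactivity=to_pactivity(consensus),
        n_merged=len(values),
        is_bound=is_bound,
    )


@dataclass
class CurationLog:
    """Counts of records and compounds at each curation stage."""

    n_input: int = 0
    n_structure_errors: int = 0
    n_relation_filtered: int = 0
    n_groups: int = 0
    n_discarded_sd: int = 0
    n_curated_records: int = 0
    n_profiles: int = 0
    structure_error_rows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CurationResult:
    profiles: list[CompoundProfile]
    records: list[CuratedRecord]
    log: CurationLog


def curate(records: Sequence[RawActivityRecord]) -> CurationResult:
    """Full curation: standardize -> filter -> group -> aggregate -> profile.

    Structure errors skip the offending row (logged), they do not abort.
    A (compound, target) group discarded by the SD rule removes that pair
    only; a compound discarded for both targets is absent from the output.
    """
    log = CurationLog(n_input=len(records))
    standardized: list[RawActivityRecord] = []
    for i, rec in enumerate(records):
        try:
            smi = standardize_structure(rec.smiles)
        except StructureError:
            log.n_structure_errors += 1
            log.structure_error_rows.append((i, rec.smiles))
            continue
        standardized.append(
            RawActivityRecord(smi, rec.target, rec.measure, rec.relation, rec.value_nM, rec.source)
        )

    kept = filter_raw_records(standardized)
    log.n_relation_filtered = len(standardized) - len(kept)

    groups: dict[tuple[str, Target], list[RawActivityRecord]] = defaultdict(list)
    for rec in kept:
        groups[(rec.smiles, rec.target)].append(rec)
    log.n_groups = len(groups)

    curated: list[CuratedRecord] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value)):
        result = aggregate_duplicates(groups[key])
        if result is DISCARDED:
            log.n_discarded_sd += 1
        else:
            curated.append(result)  # type: ignore[arg-type]
    log.n_curated_records = len(curated)

    by_compound: dict[str, dict[Target, float]] = defaultdict(dict)
    for rec in curated:
        by_compound[rec.canonical_smiles][rec.target] = rec.pactivity
    profiles = [
        CompoundProfile(
            canonical_smiles=smi,
            pactivity_s1r=vals.get(Target.S1R),
            pactivity_s2r=vals.get(Target.S2R),
        )
        for smi, vals in sorted(by_compound.items())
    ]
    log.n_profiles = len(profiles)
    return CurationResult(profiles=profiles, records=curated, log=log)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_raw_csv(path) -> list[RawActivityRecord]:
    """Read a raw bioactivity table: smiles,target,measure,relation,value_nm,source."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"smiles", "target", "measure", "relation", "value_nm"}
    missing = required - set(df.columns)
    if missing:
        raise UsageError(f"raw CSV missing columns: {sorted(missing)}")
    measure_lookup = {m.value.lower(): m for m in Measure}
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RawActivityRecord(
                smiles=row.smiles,
                target=Target(row.target),
                measure=measure_lookup[str(row.measure).lower()],
                relation=Relation(row.relation),
                value_nM=float(row.value_nm),
                source=getattr(row, "source", ""),
            )
        )
    return records


def write_curated_csv(records: Sequence[CuratedRecord], path) -> None:
    df = pd.DataFrame(
        {
            "canonical_smiles": [r.canonical_smiles for r in records],
            "target": [r.target.value for r in records],
            "pactivity": [r.pactivity for r in records],
            "n_merged": [r.n_merged for r in records],
            "is_bound": [r.is_bound for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_curated_csv(path) -> list[CompoundProfile]:
    df = pd.read_csv(path)
    by_compound: dict[str, dict[Target, float]] = defaultdict(dict)
    for row in df.itertuples(index=False):
        by_compound[row.canonical_smiles][Target(row.target)] = float(row.pactivity)
    return [
        CompoundProfile(smi, vals.get(Target.S1R), vals.get(Target.S2R))
        for smi, vals in sorted(by_compound.items())
    ]


def write_curation_log(log: CurationLog, path) -> None:
    with open(path, "w") as fh:
        json.dump(log.to_dict(), fh, indent=2)
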