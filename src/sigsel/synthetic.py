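"""Synthetic two-target bioactivity data with known ground truth.

A fragment grammar (aryl heads x alkyl/ether linkers x amine tails, one
basic nitrogen per scaffold — the classic sigma-ligand chemotype) builds a
library of valid, standardized, unique SMILES. Latent per-target activity
scores are deterministic linear functions of computed 2D properties, with
distinct weightings per target, so subtype selectivity is a learnable
function of structure. Compounds are assigned to cohorts
(S1R-/S2R-selective, nonselective, nonbinder, single-point) by quantiles
of those latent scores — the requested class mix is hit exactly and the
class remains structure-determined — and true pActivities are placed in
the corresponding label region with property-driven within-class spread.
Gaussian noise of sd ``noise_sd`` is then added per measured target.

``emit_raw_records`` inverts curation: pActivities become nM values,
optionally expanded into mean-preserving jittered replicates (which pass
the 20% SD rule) or, for inactive measurements, ">"-qualified bounds. At
``noise_sd = 0`` with no conflict flags the full round trip
emit -> curate -> label reproduces the truth table exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy.special import expit

from .curation import (
    CompoundProfile,
    Measure,
    RawActivityRecord,
    Relation,
    Target,
    standardize_structure,
)
from .errors import GenerationError, UsageError
from .labeling import SelectivityClass

_HEAD_SUBS = ["", "F", "Cl", "Br", "C", "CO", "O", "FC(F)(F)", "CC", "N#C"]
_HEADS = (
    [f"{s}c1ccc(cc1)" for s in _HEAD_SUBS]
    + [f"{s}c1cccc(c1)" for s in _HEAD_SUBS if s]
    + ["c1ccc2ccccc2c1", "c1ccncc1", "c1ccc(cc1)c1ccc(cc1)", "c1cccs1"]
)
_LINKERS = ["C", "CC", "CCC", "CCCC", "CC(C)", "COC", "CCOC", "C(=O)C", "CCCCC", "CC(O)"]
_AMINES = [
    "N(C)C",
    "N(CC)CC",
    "N1CCCCC1",
    "N1CCCC1",
    "N1CCOCC1",
    "N(C)Cc1ccccc1",
    "NC1CCCCC1",
    "N2CCC(O)CC2",
    "N(C)CCO",
    "NC(C)C",
]


class Cohort(str, Enum):
    S1R_SELECTIVE = "S1R_SELECTIVE"
    S2R_SELECTIVE = "S2R_SELECTIVE"
    NONSELECTIVE = "NONSELECTIVE"
    NONBINDER = "NONBINDER"
    SINGLE_S1R = "SINGLE_S1R"
    SINGLE_S2R = "SINGLE_S2R"


DEFAULT_CLASS_MIX = {
    Cohort.S1R_SELECTIVE: 0.08,
    Cohort.S2R_SELECTIVE: 0.09,
    Cohort.NONSELECTIVE: 0.33,
    Cohort.NONBINDER: 0.10,
    Cohort.SINGLE_S1R: 0.25,
    Cohort.SINGLE_S2R: 0.15,
}

#: Ki-dominated measure mix, echoing curated sigma-receptor data
MEASURE_MIX = ((Measure.KI, 0.843), (Measure.IC50, 0.152), (Measure.KD, 0.005))


@dataclass
class SyntheticConfig:
    n_compounds: int = 1500
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    noise_sd: float = 0.3
    duplicate_rate: float = 0.3
    bound_record_rate: float = 0.3
    boundary_buffer: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_mix = {Cohort(k): float(v) for k, v in self.class_mix.items()}
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6 or any(v < 0 for v in self.class_mix.values()):
            raise UsageError("class_mix proportions must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")
        if self.boundary_buffer < 0:
            raise UsageError("boundary_buffer must be >= 0")
        for name in ("duplicate_rate", "bound_record_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise UsageError(f"{name} must be in [0, 1]")


def enumerate_library() -> list[str]:
    """All unique standardized SMILES the fragment grammar can produce."""
    seen: dict[str, None] = {}
    for head in _HEADS:
        for linker in _LINKERS:
            for amine in _AMINES:
                smi = head + linker + amine
                mol = Chem.MolFromSmiles(smi)
                if mol is None:  # pragma: no cover - grammar is validated by tests
                    continue
                seen.setdefault(standardize_structure(smi), None)
    return list(seen)


def _property_scores(smiles: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Latent per-target activity scores from z-scored 2D properties."""
    from rdkit.Chem import GraphDescriptors

    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        rows.append(
            [
                Crippen.MolLogP(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcNumAromaticRings(mol),
                Descriptors.MolWt(mol),
                rdMolDescriptors.CalcNumRotatableBonds(mol),
                sum(a.GetAtomicNum() in (9, 17, 35) for a in mol.GetAtoms()),
                rdMolDescriptors.CalcNumHBA(mol),
                rdMolDescriptors.CalcNumRings(mol),
                # topological terms distinguish positional isomers, so the
                # latent scores are (near-)injective over the grammar
                GraphDescriptors.BalabanJ(mol),
                GraphDescriptors.Chi1v(mol),
                GraphDescriptors.Kappa2(mol),
            ]
        )
    P = np.asarray(rows, dtype=float)
    sd = P.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (P - P.mean(axis=0)) / sd
    # S1R binding favors compact basic amines: moderate logP, low polarity;
    # S2R favors lipophilic, halogen-rich, bulky aromatics
    w1 = np.array([0.6, -0.8, 0.4, -0.3, 0.3, -0.5, -0.4, 0.3, 0.4, -0.3, 0.2])
    w2 = np.array([0.9, -0.3, 0.7, 0.6, -0.2, 1.0, 0.1, 0.5, -0.2, 0.4, 0.5])
    return Z @ w1, Z @ w2


def _counts_from_mix(n: int, mix: dict) -> dict:
    """Largest-remainder apportionment of n compounds over the cohorts."""
    cohorts = list(Cohort)
    raw = np.array([n * mix.get(c, 0.0) for c in cohorts])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(cohorts)]] += 1
    return dict(zip(cohorts, counts.tolist()))


def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Mid-ranks mapped to (0, 1); empty-safe."""
    m = values.size
    if m == 0:
        return values.astype(float)
    ranks = np.empty(m)
    ranks[np.argsort(values, kind="stable")] = np.arange(m)
    return (ranks + 0.5) / m


def generate_library(
    config: SyntheticConfig,
) -> tuple[list[CompoundProfile], pd.DataFrame]:
    """Generate profiles (with measurement noise) and the noiseless truth table.

    Classes are carved by quantiles of the latent structure scores. To keep
    them separable in structure space, a buffer of candidates nearest each
    class cut (``boundary_buffer`` of n per cut, three cuts) is drawn and
    discarded, and the pActivity surfaces leave a margin around both
    decision thresholds (activity 5.0, selectivity gap 2.0). Measurement
    noise can still cross those margins, as in real assay data.
    """
    pool = enumerate_library()
    n = config.n_compounds
    g = max(2, round(config.boundary_buffer * n))  # buffer per class cut
    need = n + 3 * g
    if need > len(pool):
        raise GenerationError(
            f"grammar yields {len(pool)} unique compounds; {need} needed "
            f"({n} requested plus 3x{g} boundary buffer)"
        )
    rng = np.random.default_rng(config.seed)
    smiles_all = [pool[i] for i in rng.permutation(len(pool))[:need]]
    s1, s2 = _property_scores(smiles_all)
    counts = _counts_from_mix(n, config.class_mix)
    n_single1 = counts[Cohort.SINGLE_S1R]
    n_single2 = counts[Cohort.SINGLE_S2R]
    n_singles = n_single1 + n_single2

    # Geometric regions over ALL compounds (singles are later just hidden
    # measurements of the same consistent map, so single- and double-point
    # labels never contradict each other in structure space). Singles are
    # spread over the regions in proportion to the double-point class mix.
    geo_doubles = {
        Cohort.S1R_SELECTIVE: counts[Cohort.S1R_SELECTIVE],
        Cohort.NONBINDER: counts[Cohort.NONBINDER],
        Cohort.NONSELECTIVE: counts[Cohort.NONSELECTIVE],
        Cohort.S2R_SELECTIVE: counts[Cohort.S2R_SELECTIVE],
    }
    n_doubles = sum(geo_doubles.values())
    regions = list(geo_doubles)
    raw = np.array([n_singles * geo_doubles[c] / max(n_doubles, 1) for c in regions])
    singles_share = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - singles_share))[: n_singles - singles_share.sum()]:
        singles_share[i] += 1
    geo_total = {c: geo_doubles[c] + int(s) for c, s in zip(regions, singles_share)}

    # Candidates ordered by the latent selectivity score d = s1 - s2:
    # [ S1R-selective | buffer | middle | buffer | S2R-selective ]; the
    # middle splits by the latent activity score a = s1 + s2 into
    # [ nonbinders | buffer | nonselective ]. Buffer candidates are dropped.
    d_all = s1 - s2
    order = np.argsort(-d_all, kind="stable")
    n_sel1 = geo_total[Cohort.S1R_SELECTIVE]
    n_sel2 = geo_total[Cohort.S2R_SELECTIVE]
    sel1 = order[:n_sel1]
    sel2 = order[len(order) - n_sel2:] if n_sel2 else order[:0]
    middle = order[n_sel1 + g: len(order) - n_sel2 - g]
    a = s1[middle] + s2[middle]
    mid_by_activity = middle[np.argsort(a, kind="stable")]
    nonbinders = mid_by_activity[: geo_total[Cohort.NONBINDER]]
    nonsel = mid_by_activity[geo_total[Cohort.NONBINDER] + g:]
    if len(nonsel) != geo_total[Cohort.NONSELECTIVE]:  # pragma: no cover
        raise GenerationError("cohort assignment failed to cover the class mix")
    region_members = {
        Cohort.S1R_SELECTIVE: sel1,
        Cohort.S2R_SELECTIVE: sel2,
        Cohort.NONBINDER: nonbinders,
        Cohort.NONSELECTIVE: nonsel,
    }

    p1 = np.full(need, np.nan)
    p2 = np.full(need, np.nan)
    g1, g2 = expit(s1), expit(s2)

    # selective regions: potent on the primary target (8.2..8.8), gap
    # 2.3..2.9 growing away from the nonselective boundary, counterpart
    # still active (>= 5.3) so per-target activity has a single smooth
    # boundary at the nonbinder cut
    for region, own_first in ((Cohort.S1R_SELECTIVE, True), (Cohort.S2R_SELECTIVE, False)):
        idx_set = region_members[region]
        if idx_set.size == 0:
            continue
        dd = s1[idx_set] - s2[idx_set]
        u = _rank_unit(dd if own_first else -dd)  # distance from the boundary
        gap = 2.3 + 0.6 * u
        own = 8.2 + 0.6 * (g1[idx_set] if own_first else g2[idx_set])
        other = own - gap  # in (5.3, 7.1): active on the counterpart too
        p1[idx_set] = own if own_first else other
        p2[idx_set] = other if own_first else own

    if nonsel.size:
        # both targets >= 5.3 (never straddles the activity threshold);
        # |gap| <= 1.95 stays inside the selectivity threshold
        base = 5.3 + 2.2 * expit((s1[nonsel] + s2[nonsel]) / 2)
        delta = 1.95 * (2 * _rank_unit(s1[nonsel] - s2[nonsel]) - 1)
        p1[nonsel] = base + np.abs(delta) / 2 + delta / 2
        p2[nonsel] = base + np.abs(delta) / 2 - delta / 2
    if nonbinders.size:
        p1[nonbinders] = 3.0 + 1.7 * g1[nonbinders]
        p2[nonbinders] = 3.0 + 1.7 * g2[nonbinders]

    # designate singles: within each region a random subset loses one
    # measurement; which target stays measured is assigned at random
    cohort = np.empty(need, dtype=object)
    single_pool: list[int] = []
    for region, members in region_members.items():
        cohort[members] = region
        share = geo_total[region] - geo_doubles[region]
        if share:
            chosen = rng.choice(members, size=share, replace=False)
            single_pool.extend(int(i) for i in chosen)
    single_pool = np.array(sorted(single_pool), dtype=int)
    single_pool = single_pool[rng.permutation(len(single_pool))]
    for i in single_pool[:n_single1]:
        cohort[i] = Cohort.SINGLE_S1R
        p2[i] = np.nan
    for i in single_pool[n_single1:]:
        cohort[i] = Cohort.SINGLE_S2R
        p1[i] = np.nan

    kept = np.flatnonzero(cohort != None)  # noqa: E711
    if kept.size != n:  # pragma: no cover
        raise GenerationError(f"assignment kept {kept.size} of {n} compounds")
    smiles = [smiles_all[i] for i in kept]
    cohort, p1, p2 = cohort[kept], p1[kept], p2[kept]

    truth = pd.DataFrame(
        {
            "canonical_smiles": smiles,
            "cohort": [c.value for c in cohort],
            "true_pactivity_s1r": p1,
            "true_pactivity_s2r": p2,
        }
    )
    truth["selectivity"] = [
        SelectivityClass.UNDEFINED.value
        if np.isnan(a) or np.isnan(b)
        else _true_selectivity(a, b)
        for a, b in zip(p1, p2)
    ]

    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    noise1 = noise_rng.normal(0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    noise2 = noise_rng.normal(0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    profiles = []
    for i, smi in enumerate(smiles):
        profiles.append(
            CompoundProfile(
                canonical_smiles=smi,
                pactivity_s1r=None if np.isnan(p1[i]) else float(p1[i] + noise1[i]),
                pactivity_s2r=None if np.isnan(p2[i]) else float(p2[i] + noise2[i]),
            )
        )
    return profiles, truth


def _true_selectivity(a: float, b: float) -> str:
    from .labeling import selectivity_class

    return selectivity_class(float(a), float(b)).value


def emit_raw_records(
    profiles: Sequence[CompoundProfile],
    config: SyntheticConfig,
    conflict_smiles: Optional[set] = None,
) -> list[RawActivityRecord]:
    """Convert profiles back into raw bioactivity rows.

    Each measured (compound, target) yields one "=" record at
    10^(9 - pActivity) nM, or, with probability ``duplicate_rate``, 2-4
    mean-preserving jittered replicates (small enough to pass the 20% SD
    rule). Inactive measurements become ">"-qualified bounds at their own
    concentration (>= the 10,000 nM threshold) with probability
    ``bound_record_rate``. Compounds in ``conflict_smiles`` get replicates
    whose SD breaches the 20% rule, so curation discards them.
    Deterministic under the config seed.
    """
    conflict_smiles = conflict_smiles or set()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    records: list[RawActivityRecord] = []
    measures = [m for m, _ in MEASURE_MIX]
    probs = np.array([p for _, p in MEASURE_MIX])
    probs = probs / probs.sum()
    for prof in profiles:
        for target, p in ((Target.S1R, prof.pactivity_s1r), (Target.S2R, prof.pactivity_s2r)):
            if p is None:
                continue
            value = 10.0 ** (9.0 - p)
            measure = measures[rng.choice(len(measures), p=probs)]
            if prof.canonical_smiles in conflict_smiles:
                for f in (0.5, 1.0, 1.5):
                    records.append(
                        RawActivityRecord(
                            prof.canonical_smiles, target, measure, Relation.EQUAL, value * f, "synthetic"
                        )
                    )
                continue
            if p <= 5.0 and rng.random() < config.bound_record_rate:
                records.append(
                    RawActivityRecord(
                        prof.canonical_smiles, target, measure, Relation.GREATER, value, "synthetic"
                    )
                )
                continue
            k = 1
            if rng.random() < config.duplicate_rate:
                k = int(rng.integers(2, 5))
            if k == 1:
                values = [value]
            else:
                jitter = 1.0 + rng.uniform(-0.08, 0.08, size=k)
                jitter = jitter / jitter.mean()  # mean-preserving
                values = (value * jitter).tolist()
            for v in values:
                records.append(
                    RawActivityRecord(
                        prof.canonical_smiles, target, measure, Relation.EQUAL, v, "synthetic"
                    )
                )
    return records
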