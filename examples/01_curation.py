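"""Curate a messy bioactivity table into standardized pActivity profiles.

Builds a small raw table by hand — replicates, mixed measure types, a ">"
qualifier, a salt form, and an irreproducible group — then shows what the
curation rules do with it.
"""
from sigsel import Measure, RawActivityRecord, Relation, Target, curate

rows = [
    # three Ki replicates for one compound: averaged (SD < 20% of mean)
    RawActivityRecord("c1ccccc1CCN(C)C", Target.S1R, Measure.KI, Relation.EQUAL, 100, "src_a"),
    RawActivityRecord("c1ccccc1CCN(C)C", Target.S1R, Measure.KI, Relation.EQUAL, 110, "src_b"),
    RawActivityRecord("c1ccccc1CCN(C)C", Target.S1R, Measure.KI, Relation.EQUAL, 130, "src_b"),
    # an IC50 for the same pair: outranked by the Ki records above
    RawActivityRecord("c1ccccc1CCN(C)C", Target.S1R, Measure.IC50, Relation.EQUAL, 400, "src_c"),
    # same compound as a hydrochloride salt, measured on the other target
    RawActivityRecord("c1ccccc1CCN(C)C.Cl", Target.S2R, Measure.KI, Relation.EQUAL, 2500, "src_a"),
    # a '>' record certifying inactivity (kept, conservative bound)
    RawActivityRecord("CCN1CCCCC1", Target.S1R, Measure.KI, Relation.GREATER, 10_000, "src_a"),
    # a '>' record below the inactivity threshold: dropped, uninformative
    RawActivityRecord("CCN1CCCCC1", Target.S2R, Measure.KI, Relation.GREATER, 500, "src_a"),
    # an irreproducible duplicate group (SD >= 20% of mean): discarded
    RawActivityRecord("COc1ccccc1CN(C)C", Target.S1R, Measure.KI, Relation.EQUAL, 10, "src_a"),
    RawActivityRecord("COc1ccccc1CN(C)C", Target.S1R, Measure.KI, Relation.EQUAL, 1000, "src_b"),
]

result = curate(rows)
print("curation log:", result.log.to_dict())
for rec in result.records:
    print(f"{rec.canonical_smiles:24s} {rec.target.value}  pActivity={rec.pactivity:6.3f}"
          f"  merged={rec.n_merged}  bound={rec.is_bound}")
for prof in result.profiles:
    print(f"{prof.canonical_smiles:24s} -> {prof.point_kind.value} point")

# The phenethylamine keeps the Ki consensus (mean 113.3 nM -> pActivity 6.95)
# on S1R and the salt-stripped S2R record makes it a double point; the '>'
# at 10,000 nM becomes pActivity 5.0 flagged as a bound; the 10-vs-1000 nM
# group is discarded as irreproducible.
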