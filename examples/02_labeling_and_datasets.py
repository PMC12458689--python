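"""From pActivity profiles to selectivity labels and the six task datasets.

Generates a small synthetic library, labels it, splits off the external
validation set, and prints the composition of each dataset.
"""
from collections import Counter

from sigsel import (
    SyntheticConfig, build_dataset, extract_external_set, generate_library,
    profile_selectivity,
)

profiles, truth = generate_library(SyntheticConfig(n_compounds=400, seed=3))
print("selectivity classes:", dict(Counter(profile_selectivity(p).value for p in profiles)))

split = extract_external_set(profiles, fraction=0.10, seed=3)
print(f"external set: {len(split.external)} double points, per class:",
      split.per_class_external)

for i, description in [
    (1, "S1R activity (binary)"),
    (2, "S2R activity (binary)"),
    (3, "S1R selectivity over doubles"),
    (4, "S2R selectivity over doubles"),
    (5, "S1R 3-class (inactive/selective/nonselective)"),
    (6, "S2R 3-class"),
]:
    ds = build_dataset(i, split.training)
    print(f"dataset {i} ({description}): n={len(ds)}, labels={dict(Counter(ds.y.tolist()))}")

# Datasets 3 and 4 contain the same compounds under different labels; the
# selective classes are rare, which is why training uses undersampling and
# class weights downstream.
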