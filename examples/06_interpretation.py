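"""Feature importances and chemical-space embedding.

Trains the 3-class extra-trees model, prints its top-15 impurity-based
descriptor importances, and embeds ECFP4 fingerprints with t-SNE.
"""
from sigsel import (
    Algorithm, ModelConfig, RepresentationKind, SyntheticConfig,
    build_dataset, compute_representation, embed_2d, generate_library,
    top_feature_importances, train_final_model,
)

profiles, _ = generate_library(SyntheticConfig(n_compounds=500, seed=4))
ds = build_dataset(5, profiles)
config = ModelConfig(
    Algorithm.EXTRA_TREES, ds.task,
    fixed_params={"n_estimators": 200, "class_weight": "balanced"}, seed=4,
)
model = train_final_model(ds, RepresentationKind.DESC_COMPACT_2D, config)

ranking = top_feature_importances(model, top_k=15)
print("top 15 descriptors for S1R 3-class prediction:")
for name, weight in ranking.entries:
    print(f"  {name:24s} {weight:.4f}")

fp = compute_representation(ds.smiles[:200], RepresentationKind.FP_MORGAN_R2_2048)
coords = embed_2d(fp.values, perplexity=30, learning_rate=10, seed=4)
print(f"\nt-SNE embedding: {coords.shape[0]} compounds -> {coords.shape[1]}D,"
      f" x range [{coords[:, 0].min():.1f}, {coords[:, 0].max():.1f}]")

# High-ranking descriptors reflect the generator's latent recipe (logP,
# polarity, ring and halogen content); on real data this ranking is where
# pharmacophore interpretation starts.
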