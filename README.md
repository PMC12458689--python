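# sigsel

Activity and subtype-selectivity prediction for sigma receptor (S1R/S2R)
ligands.

The two sigma receptor subtypes share similar binding sites but have very
different biology — S1R is a neuroprotection-linked chaperone, S2R a
proliferation marker overexpressed in tumors — so medicinal chemists need
ligands that bind one subtype selectively. `sigsel` is a complete, tested
implementation of the machine-learning study design used for this problem:

* **Curation** of heterogeneous bioactivity tables (Ki/IC50/Kd/EC50 in nM,
  "=" and ">" qualifiers, replicate measurements across sources) into one
  standardized potency per compound and target,
  pActivity = −log₁₀(molar concentration), with strict rules for relation
  qualifiers, measure-type priority (Ki > IC50 > Kd > EC50), and a 20%-of-
  mean standard-deviation cutoff for irreproducible replicate groups.
* **Labeling**: active iff pActivity > 5 (i.e. < 10,000 nM); a double-point
  compound is X-selective iff active on X and either ΔpActivity ≥ 2
  (≥ 100-fold preference) or inactive on the counterpart; nonbinders are
  inactive on both.
* **Dataset construction**: a class-stratified 10% external validation
  split over double points, then six task datasets (per-target binary
  activity / pActivity regression, binary selectivity, 3-class
  inactive–selective–nonselective).
* **Representations**: extended and compact 2D descriptor collections,
  ECFP4, ECFP6, and MACCS keys, with missing-value, variance (< 0.1), and
  Pearson-correlation (|r| ≥ 0.9) filter selection fitted on training data
  only.
* **Model selection**: nested 5×5-fold cross-validation with a 50-trial
  tree-structured Parzen estimator search over random forest, extra trees,
  XGBoost, SVM, and kNN; random undersampling and class weighting for the
  imbalanced tasks; freeze-then-narrow classical 5-fold CV for final
  models; dummy/linear baselines.
* **Three prediction architectures**, compared head-to-head on the external
  split with per-class bootstrap confidence intervals: a 2-step
  classification workflow (activity gate → selectivity call), a 2-step
  regression workflow (predicted pActivities → threshold rules), and a
  1-step multiclass workflow (one 3-class model per target).
* A **synthetic-data generator** with known ground truth — valid
  amine-scaffold SMILES, structure-determined classes, configurable
  imbalance, replicates, and ">"-qualified records — so the entire pipeline
  is testable without any database downloads.

## Worked example

```python
from sigsel import (
    SyntheticConfig, generate_library, emit_raw_records, curate,
    extract_external_set, build_dataset, compute_representation,
    RepresentationKind, ModelConfig, Algorithm, nested_cv,
)
from sigsel import tpe

# a 1,000-compound two-target library with realistic noise and imbalance
cfg = SyntheticConfig(n_compounds=1000, noise_sd=0.3, seed=7)
profiles, truth = generate_library(cfg)
records = emit_raw_records(profiles, cfg)

result = curate(records)                 # standardize, filter, aggregate
split = extract_external_set(result.profiles, fraction=0.10, seed=7)
ds = build_dataset(5, split.training)    # 3-class S1R task
X = compute_representation(ds.smiles, RepresentationKind.DESC_EXTENDED_2D)

config = ModelConfig(
    Algorithm.EXTRA_TREES, ds.task, seed=7,
    search_space={"n_estimators": tpe.Int(50, 200), "max_depth": tpe.Int(5, 25)},
)
cv = nested_cv(ds, X, config, n_trials=10)
print(f"n = {len(ds)}  ROC-AUC = {cv.mean['ROC_AUC']:.3f} ± {cv.sd['ROC_AUC']:.3f}"
      f"  MCC = {cv.mean['MCC']:.3f}")
```

Output:

```
n = 585  ROC-AUC = 0.969 ± 0.026  MCC = 0.767
```

585 compounds qualify for the S1R 3-class dataset after curation and the
external split; the mean outer-fold one-vs-rest weighted ROC-AUC of 0.969
(SD over the 5 outer folds) and multiclass MCC of 0.77 say the extra-trees
model recovers the planted structure–selectivity signal from 2D descriptors
despite 0.3 log-units of measurement noise and a ~5:1 class imbalance —
outer folds are never touched by the hyperparameter search, so this is an
unbiased generalization estimate.

Longer narrative scripts, one per capability, live in `examples/`. The
`sigsel` command-line tool exposes the same steps
(`sigsel synth`, `sigsel curate`, `sigsel label`, `sigsel build-datasets`,
`sigsel featurize`, `sigsel run-study`, `sigsel predict`, `sigsel evaluate`,
`sigsel importance`, `sigsel embed`).

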