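# Methods

`sigsel` implements a complete modeling study for predicting the activity
and subtype selectivity of sigma receptor (S1R/S2R) ligands. This note
documents the procedures, the choices made where reasonable alternatives
existed, and what the synthetic benchmark does and does not demonstrate.

## Bioactivity curation

Raw records are rows of (SMILES, target, measure type, relation qualifier,
value in nM). Curation reduces them to one pActivity value per
(compound, target):

1. **Structure standardization.** SMILES are parsed with RDKit, salts are
   stripped by keeping the fragment with the most heavy atoms (ties: more
   carbons, then lexicographically smallest canonical SMILES), and the
   canonical SMILES of that fragment is the compound identity.
   Stereochemistry is preserved as written; no tautomer canonicalization is
   attempted. Unparsable rows are logged and skipped, never fatal.
2. **Relation filter.** "=" records are kept at any value. ">" records are
   kept only when the value is at or above 10,000 nM: a lower bound below
   the inactivity threshold carries no usable information, while a bound at
   or above it certifies inactivity (pActivity <= 5).
3. **Duplicate aggregation**, per (compound, target) group: "=" records
   take precedence over ">" records; a group with only ">" records keeps
   the single highest value (the most conservative bound, flagged
   `is_bound`). Among survivors only the highest-priority measure type is
   kept, Ki > IC50 > Kd > EC50 (EC50 is placed last because it is the
   rarest and least comparable of the four). Remaining replicates are
   averaged; if their sample (n-1) standard deviation reaches 20% of the
   mean, computed on the nM scale, the group is discarded as
   irreproducible. Values are sorted before averaging so the result is
   bit-identical under permutation of the input.
4. **pActivity.** The consensus concentration c (nM) becomes
   `9 - log10(c)`, i.e. the negative log10 of the molar concentration;
   10,000 nM maps to exactly 5.0.

The SD rule's scale (nM) and estimator (sample SD) are conventions of this
package; both choices are recorded here because assay-reporting practice
does not fix them.

## Labels

* **Activity**: active iff pActivity > 5 (strict); 5.0 exactly is inactive.
* **Selectivity** (double points only): X-selective iff active on X and
  either the difference in pActivity is >= 2 (at least 100-fold preference,
  inclusive at exactly 2) or the counterpart is inactive; nonbinder iff
  inactive on both; nonselective otherwise (both active, |delta| < 2).
  Exactly one class holds for every input, and swapping the targets swaps
  the selective classes.
* **Dataset labels**: six task datasets are built per target — binary
  activity (datasets 1/2, which double as pActivity regression tasks),
  binary selectivity over non-nonbinder double points (3/4, where the
  opposite-selective class counts as nonselective), and per-target 3-class
  inactive(0)/selective(1)/nonselective(2) (5/6, where nonbinders and
  target-inactive single points form the inactive class).

## External split and dataset construction

Ten percent of double-point compounds are drawn per selectivity class
(nearest-integer rounding, so a 2-member class can contribute 0), uniformly
without replacement under one seed, before any model sees the data. Single
points never enter the external set, since selectivity cannot be verified
for them. The split, all downstream training artifacts, and the manifest
record the seed; the external SMILES set is hashed into the study manifest
so training steps can be audited against it.

## Molecular representations and feature selection

Five representations: an extended 2D descriptor collection (the full RDKit
descriptor list, 210 descriptors), a compact collection (the 125 RDKit
descriptors excluding substructure-fragment counts), 2048-bit Morgan
fingerprints at radius 2 and 3 (ECFP4/ECFP6), and MACCS keys stored at
width 167 with bit 0 unset. Descriptor failures become missing values.

Filter selection, fitted on training rows only: drop features with any
missing value; drop features with population variance < 0.1 on raw values;
scan the remainder in native feature order and drop any feature whose
absolute Pearson correlation with an earlier retained feature is >= 0.9
(first seen kept; anticorrelated features are equally redundant, hence the
two-sided rule). By default the filters apply to descriptor matrices only;
a switch extends them to fingerprints, where a bit with set-fraction p has
variance p(1-p), so the 0.1 cutoff drops bits with p outside roughly
[0.113, 0.887].

SVM and kNN receive standardized features (scaler fitted on the training
portion of each fold); tree ensembles receive raw values. Scaling
parameters travel with every persisted model.

## Model selection

Five algorithm families — random forest, extra trees, gradient-boosted
trees (XGBoost), RBF-kernel SVM, and kNN — are tuned by a tree-structured
Parzen estimator (TPE) sampler implemented in `sigsel.tpe`: after a random
start-up phase, trials are split at the gamma = 0.25 quantile, each
parameter gets "good" and "bad" Parzen densities (Gaussian mixtures with a
uniform prior component for numeric parameters; smoothed counts for
categorical ones), and candidates drawn from the good density are ranked by
log l(x) - log g(x). Densities are factorized per parameter, the standard
TPE simplification. Everything is reproducible from one seed.

**Nested CV**: 5 outer folds (stratified for classification) estimate
generalization; inside each outer-training portion, a 50-trial TPE search
scores candidates by mean weighted ROC-AUC (classification) or RMSE
(regression) over 5 inner folds. Feature selection and scaling are
re-fitted inside every training portion. For the imbalanced tasks
(datasets 3–6) every training portion is randomly undersampled to the
minority-class count, re-drawn per fold under the run seed; test folds keep
the original imbalance. Class weights (trees, SVM), balanced sample weights
(XGBoost), and distance-weighted neighbors (kNN) additionally counter
imbalance. ROC-AUC uses probabilities when available and decision-function
margins otherwise; for multiclass margins the one-vs-rest support-weighted
AUC is computed per class column, which is rank-equivalent and avoids an
unstated calibration step.

**Freeze-then-narrow**: after nested CV, a hyperparameter is frozen when
its fold-best values agree — modal value in a majority of folds
(categorical) or all values within ±25% of their median (numeric, frozen
at the median). The rest are re-tuned over the [min, max] of fold-best
values during a classical 5-fold CV on the full dataset. If nothing is
consistent, the single most consistent parameter is frozen so the protocol
stays defined. Winners per task are chosen by mean outer-fold optimization
metric with standard deviation as tie-breaker; an explicit
(algorithm, representation) pin per task can override.

**Baselines**: logistic regression, 1-NN, a decision tree, logistic
regression on SLogP alone, majority-class and uniform-random dummies
(classification), and a training-median dummy (regression), all under plain
(stratified) 5-fold CV with library defaults and no undersampling.

## Workflow architectures

* **2-step classification**: per-target binary activity models gate
  per-target binary selectivity models. Both-inactive compounds are
  nonbinders; single-target actives are selective for that target (the
  counterpart-inactive branch of the labeling rule); both-active compounds
  are routed through both selectivity models — (selective, nonselective)
  resolves to the respective selective class, (nonselective, nonselective)
  to nonselective, and the contradictory (selective, selective) outcome is
  reported nonselective with an `inconsistent` flag, since no defensible
  single call exists.
* **2-step regression**: per-target pActivity regressors, then the labeling
  thresholds applied verbatim to the predictions.
* **1-step multiclass**: one 3-class model per target; both calls are
  reported without forced reconciliation (disagreements are flagged).

External reports give per-class precision/recall/F1/support and overall
accuracy, MCC, and weighted ROC-AUC, each with a 95% percentile bootstrap
CI over 2,000 compound-level resamples under a fixed seed (the CI method is
a package convention). Because the three architectures emit different label
spaces, the study-level comparison maps every workflow into the per-target
3-class frame (selective / nonselective / inactive per target) and ranks by
external MCC.

## Synthetic benchmark

The generator builds valid, unique, standardized SMILES from a fragment
grammar (aryl heads x alkyl/ether linkers x amine tails, 2,200 unique
structures, one basic nitrogen each — the classic sigma-ligand chemotype).
Two latent activity scores per compound are distinct linear combinations of
eleven z-scored 2D properties (logP, TPSA, aromatic rings, MW, rotatable
bonds, halogen count, H-bond acceptors, ring count, plus Balaban J, Chi1v
and Kappa2 so positional isomers have distinct scores). Compounds are
assigned to regions by quantiles of those scores — selective tails of the
differential score, a nonbinder slice at the bottom of the joint-activity
score — and a buffer of candidates nearest each cut (2% of n per cut by
default) is discarded so classes are separable in structure space, not only
in pActivity space. True pActivities are monotone in the within-region
ranks with deliberate margins around both thresholds: actives >= 5.3,
inactives <= 4.7, selective gaps in [2.3, 2.9], nonselective gaps within
±1.95, and selective counterparts kept active so per-target activity has a
single smooth boundary. Single points are randomly hidden measurements of
the same map, so single- and double-point labels never contradict each
other in the same structural region. Gaussian noise (default sd 0.3
pActivity units, a typical inter-assay spread) is added per measured value.

Default study conditions: n = 1500 compounds; class mix 8% S1R-selective,
9% S2R-selective, 33% nonselective, 10% nonbinder, 25% S1R-only and 15%
S2R-only single points (severe selective-class imbalance and an
S1R-dominant corpus, as in public sigma-receptor data); 30% replicate rate
with mean-preserving jitter small enough to pass the 20% SD rule; 30% of
inactive measurements emitted as ">"-qualified bounds at the compound's own
concentration (>= 10,000 nM), so curation recovers the profile exactly.
A conflict flag emits replicates whose SD breaches the rule, for testing
the discard path. With zero noise the full round trip
emit -> curate -> label reproduces the generator truth exactly.

**What passing proves — and does not.** The synthetic map is smooth,
low-dimensional, and margin-protected; real structure-activity landscapes
have activity cliffs, assay heterogeneity, and scaffold-specific effects
the generator does not emulate. Green tests demonstrate that the machinery
is correct (rules, splits, leakage discipline, metrics, routing) and that
the pipeline can recover a learnable signal under class imbalance and
measurement noise — not that real S1R/S2R selectivity is predictable at
these accuracies.

## Problem sizes and numerical conventions

Tests and the acceptance script run scaled-down studies chosen as the
package's own benchmark sizes: libraries of 200–1500 compounds, TPE budgets
of 2–15 trials over reduced tree search spaces, and 50–400 bootstrap
resamples; the protocol defaults (5x5 folds, 50 trials, 2,000 resamples)
remain the library defaults. The workflow-consistency check trains its
models without undersampling — it isolates routing correctness on balanced
evidence, while undersampling mechanics are verified separately. Other
conventions: half-away-from-zero rounding for per-class external counts;
Tc of two empty fingerprints defined as 0; R^2 is an error (not NaN) for
zero-variance truth; impurity-based importances with name-ascending tie
breaks; t-SNE with two components, perplexity 30, learning rate 10, PCA
initialization, fixed seed.

## Known limitations

* The extended descriptor set is the full RDKit list (210 descriptors),
  an order of magnitude smaller than large third-party 2D collections;
  matrix widths and selected-feature counts differ accordingly.
* The freeze rule (majority mode / ±25% of median) is one deterministic
  reading of "consistently strong" hyperparameters; other operationalizations
  are defensible.
* Undersampling to the minority count discards most majority-class
  training data; on small datasets this visibly costs majority-class
  accuracy (the synthetic diagnostics reproduce this known trade-off).
* The TPE sampler factorizes parameter densities independently and will
  not model parameter interactions.
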