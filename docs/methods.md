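# Methods

## Problem and model

The pipeline asks whether diet-driven shifts in the gut microbiome are
associated with region-specific changes in brain white-matter
microstructure, in a balanced four-diet rodent design (n = 20; 5 animals
per diet). Its inputs are an OTU relative-abundance table (16S amplicon
profiles closed to 1 per sample), a brain feature table of per-ROI means
of four diffusion-tensor indices (fractional anisotropy `fa`, radial
diffusivity `rd`, axial diffusivity `ad`, trace `tr` = 3 × mean
diffusivity), and the diet label of each animal.

Three random-forest analyses feed a rank-product score:

1. **Diet classification from OTUs.** OTU abundances are transformed with
   log₂(x + pseudocount) and a forest predicts diet. Feature importance is
   out-of-bag (OOB) permutation *MeanDecreaseAccuracy*: for each tree, the
   drop in OOB accuracy when one feature's values are permuted among that
   tree's OOB samples, averaged over trees.
2. **Diet classification from brain features.** Brain features are
   z-scaled per column (sample sd, n−1) and scored identically.
3. **Per-feature regression.** Each z-scaled brain feature is predicted
   from all OTUs by a regression forest; OTU importance is *%IncMSE*, the
   OOB permutation increase in MSE expressed as a percent of the mean
   per-tree OOB MSE.

Each importance vector is converted to a rank score: ascending rank over
N, so the most important feature scores 1 and the least 1/N, ties sharing
the average of their positions. For a pair (OTU i, brain feature j),

    S_Combined(i, j) = S(OTU_i) · S(BrainM_j) · S(OTU_i, BrainM_j)

where the third factor ranks OTU i's %IncMSE within feature j's
regression (over N_OTU). Pairs are ordered by S_Combined; the top 27 feed
three downstream diet classifiers (OTU-only, brain-only, combined) grown
by forward selection until 100% leave-one-out accuracy, and a score
cutoff (default 0.84) extracts the confident pairs.

## Accuracy estimation, honest and optimistic

Two cross-validation estimates are first-class outputs because they answer
different questions:

* **LOOCV after global selection** selects the top-k features from an
  importance fit that saw *all* samples, then leave-one-out-validates the
  reduced matrix. Feature selection leaks information about every held-out
  sample, so this estimate is optimistic; it is reported because it is the
  headline procedure the pipeline reproduces.
* **Nested 3 × 5-fold CV (stratified by diet)** re-runs the importance
  ranking and top-k selection inside every training split. Its mean ± 1.96
  × (sample sd of the 15 fold accuracies) is the honest generalization
  estimate. The sd/√n variant of the interval is available via
  `sem_interval=True`; the wider ±1.96·s reading is the default because a
  ±10-percentage-point interval on 15 fold accuracies is only consistent
  with that convention.

Chance level for four balanced classes is 25%. Stratified folds are built
per class: shuffle the class's samples with the run seed and deal
round-robin, which gives exactly one sample per class per fold in the
5-per-class design.

## Forest implementation choices

* The ensembles are scikit-learn's `RandomForestClassifier` /
  `RandomForestRegressor`; the OOB permutation importances are computed in
  this package from each tree's bootstrap mask (scikit-learn offers only
  impurity importance and held-out-set permutation importance, which rank
  differently). Bag masks replicate sklearn's bootstrap draw and are
  verified against it in a test.
* `mtry` defaults: ⌊√p⌋ (classification) and ⌊p/3⌋ (regression), the R
  randomForest defaults. Node size: classification splits nodes of ≥ 2;
  regression splits nodes of ≥ 6 with no lower bound on child size
  (`min_samples_split=6, min_samples_leaf=1`). The latter is the faithful
  translation of R's `nodesize = 5`, which bounds when a node *stops
  splitting*, not the size of its children; using `min_samples_leaf=5`
  instead would reduce most trees to stumps at n ≈ 20 and destroy
  permutation importance.
* Importance is the raw mean decrease by default (`importance_scaled=False`);
  dividing by the across-tree standard error (R's `scale=TRUE`) is exposed
  for sensitivity analysis. %IncMSE is normalized by the mean per-tree OOB
  MSE; every downstream use is rank-based, so the normalization does not
  affect any score.
* Negative importances (common for noise features) are ranked as-is;
  clipping would create large artificial ties.
* `ntree` defaults to 500. The study-scale values (16,000 for
  classification, 4,000 for regression) are supported and exposed as flags
  in the analysis drivers; at n = 20 the importance rankings stabilize far
  below that, and the package's own analyses use 500/300 trees.
* Determinism: one `seed` in `ForestConfig` drives both tree construction
  and the permutation stream; cross-validation loops derive per-fold seeds
  from it. Equal seeds give identical models, importances, and files.

## Synthetic cohorts

No real cohort ships with the package, so `synthetic_cohort` generates
cohorts with the statistical structure the analysis assumes, plus ground
truth for recovery tests.

* **OTU table.** Per-OTU log₂ intensities are Gaussian with per-OTU base
  means ~ N(0, 2) and within-diet sd `otu_within_sd` (default 1); samples
  are closed to the simplex (log-normal composition). Each of the
  `n_signal_otus` signal OTUs is assigned a diet round-robin and shifted
  symmetrically: +effect/2 in its diet, −effect/2 elsewhere (log₂ units ×
  within-diet sd), so the realized between-diet contrast equals
  `otu_effect_size × otu_within_sd` (calibration verified to 10% over 200
  seeds) and zero-effect designs make signal columns exchangeable with
  noise columns.
* **Brain table.** Feature j of sample s is a per-(diet, feature) baseline
  ~ N(0, `brain_diet_sd`²) plus `link_strength` × the standardized log₂
  abundance of each OTU linked to j, plus N(0, `noise_sd`²) noise. Linked
  pairs are planted on distinct brain features while capacity allows, so
  each planted pair carries the full marginal `link_strength`.
* **Defaults** emulate the study design: 4 diets × 5 animals, 100 OTUs
  with 9 signal OTUs at effect 4, 40 brain features (10 ROIs × 4 metrics)
  with 9 linked pairs at link 3 and unit noise, `brain_diet_sd = 0.5`
  (a mild diffuse diet effect on all regions, as white-matter analyses of
  diet typically show).
* **Paired sampling** optionally adds a pre-diet baseline OTU sample per
  animal drawn from the common weaning distribution (no diet effect); a
  helper returns the post−pre log₂ difference table, so analyses can use
  either post-diet abundances or pre/post changes as features.

What the generator does **not** emulate: sequencing-depth (count) noise and
rarefaction, taxonomic correlation structure among OTUs, cage/litter/
coprophagy effects, nonlinear or interactive OTU–brain relationships, and
spatial correlation among ROIs. Passing recovery tests therefore shows the
pipeline detects linear-Gaussian planted structure at the stated effect
sizes in compositional data — not that it would perform identically on real
16S/DTI cohorts.

## Numerical and procedural details

* log₂ pseudocount default 1e-6 (order of the smallest detectable relative
  abundance at typical sequencing depth); zeros with a zero pseudocount are
  rejected rather than mapped to −∞.
* z-scaling uses sample sd (ddof = 1); constant columns become all-zero
  with a warning. Scale flags (`relative/log2`, `raw/zscaled`) gate both
  transforms so neither can be applied twice.
* Sample alignment restricts all tables to the common samples in
  lexicographic order and reports what was dropped.
* All rank orderings break ties by feature identifier (stable sort), and
  pair ordering by (s_combined desc, otu_id, brain_feature_id), so every
  output is deterministic.
* Heat maps use Euclidean distance with average linkage by default
  (correlation distance and complete linkage available); rows/columns are
  pre-sorted by label before clustering so equal-distance merges resolve
  identically on every run. The tested surface is the reordered CSV and
  leaf orders, not rendered figures.
* Relative-abundance validation rejects rows whose sum deviates from 1 by
  more than 1e-6, values outside [0, 1], and any missing entries.

## Problem sizes used by the test-suite and reference computations

The packaged analyses run at sizes chosen to keep a full run on one CPU
comfortable while preserving the study's structure: the strong-signal
LOOCV reproduction uses the full 20 × 100 design at ntree = 500; pair-
recovery uses 25 cohorts of 30 OTUs × 12 brain features with 4 planted
links (the same low linked-feature fraction as the 9-of-40 default) at
ntree = 150/100; the leakage comparison uses 10 cohorts of 80 OTUs at
effect 1.5 and ntree = 120; null cohorts use 8 seeds. The oracle
cross-check compares the engine's one-permutation-per-tree estimate with a
1,000-permutation direct estimate on a 12-sample, 2-feature toy.

## Known limitations

* The 0.84 cutoff is interpreted as a threshold on S_Combined (configurable);
  with N_OTU = 100 and N_BrainM = 40 only a handful of pairs can exceed it.
* Forward selection evaluates prefixes of the fixed S_Combined ordering; it
  does not search subsets.
* The LOOCV-after-global-selection estimate is intentionally optimistic
  (see above); it must not be quoted as generalization accuracy.
* With n = 20, nested-CV accuracy has a wide sampling distribution; the
  ±1.96·s interval reflects fold-to-fold spread, not the standard error of
  the mean.
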