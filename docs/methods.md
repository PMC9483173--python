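# Methods

## The problem

Off-target blockade of the hERG potassium channel causes drug-induced QT
prolongation and is a leading reason for late-stage attrition and market
withdrawal. `hergml` implements a ligand-based binary QSAR workflow that
classifies compounds as hERG blockers (ACT) or nonblockers (INA) at two
potency thresholds — pIC50 ≥ 6 (IC50 ≤ 1 µM, the level of regulatory
concern) and pIC50 ≥ 5 (IC50 ≤ 10 µM) — from 2D molecular descriptors.

## Curation model

Raw activity exports (ChEMBL-style field names) pass four entry filters:
IC50-type records only, human target, direct-binding assay (`assay_type ==
"B"`), and an empty data-validity comment. Entries carrying no numeric value
but annotated "not active" are kept as label-only inactives (INA at both
thresholds); when a structure has both, numeric records win. Structures are
standardized to a salt-free, charge-neutral, stereochemistry-free canonical
SMILES: the largest organic fragment is kept when the minor fragments are
counterion-sized (≤ 6 heavy atoms), true multi-component mixtures are
rejected, as are inorganics and molecules containing elements outside
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}. IC50 values are converted to
pIC50 = −log10(IC50 in molar). Replicates per canonical structure are
aggregated to their arithmetic mean; the replicate spread σ is the sample
standard deviation (n−1 denominator, 0 for singletons) and compounds with
σ > 2 log units are excluded as irreproducible. The class boundary is
inclusive: ACT iff pIC50 ≥ threshold, which is the direction forced by the
−log transform (IC50 ≤ 1 µM ⇔ pIC50 ≥ 6).

## Descriptors

The default backend is the RDKit 2D descriptor list (~210 descriptors, no
conformer dependence); the pipeline is descriptor-agnostic and accepts any
precomputed compounds × descriptors CSV. Pruning removes, in order,
descriptors with any missing value, near-constant descriptors
(sd < 0.01), and for every pair with |Pearson r| > 0.95 the later
descriptor in name-sorted order — a deterministic greedy scan chosen
because the survivor choice is otherwise arbitrary and determinism matters
more than the particular choice. Surviving columns are z-scored; validation
and external sets always reuse the training-set mean/sd verbatim.

## Dataset division

Training/validation splitting runs greedy MaxMin diversity picking
separately within each class on Morgan fingerprints (radius 2, 2048 bits,
the toolkit's conventional parameters) under Tanimoto distance
(1 − similarity; two all-zero fingerprints count as identical). The first
pick is the fingerprint with maximal popcount, ties broken lexicographically
by compound id, and later ties in the max–min distance are also broken by
id, so the selected set is invariant to input order; a seed-randomized
start is available. round(0.8·n_class) compounds per class go to training,
preserving the class ratio to within one compound. A PCA coverage check on
the pooled matrix reports the variance captured by the first two components
and each subset's score bounding box.

## Feature selection

A three-step random-forest procedure, run on training rows only:

1. **Thresholding.** Features are ranked by mean out-of-bag permutation
   importance across several independently seeded forests (default 12
   forests × 150 trees, mtry = √p). The retention threshold is the minimum
   of a CART regression of the importance standard deviation on rank — an
   estimate of the pure-noise importance jitter — and features whose mean
   importance falls below it are dropped.
2. **Interpretation.** Nested forests on the top-k survivors for
   k = 1..K; the smallest k whose mean OOB error is within one standard
   deviation of the minimum is kept.
3. **Prediction.** A greedy forward pass over the interpretation set in
   rank order admits a feature only if it lowers OOB error by more than the
   mean absolute OOB jitter of noise-only additions (estimated from
   retained features outside the interpretation set). This step exists to
   discard redundant features, so it deliberately returns fewer features
   than were planted when their class signals overlap.

The forests are hand-rolled ensembles of scikit-learn decision trees so
each tree's bootstrap and OOB sets are explicit; default sizes
(12 × 150 ranking trees, 100-tree nested forests) keep a 600-compound,
60-descriptor selection under ~10 s while meeting the recovery contract
below. All randomness derives from one master seed recorded in the result.

## Imbalance handling

SMOTE oversamples the minority class in the normalized, selected feature
space: each synthetic row is x_i + u·(x_nn − x_i) with u ~ U(0,1) and x_nn
one of the k = 5 Euclidean nearest minority neighbors (Chawla's canonical
default; k is clamped to n_min − 1 with a warning when the minority class
is tiny). Synthesis stops at an exact 1:1 ratio; each minority row is used
⌊need/n_min⌋ times and the remainder is drawn uniformly. SMOTE touches the
training partition only — validation and external sets stay unbalanced so
measured performance reflects the real class distribution — and no SMILES
are fabricated: synthetic rows exist only in descriptor space.

The balanced random forest (BRF) instead draws, per tree, n_min samples
with replacement from each class; it is the preferred model on the 5:1
composition and combining it with SMOTE is refused by default (double
balancing), overridable explicitly.

## Models, tuning, consensus

Seven algorithm ids: BRF (in-package), RF, KNN, GB, MLP, SVM
(scikit-learn; SVM probabilities via Platt-style calibration), XGB
(xgboost). Hyperparameters are chosen by exhaustive grid search — except
SVM and XGB, which use a budgeted random search (default 10 draws) over the
same space — scoring mean balanced accuracy under stratified 5-fold CV, and
the winner is refit on the full training data. Class calls use the 0.5
probability cutoff. Default spaces are small literature-standard grids
(trees ∈ {100, 300}; k ∈ {3,5,7,9}; C ∈ 10^{−1..2}; γ ∈ {scale, 10^{−3..0}};
learning rates {0.05, 0.1, 0.3}; one/two hidden layers of 64–128 units),
all overridable per run.

A consensus model combines 2–3 bundles sharing a threshold and emits a
label only on unanimous agreement (for two members, majority and unanimity
coincide); discordant rows abstain, and predicted + abstained always equals
the input size. The consensus score — needed for AUC, which a vote does not
define — is the arithmetic mean of member probabilities.

## Applicability domain

Leverage h = xᵀ(XᵀX)⁻¹x against the normalized, feature-selected training
matrix, excluding SMOTE rows (the domain describes real chemical space).
Compounds with h > 3p/n are out of domain; the boundary itself is in
domain. XᵀX falls back to the Moore–Penrose pseudoinverse when singular
(collinearity can survive the 0.95 correlation filter), in which case the
training leverages sum to rank(X) rather than p. Reported metrics cover
only in-domain, non-abstained rows.

## Metrics

SE = TP/(TP+FN), SP = TN/(TN+FP), BA = (SE+SP)/2 (exact identity on
unrounded values), MCC with a zero-marginal convention of 0 and a log-space
denominator against overflow, and rank-based (Mann–Whitney) AUC with ties
counted one half. Report display uses decimal half-up rounding to 2 places;
internal values stay unrounded.

## Synthetic data: what it emulates and what it does not

The descriptor-matrix generator plants `n_informative` columns shifted by
±effect/2 between classes among standard-normal noise columns, with an
exact class ratio (5:1 emulates the stricter threshold's composition, 1:1
the looser one). The activity-table generator assigns potency bands
(1/6 potent, 1/3 moderate, 1/2 inactive — reproducing ≈5:1 at pIC50 = 6 and
≈1:1 at pIC50 = 5 after curation) by the rank of a latent score coupled to
computable structure properties (a logP/TPSA blend), emits replicate IC50
rows in mixed units (values generated on the pIC50 scale and
back-converted, so unit handling is exercised), spreads a configurable
fraction of compounds beyond σ = 2 to exercise the outlier rule, and
injects one violator of each curation filter. The latent noise scale
(sd 0.5) is calibrated so that recovering the class from structure at a
given nominal effect size is about as hard as recovering it from the
descriptor generator, whose shift is spread over several independent
columns.

Structures come from a fixed enumeration of ~900 drug-like template
variations, so descriptor computation is meaningful offline. The generator
does **not** emulate real hERG structure–activity relationships, assay
noise heterogeneity, activity cliffs, or the scaffold clustering of real
ChEMBL data; passing tests therefore demonstrate the machinery's
correctness and statistical behavior under known ground truth, not
predictive performance on real compounds.

## Verified statistical contracts (computed by the test suite)

- Planted-feature recovery of the full selector ≥ 80% with ≤ 20%
  contamination at effect size 1.5, averaged over 20 seeds at 600
  compounds × 60 descriptors.
- Hat-matrix trace identity Σh = rank(X) to 1e-6; SMOTE exact 1:1 balance
  and parent-segment convexity; AUC rank formula vs O(n²) pair oracle to
  1e-12; consensus conservation; per-class split arithmetic and agreement
  of the MaxMin picker with an exhaustive reimplementation on ≤ 6-item
  instances; end-to-end determinism under one master seed; chance-level
  (BA ∈ [0.4, 0.6]) cross-validation on zero-effect data.
- The packaged benchmark table of published confusion counts reproduces the
  published headline metric values exactly at 2-decimal rounding; a
  minority of published rows are internally inconsistent (their printed
  metrics do not follow from their own printed counts under any rounding),
  which the test suite surfaces rather than hides.

## Problem sizes and limitations

Default desk-scale runs use 600 compounds and the RDKit descriptor set;
the full pipeline completes in about a minute on one CPU, and the selector
defaults trade a little ranking stability for that speed. Known
limitations: no tautomer handling or InChI canonicalization in curation;
the correlation-pruning survivor rule is deterministic but arbitrary; the
consensus AUC definition (mean member probability) is one reasonable
choice among several; leverage-based AD assumes an approximately
ellipsoidal training domain and flags nothing about interpolation gaps
inside it.
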