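# hergml

Ligand-based QSAR classification of hERG potassium-channel blockade.

Drug-induced blockade of the hERG channel prolongs the cardiac QT interval
and can trigger fatal arrhythmias; screening candidate molecules *in
silico* for hERG liability is a standard step in early drug discovery.
`hergml` provides the complete workflow for building and applying binary
hERG blocker/nonblocker classifiers from 2D molecular descriptors, aimed at
computational chemists who have an activity export (e.g. from ChEMBL) and
want tested, reproducible models rather than ad-hoc notebooks.

The pipeline:

1. **Curation** — entry filters (human, direct-binding, IC50-only, no
   validity warnings), structure standardization (salt stripping, charge
   neutralization, stereochemistry removal, rejection of inorganics /
   organometallics / mixtures), conversion to pIC50 = −log10(IC50 [M]),
   replicate aggregation with a σ > 2 outlier rule, and labeling at two
   thresholds: ACT iff pIC50 ≥ 6 (IC50 ≤ 1 µM) or pIC50 ≥ 5 (IC50 ≤ 10 µM).
2. **Descriptors** — RDKit 2D descriptors (or any precomputed CSV), pruned
   (missing values, sd < 0.01, |r| > 0.95) and z-normalized with
   training-set statistics.
3. **Splitting** — per-class greedy MaxMin diversity picking on Morgan
   fingerprints under Tanimoto distance (80/20, class ratio preserved),
   with a PCA coverage check.
4. **Feature selection** — a three-step random-forest procedure
   (importance thresholding → nested-forest interpretation → parsimonious
   prediction step), training rows only.
5. **Balancing** — SMOTE to an exact 1:1 ratio (training only), or a
   balanced random forest (equal per-class bootstrap per tree).
6. **Models** — BRF, RF, KNN, GB, XGB, MLP, SVM; grid or budgeted random
   hyperparameter search scored by 5-fold cross-validated balanced
   accuracy.
7. **Consensus** — 2–3 top models vote; discordant compounds are reported
   as ABSTAIN rather than guessed.
8. **Applicability domain** — leverage h = xᵀ(XᵀX)⁻¹x with the h > 3p/n
   rule; predictions outside the training chemical space are flagged.
9. **Metrics** — SE, SP, BA = (SE+SP)/2, MCC, and rank-based AUC, computed
   over in-domain, non-abstained compounds.

See `docs/methods.md` for the statistical details and design rationale.

## Worked example

Train on a synthetic activity export (300 compounds whose potency is a
noisy function of structure), then predict new SMILES:

```python
from hergml.synthetic import SyntheticSpec, generate_activity_table
from hergml.pipeline import run_training_pipeline, predict

table, truth = generate_activity_table(
    SyntheticSpec(n_compounds=300, effect_size=1.5, fraction_outliers=0.02, seed=7)
)
table.to_csv("activity.csv", index=False)

res = run_training_pipeline(
    {"input_table": "activity.csv", "threshold": 6, "seed": 42,
     "algorithms": [{"algorithm": "BRF", "smote": False},
                    {"algorithm": "KNN", "smote": True}]},
    "run",
)
print(res.metrics.round(3).to_string(index=False))
```

```
              model dataset    BA  SE    SP   MCC   AUC  n_abstained  n_out_of_domain
                BRF      VS 0.968 1.0 0.936 0.838 1.000            0                3
               SKNN      VS 0.968 1.0 0.936 0.838 0.975            0                3
consensus(BRF+SKNN)      VS 0.968 1.0 0.936 0.838 1.000            0                3
```

Each row is a model evaluated on the held-out validation set after
applicability-domain filtering (3 compounds were outside the domain): the
balanced random forest catches every true blocker (SE = 1.0) while keeping
specificity at 0.94, and the consensus abstained on nothing here.

```python
rep = predict(
    ["Cc1ccc(Cl)cc1",                            # lipophilic aromatic
     "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",    # structurally alien
     "bad-smiles"],
    ["run/bundles/BRF", "run/bundles/SKNN"],
)
```

```
                         input_smiles BRF SKNN consensus  consensus_score applicability_domain        flag
                        Cc1ccc(Cl)cc1 ACT  ACT       ACT         0.981667                 True
FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F ACT  ACT       ACT         0.875000                False
                           bad-smiles                                 NaN                      unparseable
```

The first compound is called a blocker inside the applicability domain
(trustworthy). The perfluorinated chain also gets a call, but
`applicability_domain = False` marks it as outside the training chemical
space — the prediction should not be trusted. The unparseable row is kept
and flagged, so the report always has one row per input.

The same workflow is available from the shell:

```bash
hergml synth --seed 7 --out data/
hergml curate --input data/activity_table.csv --output curated/
hergml descriptors --input curated/curated.csv --output matrix.csv
hergml predict --smiles "Cc1ccc(Cl)cc1" --bundles run/bundles/BRF --bundles run/bundles/SKNN
```

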