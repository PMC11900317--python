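# kinasepred

Fingerprint-based prediction of small-molecule kinase activity, with
explainable atom-level attributions. The package covers the full workflow:

1. **Curation** (`kinasepred.curation`) — SMILES standardization (largest
   fragment, charge neutralization, fixed pH-7.4 re-ionization rules),
   element / molecular-weight / heavy-atom filters, duplicate removal,
   activity labeling (≤ 10 µM, confidence ≥ 9), decoy balancing, and
   stratified 80:20 splits.
2. **Featurization** (`kinasepred.featurize`) — three binary fingerprints,
   each with full bit → atom-set provenance: Morgan (radius 2, 2048 bits),
   path/subgraph (1–7 bonds, 2048 bits), and an 881-position
   substructure-key dictionary (`kinasepred.keys881`).
3. **Metrics** (`kinasepred.metrics`) — precision, recall, NPV,
   specificity, balanced accuracy, and MCC from confusion counts, with
   undefined-rate propagation and mean ± sd summaries over repeats.
4. **Family models** (`kinasepred.family_model`) — random forest,
   Gaussian naive Bayes, and MLP classifiers over any fingerprint kind;
   exhaustive grid search (3-fold stratified CV scored by MCC), repeated
   stratified 70/30 holdout evaluation, and externally validated
   prediction with a structural-overlap guard.
5. **Explainability** (`kinasepred.explain`) — an in-package Kernel SHAP
   estimator (exact when the set-bit count permits exhaustive coalition
   enumeration), equal-partition retro-mapping of bit attributions onto
   atoms, and SVG rendering with orange shading for positive
   contributions.
6. **Target models** (`kinasepred.target_models`) — per-kinase
   class-weighted random forests (100 trees, 0.75 decision threshold),
   inactive-ratio imbalance flagging (< 0.25), ensemble reports with and
   without flagged models, and compound × target prediction panels with
   per-compound success rates.
7. **Screening** (`kinasepred.screening`) — library scoring with leak
   guards and sphere-exclusion (leader) clustering of hits on Tanimoto
   distance, with centroid representatives.
8. **Fixtures** (`kinasepred.fixtures`) — deterministic combinatorial
   molecule generation with a planted fused-bicycle activity motif, so the
   entire pipeline is testable offline.

## Tests

```bash
python -m pytest -q tests/
```

The suite is fully self-contained: all molecular data are generated by
the fixtures module at test time. `tests/test_acceptance.py` holds the
end-to-end acceptance criteria (planted-motif pipeline, SHAP motif
recovery, target-ensemble imbalance analysis, determinism).

## CLI

```bash
# generate synthetic data
kinasepred fixtures family --out data/ --seed 42 --n-active 200 --n-inactive 200
kinasepred fixtures targets --out activities.csv --seed 42 --n-targets 5

# curate an activity table + decoy library into a balanced dataset
kinasepred curate --activities activities.csv --decoys decoys.smi \
    --out curated/ --seed 1 --train-fraction 0.8

# fingerprints (kinds: morgan | path | keys881)
kinasepred featurize --in curated/dataset.csv --kind morgan --out features

# train (grid search + repeated-holdout CV), evaluate, validate
kinasepred train --dataset curated/dataset.csv --algorithm random_forest \
    --kind morgan --out model/ --seed 1
kinasepred evaluate --model model/model.joblib --dataset curated/dataset.csv
kinasepred validate-external --model model/model.joblib --dataset external.csv

# explain one molecule (SVG + per-atom CSV + per-bit JSON)
kinasepred explain --model model/model.joblib --smiles "CCOc1ccc(...)cc1" \
    --background curated/dataset.csv --out explain/

# virtual screening with hit clustering
kinasepred screen --model model/model.joblib --library library.smi \
    --threshold 0.5 --cluster-cutoff 0.4 --out hits.csv

# per-target models
kinasepred targets build --activities activities.csv --out targets.json
kinasepred targets train --activities activities.csv --out target_models/
```

## Notes and documented choices

- Standardization replaces vendor washing tools with an open rule set:
  largest fragment by heavy atoms (ties: MW, then canonical string),
  neutralize, then re-ionize at pH 7.4 (carboxylic/sulfonic/phosphonic
  acids → anion; aliphatic amines and amidines/guanidines → cation).
- Zero-denominator rates are reported as undefined, never silently 0;
  summaries record per-metric exclusion counts. Standard deviations are
  population (N) by default.
- "n-fold CV" follows the repeated-random-subsampling protocol: n
  independent stratified 70/30 splits, not canonical k-fold.
- Kernel SHAP treats only the query molecule's set bits as players;
  unset bits stay at background values. With few set bits the estimate
  is exact; otherwise coalitions are sampled by Shapley-kernel weight
  with the efficiency constraint imposed exactly.
- Count-type substructure keys (element/ring counts) carry no atom
  provenance and are excluded from atom retro-mapping; their summed
  attribution is reported separately.
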