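# recurbn

Discrete Bayesian networks for multi-horizon recurrence-risk prediction,
comparing an **expert-elicited** structure (built through a multi-expert
consensus protocol under clinical-timeline tier constraints) against a
**BIC hill-climbing** structure learned from data, on the same
training/validation split. Because the underlying multi-trial clinical
dataset is not public, the package ships a synthetic-cohort generator whose
category marginals, per-variable missingness fractions, and outcome
prevalences are calibrated to the published cohort characteristics.

## What's inside

| Module | Purpose |
| --- | --- |
| `recurbn.synthetic` | Ground-truth network construction from a generator config; ancestral cohort sampling; MCAR missingness injection |
| `recurbn.preprocess` | Continuous-variable categorization, CRM dichotomization, missing-as-`Unknown` encoding, per-cohort stratified 80/20 split, all-nominal SMOTE (Hamming neighbours + per-feature majority vote) |
| `recurbn.bn` | DAG/CPT/network types, Laplace/ML parameter fitting, log-likelihood, ancestral sampling, JSON serialization |
| `recurbn.inference` | Exact posteriors by variable elimination (min-degree order) |
| `recurbn.tiers` | Timeline tier map, forbidden-arc (backward-in-time) sets, the propose → intersect → review → validate elicitation protocol, expert-DAG construction |
| `recurbn.structure` | Decomposable BIC (higher = better), score cache, greedy add/delete/reverse hill climbing with blacklists and seeded random restarts |
| `recurbn.cpdag` | DAG → CPDAG (Meek rules) and structural Hamming distances |
| `recurbn.evaluate` | Vectorized risk prediction, Mann–Whitney AUC, DeLong CIs and paired AUC test, confusion metrics, bootstrap calibration curves, structure diffs |
| `recurbn.pipeline` | One-config end-to-end experiment producing a report bundle per endpoint |

Packaged fixtures (editable YAML under `src/recurbn/data/`): the tier map,
the transcribed expert consensus arc list (19 arcs over 10 variables, 6
outcome parents), the full study-like generator spec, and a compact
10-node all-binary ground truth used for structure-recovery exercises.

## CLI

```bash
recurbn simulate --seed 1 --out cohort.csv        # synthetic cohort CSV
recurbn run --config experiment.yaml --out report # full comparison bundle
recurbn learn --csv cohort.csv --outcome recurrence_2y
recurbn evaluate --network net.json --csv cohort.csv --outcome recurrence_2y
recurbn diff --a arcs_a.tsv --b arcs_b.tsv --outcome recurrence_2y
```

`recurbn run` writes, per endpoint: metrics CSV/JSON (accuracy, AUC with
95% CI, sensitivity, specificity, on training and validation for both
structures), DeLong AUC-difference p-values, calibration curves, structure
diff reports, and serialized networks.

## Conventions

- BIC sign: **higher is better** (log-likelihood minus `(log N / 2) ×`
  parameter count). Note many packages use the opposite sign.
- Missingness is a first-class category (`Unknown`), supplied as ordinary
  evidence at prediction time; rows missing the outcome are excluded.
- All randomness flows from explicit integer seeds; experiment-level seeds
  are split in a documented order (see `recurbn.pipeline`).
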