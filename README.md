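# neodl

Survival stratification of IDH wild-type glioblastoma from **neoantigen
intrinsic features** — sequence-derived properties of mutant 9-mer peptides
and their wild-type counterparts. Simple immunogenomic baselines (missense
mutational load, neoantigen count, differential agretopicity) do not
stratify survival in this tumor type; this package implements the pipeline
that does: peptide featurization, Cox-based feature screening,
clustering-derived survival labels, an LSTM stratifier, and a repeated-split
validation protocol — plus a synthetic-cohort generator so every stage is
testable without patient data.

It is aimed at computational immunologists and biostatisticians who want a
tested, reusable implementation of this class of pipeline, or its pieces
(descriptor featurization, fast univariate Cox screening, hierarchical
k-means labeling).

## The method

For each patient, mutant/wild-type (MT/WT) 9-mer pairs with predicted MHC-I
binding affinities are filtered by the strict neoantigen rule
IC50(MT) < 500 nM < IC50(WT). Each peptide is encoded by 66 amino-acid
descriptor components (Cruciani PP, Kidera, Z-scales, FASGAI, T-scales,
VHSE, ProtFP, ST-scales, BLOSUM indices, MS-WHIM) plus composition-class
flags, molecular weights, physico-chemical properties and Shannon entropy,
at every position, adjacent di-/tripeptide, mutation-anchored unit and the
whole sequence — a fixed vocabulary of 4,348 named features per pair,
averaged per patient.

Each feature is screened against overall survival with a univariate Cox
proportional-hazards fit (Efron ties); features with Wald p ≤ 0.05 are
*valid*. Patients are labeled by hierarchical k-means (Ward tree cut at
k = 2 seeding Lloyd's algorithm) on the z-scored valid features; the cluster
with longer median OS is "long-term". The stratifier is a recurrent network
reading the valid-feature vector as a sequence of scalars —
LSTM(128) → LSTM(32) → dense(8, sigmoid) → dense(1, sigmoid) — trained with
MSE loss and Adam on the cluster labels, implemented in NumPy with seeded,
bit-reproducible training. Validation repeats stratified 60/40 splits
(round-half-up per stratum: strata of 126/136 send 76/82 patients to
training), retrains per trial, and records the test-set log-rank p between
predicted groups, with AUC/accuracy against the cluster labels.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic cohort (200 patients, two planted groups differing in
residue usage at peptide sites 3–4 and in hazard, HR ≈ 3) and try the three
classical baselines:

```bash
neodl simulate --seed 11 --out-dir cohort
neodl baseline --peptides cohort/peptides.tsv --clinical cohort/clinical.tsv \
               --mutations cohort/mutations.tsv --out-dir baseline
```

```json
{
  "neoantigen_count": {"logrank_chi2": 0.013, "logrank_p": 0.909, "n_high": 91, "n_low": 109},
  "missense_load":    {"logrank_chi2": 0.750, "logrank_p": 0.387, "n_high": 91, "n_low": 109},
  "dai":              {"logrank_chi2": 0.489, "logrank_p": 0.484, "n_high": 81, "n_low": 118}
}
```

None of the mean-split baselines separates survival (log-rank p ≈ 0.39–0.91):
the planted signal lives in positional sequence features, not in counts or
affinity differences. The full pipeline finds it:

```bash
neodl validate --peptides cohort/peptides.tsv --clinical cohort/clinical.tsv \
               --config examples/desk_scale.toml --seed 7 --out-dir run
```

```json
{
  "n_valid_features": 1341,
  "n_significant_trials": 30,
  "n_trials": 30,
  "auc_full_cohort": 0.9881313131313131
}
```

About a third of the vocabulary screens as survival-associated (the
planted residue bias touches many correlated features), all 30 repeated
60/40 trials separate the held-out patients at log-rank p < 0.05, and the
best trial's model reproduces the cluster labels nearly perfectly on the
full cohort (AUC 0.988). `run/` contains the feature matrix, screening
report, label table, per-trial report, the serialized model and an
evaluation summary.

The same works from Python:

```python
from neodl import SimConfig, generate_cohort, PipelineConfig, run_full_pipeline

sim = generate_cohort(SimConfig(n_patients=200, seed=42))
result = run_full_pipeline(sim.cohort, PipelineConfig.desk_scale(master_seed=7))
print(sum(t.significant for t in result.trials), "/", len(result.trials))
print(round(result.auc_full, 3))
```

## CLI

`neodl simulate | featurize | screen | label* | train | validate | apply |
baseline` (*labeling happens inside `validate`; `train` consumes its label
table). Common flags: `--config <TOML>`, `--seed`, `--out-dir`.

## Layout

- `neodl.peptide_features` — descriptor tables, vocabulary, featurization
- `neodl.cohort_io` — cohort model, TSV readers/writers, neoantigen calling,
  DAI, mutational load
- `neodl.survival_stats` — Cox fits and vectorized screening, KM, log-rank,
  mean-split baselines, correlations, t-tests
- `neodl.stratifier` / `neodl.nn` — z-scaler, hkmeans labeling, the NumPy
  LSTM classifier and model artifacts
- `neodl.validation` — split protocol, trials, reliability resampling, full
  pipeline orchestration
- `neodl.synthetic_cohort` — the cohort generator
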