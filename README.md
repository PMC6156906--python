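# prescriptome

Data mining of inpatient prescription records ("the prescriptome") for
30-day psychiatric readmission risk.

Psychiatric inpatients are readmitted within 30 days of discharge at high
rates, and the full set of drugs prescribed during the index admission is
an easily available but under-used risk signal. This package implements a
pharmacovigilance-style analysis pipeline for that problem, aimed at
clinical data scientists and biostatisticians working with EMR extracts:

- **Per-drug association scan** — one covariate-adjusted logistic model per
  drug, logit P(readmit) = β₀ + β₁·exposure + β₂·age + β₃·male, fitted at
  the posterior mode under weakly informative Cauchy priors (scale 2.5 on
  standardized slopes, 10 on the intercept) so estimates stay finite under
  the complete separation that rare drugs routinely cause. Reported as
  OR = exp(β₁) with 95% Wald CIs and Benjamini–Hochberg q-values; drug
  classes (ATC-style) are tested as member-exposure unions.
- **Side-effect projection and enrichment** — patients are projected onto
  primary adverse-event terms (single-drug reference, Offsides-style TSV)
  and secondary terms (drug-pair interaction reference, Twosides-style
  TSV, over all C(k,2) co-prescription pairs), then each term is tested
  case-vs-control with a 2×2 Fisher exact test and Haldane-corrected OR.
- **Digital comorbidity survey** — pairwise disease co-occurrence odds
  ratios (optionally race-stratified) with network export.
- **Shared genetic architecture** — hypergeometric upper-tail tests of
  gene-set overlap between disease phenotypes, P(X ≥ k) for k shared genes
  between sets of sizes m and n in a universe of N.
- **Calibrated synthetic EMR generator** — a fully synthetic cohort with
  the structure of a real one-year psychiatric inpatient cohort (1275
  discharges, 89 readmitted; group-specific demographics and prescription
  burden; Zipf-skewed drug vocabulary; planted drug and comorbidity
  effects), so the entire pipeline is developed and tested without
  protected health records.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (seed 20140901), writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_cohort_characteristics.py
python analysis/03_drug_association_scan.py
python analysis/04_side_effect_enrichment.py
python analysis/05_comorbidity_genetics.py
```

Step 02 prints the cohort descriptives the generator is calibrated to:

```
                     n    pct  mean_age  pct_male  mean_prescriptions  distinct_drugs
group
readmitted        89.0   6.98     39.71     59.55               12.47           114.0
no_readmission  1186.0  93.02     40.60     50.34                6.31           120.0

Welch test on prescription counts: t = 9.09, p 1.7e-14
```

i.e. 89/1275 = 6.98% readmitted, cases carry roughly twice the
prescription burden of controls (12.47 vs 6.31 records/patient), and the
burden difference is overwhelming by Welch's test. Step 03 then recovers
the three planted drug effects:

```
planted effects vs estimates:
  chlorpromazine: truth OR 4.53, estimate 4.80 (2.99-7.71), p 8.22e-11, CI covers truth: True
  clopidogrel:    truth OR 10.14, estimate 9.18 (4.23-19.95), p 2.13e-08, CI covers truth: True
  pravastatin:    truth OR 13.10, estimate 9.73 (4.73-20.01), p 6.1e-10, CI covers truth: True
```

The common antipsychotic signal is estimated tightly; the two rare
cardiovascular drugs (≈ 30 exposed patients each) get the characteristic
wide intervals. Step 05 reports the planted hypertension + sleep-disorder
comorbidity (OR 2.35, CI 1.75–3.14 against a planted 2.82 in this
realization) and the curated gene modules, e.g. bradycardia and
schizophrenia sharing 8 cardiac-conduction genes (p = 9.1e-06 against the
collection universe).

The same pipeline is available as a CLI for arbitrary TSV/GMT inputs:

```sh
prescriptome simulate --out data/ --seed 7
prescriptome run --in data/ --out results/
prescriptome report results/
```

Input schemas (tab-separated, header required): `patients.tsv`
(patient_id, age, sex, race, admit_date, discharge_date, readmit_date),
`prescriptions.tsv` (patient_id, drug_raw, drug_id), `diagnoses.tsv`
(patient_id, dx_code, dx_name), `drugmap.tsv`, `dxmap.tsv`,
`offsides.tsv`, `twosides.tsv`, `genesets.gmt`.

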