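# Methods

## Problem and model

The package mines the *prescriptome* — the set of all prescription records
over an index inpatient psychiatric admission — for factors associated with
30-day hospital readmission. The outcome is binary: a patient is a *case*
if they are readmitted to any inpatient unit between 1 and 30 days
(inclusive) after discharge from the index admission, a *control*
otherwise. The day-0 boundary is exclusive (a same-day transfer is not a
readmission) and day 30 is inclusive, matching the CMS convention.

Three exposure modalities are analysed:

1. **Drug exposure.** Visit-level binary exposure: `x_ij = 1` if drug *j*
   appears in patient *i*'s prescription record for the visit. Dose, route,
   escalation and adherence are deliberately ignored. For each drug a
   separate logistic model is fitted,

   logit P(readmit) = β₀ + β₁·exposure + β₂·age + β₃·male,

   and the exposure effect is reported as OR = exp(β₁) with a 95% Wald CI
   and a two-sided normal p-value. p-values are corrected across the fitted
   drugs with the Benjamini–Hochberg step-up (the *q*-value). Drug classes
   are tested the same way with class exposure defined as the union of
   member-drug exposures, in a separate BH family.

2. **Primary side effects.** A patient carries an adverse-event term if at
   least one prescribed drug is linked to the term in a single-drug
   reference table (the Offsides-style format: `drug_id, term_id,
   term_name`). Projection is a set union; an audit trail records the
   contributing drugs.

3. **Secondary side effects.** A patient carries a term if at least one
   unordered pair of their co-prescribed drugs maps to the term in a
   drug-pair interaction reference (the Twosides-style format). All C(k,2)
   pairs of a patient's k drugs are enumerated in canonical lexicographic
   order. Interaction severity classes are carried through as an optional
   column but do not alter the statistics.

Term enrichment between cases and controls is a patient-level 2×2 Fisher
exact test (two-sided, point-probability rule) with a Haldane–Anscombe
corrected odds ratio (0.5 added to every cell when any cell is zero). The
enrichment unit is the patient, not the prescription event. BH correction
is applied within each channel separately; a combined family is available
by concatenating the channels before correction.

Two companion analyses connect diseases rather than drugs:

- **Digital comorbidity survey.** For every unordered disease pair (and
  optionally within strata such as race), the has-A × has-B 2×2 table is
  tested with the same Fisher/Haldane machinery, plus a Woolf-type Wald CI
  on the corrected log-OR. Significant pairs export as a disease network
  (GraphML / edge-list TSV) with a neuropsychiatric node flag. The 2×2 is
  unadjusted; a covariate-adjusted logistic alternative can be run through
  the association module on a disease incidence matrix.

- **Shared genetic architecture.** For two disease gene sets A and B over a
  finite universe of N genes, the overlap k = |A∩B| is tested with the
  hypergeometric upper tail P(X ≥ k). The universe defaults to the union
  of all loaded sets and can be overridden with a genome-scale constant;
  this choice changes p-values materially (the overlap counts do not), so
  published tail probabilities are only reproducible when the universe is
  known.

## Separation-robust Bayesian logistic regression

Per-drug 2×2 tables are frequently sparse (a drug prescribed to a handful
of patients, sometimes only cases), so maximum likelihood suffers complete
or quasi-complete separation. `fit_bayes_logistic` returns the posterior
mode under independent weakly informative priors, following the widely
used convention: binary predictors are centered, continuous predictors are
centered and rescaled to SD 0.5, and a Cauchy prior with scale 2.5 is
placed on each slope and scale 10 on the intercept (a Student-t family
with configurable df is available; a flat prior recovers ML). Coefficients
and their covariance are transformed back to the original data scale
before reporting.

Optimization is Newton iteration on the penalized log-likelihood with
step-halving, tolerance 1e-8 on the coefficient change and at most 100
iterations. The Cauchy log-prior is non-concave for |β| > scale, so the
Hessian is Levenberg-damped toward positive definiteness when a Cholesky
factorization fails. Standard errors come from the inverse observed
information (negative Hessian of the log posterior) at the mode. The
contract is enforced by oracle-equivalence tests (agreement with an
independent derivative-free optimizer within 1e-6 penalized log-likelihood
on random small designs, and with IRLS maximum likelihood under a flat
prior), not by the algorithm choice.

Other primitives: Wilson score intervals for binomial proportions (chosen
over Wald/Clopper–Pearson for small-count behaviour), Welch's
unequal-variance t-test for group prescription-count comparisons, and the
hypergeometric tail via the stable survival function. Human-readable
output floors p-values at "< 2.2e-16"; machine outputs keep full
precision.

## The synthetic cohort generator

The generator emulates a one-year single-hospital inpatient psychiatric
cohort: 1275 index discharges, 89 readmitted (6.98%), controls mean age
40.49 with 50.3% male, cases mean age 38.78 with 59.6% male, and mean
prescription records per patient of 12.47 (cases) vs 6.31 (controls).
These group-level descriptives are treated as *conditions of the emulated
study*, not free random variables:

- **Sex** is assigned exactly: round(frac × n) males per outcome group, in
  random order.
- **Prescription counts** are drawn per patient from a negative binomial
  (dispersion size 4 by default — overdispersed counts are the realistic
  regime for inpatient prescribing; the value is configurable) and the
  group total is then nudged by ±1 increments to round(n_group × mean), so
  the group mean is pinned while between-patient overdispersion is
  preserved.
- **Ages** remain fully stochastic: a normal truncated to 18–65 whose
  location is solved numerically so the *truncated* mean equals the
  configured group mean (SD 12 years by default; the study reports no SD).

Drugs are sampled per patient without replacement from a 120-drug
vocabulary with Zipf-like popularity weights (rank^-1.1). Planted
drug–outcome effects are injected through the *exposure* model: for a
planted drug with log-odds-ratio γ, controls are exposed with the
popularity-implied probability p₀ and cases with expit(logit(p₀) + γ).
Because the 2×2 odds ratio is symmetric, the marginal exposure–outcome OR
equals exp(γ) exactly while the case count stays fixed at 89 — outcome
labels are never resampled. Planted drugs are excluded from the popularity
fill so their exposure probabilities are exact. The default configuration
plants three cardiovascular/antipsychotic signals (OR 4.53 at ~9% control
exposure; OR 13.10 and 10.14 at ~1.5% exposure), giving the default cohort
the headline structure of the emulated study: one common moderate signal
and two rare large ones with wide CIs.

Diagnoses are Bernoulli per disease with planted pairwise odds ratios
constructed via the Plackett joint-probability solution; when a disease
participates in more than one planted pair, later pairs are generated
conditionally on the already-assigned partner so every planted OR holds
marginally. Race strata (3 groups at 0.4/0.3/0.3) are assigned by largest
remainder; admission dates are uniform over the calendar year, length of
stay is 1 + Poisson(9) days, and case readmission gaps are uniform on
{1..30} days.

Reference tables are generated in the public-database formats: 0–3
adverse-event terms per drug (terms drawn from the first 50 of a 69-term
vocabulary), ~250 popularity-biased drug-pair interactions (terms from
index 20 upward, so the two ontologies overlap partially, exercising the
ontology-comparison operation), and gene sets over a 500-gene universe
with exact planted pairwise overlaps (defaults: 37 and 25 shared genes).

All randomness flows from a single integer seed through one generator
(reference tables use a spawned child stream so they are independent of
whether the cohort was generated first); identical config + seed yields
byte-identical files.

### What the generator does and does not emulate

It reproduces the cohort's group sizes, demographics, prescription burden,
skewed drug popularity, planted effect structure, and the file formats of
the real references. It does **not** emulate: realistic ICD hierarchies,
longitudinal multi-visit trajectories, medication adherence, correlated
prescribing (drug co-occurrence beyond shared popularity), term
co-occurrence structure of real pharmacovigilance databases, or the
distinct-drug richness of the real cohort (matching that would require
fitting the popularity exponent, which is not reported). Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under a realistic-scale synthetic regime — not that the
pipeline would reproduce any particular finding on protected real records.

One consequence of emulating the burden gap (12.47 vs 6.31) is that
*every* commonly prescribed drug is marginally associated with readmission
in the default cohort — exposure probability rises with prescription
count. This mirrors the confounding-by-burden structure a real
prescriptome scan faces and is why the error-control experiments use a
dedicated global-null configuration (no planted effects **and** equal
group burden).

## Numerical and design choices

- `min_exposed` defaults to 5 but is configurable down to 1; the emulated
  study evidently retained very rare drugs (CIs like 2.82–60.8 imply
  single-digit exposure counts).
- Skipped drugs contribute no p-values: BH m counts fitted drugs only.
- Unknown-sex rows are excluded from model fits and from percent-male
  denominators; zero-variance covariates are dropped from the design with
  a warning.
- Drug normalization is exact case-insensitive lookup against a static
  map; unmatched records are flagged UNMAPPED, counted, and excluded from
  the exposure matrix but still counted as prescription burden.
- "Prescriptions per patient" counts records, not distinct drugs (the two
  coincide in the generator, which draws distinct drugs per patient).
- Degenerate enrichment terms (present in all or no patients) are retained
  with p = 1 and a flag rather than dropped.
- All-zero 2×2 tables return p = 1 with an undefined (NaN) odds ratio.
- Pipeline outputs are a pure function of inputs + configuration; the run
  manifest records input checksums and row counts but no timestamps or
  filesystem paths, so reruns are byte-identical.

## Problem sizes used by the test suite

Monte-Carlo experiments run at the study scale n = 1275: 200 replicate
cohorts for planted-effect CI coverage (drug OR 4.53 and comorbidity OR
2.82, both requiring ≥ 90% coverage), 100 replicates for the global-null
BH check (≥ 95% empty selection sets), and 200 outcome permutations for
enrichment p-value calibration (rejection fraction 0.05 ± 0.02 at α =
0.05; the Fisher test's discreteness keeps the realized rate slightly
below nominal, ~0.04). Oracle-equivalence checks sweep all 2×2 tables with
total ≤ 20 and all hypergeometric configurations with N ≤ 12 plus a
random sample up to N = 50.

## Known limitations

- The Cauchy-prior posterior mode is a point estimate; no full posterior
  (MCMC) or profile-likelihood CIs. Wald intervals on shrunken estimates
  can under-cover for extremely rare exposures.
- Comorbidity ORs are unadjusted for age/sex by default.
- The packaged curated gene modules are a small literature-derived fixture
  for demonstrating the overlap test, not a genome-scale annotation; their
  tail probabilities depend on the universe choice as discussed above.
- The stratified comorbidity scan at ~425 patients per stratum has limited
  power against moderate ORs after BH over 120 pairs; the pooled scan is
  the powered analysis at this scale.
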