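"""Synthetic EMR cohort generator.

Emulates a one-year inpatient psychiatric cohort with a 30-day readmission
outcome: 1275 index discharges of which 89 are readmitted, group-specific
demographics (controls mean age 40.49 with 50.3% male, cases mean age 38.78
with 59.6% male) and group-specific prescription burden (means 12.47 vs 6.31
records per patient).  Drugs are drawn from a skewed (Zipf-like) vocabulary;
selected drugs carry planted log-odds-ratio effects injected through the
*exposure* model — the probability of being prescribed the drug is tilted on
the logit scale by outcome group — so the marginal case count stays fixed
and a downstream association scan becomes a parameter-recovery experiment.

Group-level descriptives that the generator is calibrated to (group mean
prescription counts, percent male) are treated as conditions of the emulated
study rather than free random variables: counts are drawn from a negative
binomial and then the group total is nudged to the configured target, and
the number of males per group is set exactly.  Ages remain stochastic
(truncated normal on 18-65 with the location solved so the truncated mean
equals the configured mean).

Everything is driven by one integer seed; identical config + seed yields
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "ReferenceTables",
    "CohortConfigError",
    "generate_cohort",
    "generate_reference_tables",
    "write_cohort",
    "DRUG_VOCABULARY",
    "DISEASE_TABLE",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str) -> None:
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


# Drug vocabulary ordered by prescribing popularity (rank 1 = most common).
# Psychiatric-unit staples first, then common somatic co-medications.
DRUG_VOCABULARY = [
    "lorazepam", "haloperidol", "olanzapine", "quetiapine", "risperidone",
    "sertraline", "trazodone", "hydroxyzine", "diphenhydramine", "acetaminophen",
    "ibuprofen", "chlorpromazine", "lithium", "valproate", "clonazepam",
    "escitalopram", "fluoxetine", "aripiprazole", "mirtazapine", "melatonin",
    "nicotine", "docusate", "senna", "bisacodyl", "ondansetron",
    "omeprazole", "pantoprazole", "famotidine", "lisinopril", "amlodipine",
    "hydrochlorothiazide", "metoprolol", "propranolol", "atorvastatin", "simvastatin",
    "metformin", "insulin_glargine", "insulin_lispro", "aspirin", "albuterol",
    "levothyroxine", "gabapentin", "duloxetine", "venlafaxine", "bupropion",
    "buspirone", "clozapine", "ziprasidone", "paliperidone", "fluphenazine",
    "perphenazine", "thiothixene", "benztropine", "amantadine", "propafenone",
    "carbamazepine", "lamotrigine", "topiramate", "oxcarbazepine", "pravastatin",
    "rosuvastatin", "losartan", "valsartan", "clopidogrel", "warfarin",
    "apixaban", "enoxaparin", "furosemide", "spironolactone", "digoxin",
    "diltiazem", "verapamil", "isosorbide", "nitroglycerin", "clonidine",
    "prazosin", "terazosin", "tamsulosin", "finasteride", "sildenafil",
    "montelukast", "fluticasone", "ipratropium", "tiotropium", "prednisone",
    "methylprednisolone", "hydrocortisone", "azithromycin", "amoxicillin", "ceftriaxone",
    "ciprofloxacin", "doxycycline", "metronidazole", "nitrofurantoin", "vancomycin",
    "fluconazole", "acyclovir", "oseltamivir", "naltrexone", "methadone",
    "buprenorphine", "tramadol", "oxycodone", "morphine", "fentanyl",
    "ketorolac", "naproxen", "meloxicam", "celecoxib", "allopurinol",
    "colchicine", "cyclobenzaprine", "baclofen", "tizanidine", "donepezil",
    "memantine", "ramelteon", "zolpidem", "eszopiclone", "modafinil",
]

# Brand-name synonyms occasionally emitted as the raw prescription string.
BRAND_SYNONYMS = {
    "clopidogrel": "plavix",
    "pravastatin": "pravachol",
    "chlorpromazine": "thorazine",
    "ondansetron": "zofran",
    "diphenhydramine": "benadryl",
    "quetiapine": "seroquel",
    "sertraline": "zoloft",
}

# (disease_id, dx_code, display name, baseline prevalence, neuropsychiatric)
DISEASE_TABLE = [
    ("major_depressive_disorder", "DX001", "Major depressive disorder", 0.35, True),
    ("anxiety_disorder", "DX002", "Anxiety disorder", 0.30, True),
    ("hypertension", "DX003", "Hypertension", 0.25, False),
    ("substance_use_disorder", "DX004", "Substance use disorder", 0.22, True),
    ("sleep_disorder", "DX005", "Sleep disorder", 0.20, True),
    ("bipolar_disorder", "DX006", "Bipolar disorder", 0.18, True),
    ("schizophrenia", "DX007", "Schizophrenia", 0.15, True),
    ("diabetes_mellitus", "DX008", "Diabetes mellitus", 0.12, False),
    ("psychotic_disorder", "DX009", "Psychotic disorder (other)", 0.12, True),
    ("coronary_artery_disease", "DX010", "Coronary artery disease", 0.10, False),
    ("asthma", "DX011", "Asthma", 0.10, False),
    ("cardiomyopathy", "DX012", "Cardiomyopathy", 0.04, False),
    ("hyperlipidemia", "DX013", "Hyperlipidemia", 0.15, False),
    ("hypothyroidism", "DX014", "Hypothyroidism", 0.08, False),
    ("bradycardia", "DX015", "Bradycardia", 0.05, False),
    ("obesity", "DX016", "Obesity", 0.20, False),
]

# Side-effect term vocabulary (shared id space across the primary and
# interaction references so ontology-overlap comparisons are meaningful).
SIDE_EFFECT_TERMS = [
    "somnolence", "dizziness", "dry_mouth", "nausea", "constipation",
    "fatigue", "headache", "weight_gain", "insomnia", "tremor",
    "orthostatic_hypotension", "qt_prolongation", "st_segment_depression",
    "tachycardia", "bradycardia", "palpitations", "cardiac_ischemia",
    "hypotension", "hypertension", "hyperglycemia", "hyponatremia",
    "hypokalemia", "elevated_transaminases", "rash", "pruritus",
    "photosensitivity", "blurred_vision", "urinary_retention", "diarrhea",
    "vomiting", "dyspepsia", "abdominal_pain", "anorexia", "increased_appetite",
    "akathisia", "dystonia", "parkinsonism", "tardive_dyskinesia", "sedation",
    "confusion", "agitation", "anxiety", "depression", "suicidal_ideation",
    "mania", "seizure", "syncope", "falls", "myalgia",
    "arthralgia", "rheumatoid_arthritis", "back_pain", "muscle_cramps",
    "peripheral_edema", "dyspnea", "cough", "rhinitis", "sweating",
    "fever", "chills", "anemia", "leukopenia", "thrombocytopenia",
    "bleeding", "bruising", "atrial_fibrillation", "heart_failure",
    "renal_impairment", "hepatotoxicity", "pancreatitis",
]


def _default_planted_effects() -> list[tuple[str, float]]:
    # headline cardiovascular / antipsychotic signals the default cohort plants
    return [
        ("chlorpromazine", math.log(4.53)),
        ("pravastatin", math.log(13.10)),
        ("clopidogrel", math.log(10.14)),
    ]


def _default_comorbidity_pairs() -> list[tuple[str, str, float]]:
    return [
        ("hypertension", "sleep_disorder", 2.82),
        ("coronary_artery_disease", "sleep_disorder", 1.75),
    ]


def _default_race_fractions() -> dict[str, float]:
    return {
        "european_american": 0.4,
        "hispanic_latino": 0.3,
        "african_american": 0.3,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults encode the emulated study."""

    n_patients: int = 1275
    n_cases: int = 89
    age_mean_controls: float = 40.49
    age_mean_cases: float = 38.78
    age_sd: float = 12.0
    age_min: int = 18
    age_max: int = 65
    male_frac_controls: float = 0.503
    male_frac_cases: float = 0.596
    rx_mean_cases: float = 12.47
    rx_mean_controls: float = 6.31
    rx_dispersion: float = 4.0
    n_drugs: int = 120
    popularity_exponent: float = 1.1
    planted_effects: list[tuple[str, float]] = field(default_factory=_default_planted_effects)
    race_fractions: dict[str, float] = field(default_factory=_default_race_fractions)
    n_diseases: int = 16
    comorbidity_pairs: list[tuple[str, str, float]] = field(default_factory=_default_comorbidity_pairs)
    year: int = 2014
    seed: int = 20140901

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 0:
            raise CohortConfigError("n_patients", "must be >= 0")
        if not 0 <= self.n_cases <= self.n_patients:
            raise CohortConfigError("n_cases", "must satisfy 0 <= n_cases <= n_patients")
        for name in ("male_frac_controls", "male_frac_cases"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(name, "must lie in [0, 1]")
        for name in ("rx_mean_cases", "rx_mean_controls"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(name, "must be > 0")
        if self.rx_dispersion <= 0:
            raise CohortConfigError("rx_dispersion", "must be > 0")
        if not 1 <= self.n_drugs <= len(DRUG_VOCABULARY):
            raise CohortConfigError(
                "n_drugs", f"must lie in [1, {len(DRUG_VOCABULARY)}]"
            )
        if self.age_sd <= 0:
            raise CohortConfigError("age_sd", "must be > 0")
        vocab = set(DRUG_VOCABULARY[: self.n_drugs])
        for drug, _ in self.planted_effects:
            if drug not in vocab:
                raise CohortConfigError(
                    "planted_effects", f"drug {drug!r} not in the first n_drugs of the vocabulary"
                )
        if self.race_fractions:
            total = sum(self.race_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise CohortConfigError("race_fractions", f"must sum to 1 (got {total})")
            if any(v < 0 for v in self.race_fractions.values()):
                raise CohortConfigError("race_fractions", "fractions must be >= 0")
        if not 1 <= self.n_diseases <= len(DISEASE_TABLE):
            raise CohortConfigError(
                "n_diseases", f"must lie in [1, {len(DISEASE_TABLE)}]"
            )
        diseases = {row[0] for row in DISEASE_TABLE[: self.n_diseases]}
        for da, db, orr in self.comorbidity_pairs:
            if da not in diseases or db not in diseases:
                raise CohortConfigError(
                    "comorbidity_pairs", f"pair ({da}, {db}) references an unknown disease"
                )
            if orr <= 0:
                raise CohortConfigError("comorbidity_pairs", "odds ratios must be > 0")
        if not 0 <= int(self.seed) < 2**31:
            raise CohortConfigError("seed", "must be a non-negative 31-bit integer")

    # -- convenience --------------------------------------------------------
    def drug_names(self) -> list[str]:
        return DRUG_VOCABULARY[: self.n_drugs]

    def popularity_weights(self) -> np.ndarray:
        r = np.arange(1, self.n_drugs + 1, dtype=float)
        w = r ** (-self.popularity_exponent)
        return w / w.sum()

    def planted_base_exposure(self, drug: str) -> float:
        """Control-group exposure probability implied by the drug's popularity."""
        w = self.popularity_weights()[self.drug_names().index(drug)]
        return float(1.0 - (1.0 - w) ** self.rx_mean_controls)

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "planted_effects" in d:
            d["planted_effects"] = [(str(a), float(b)) for a, b in d["planted_effects"]]
        if "comorbidity_pairs" in d:
            d["comorbidity_pairs"] = [
                (str(a), str(b), float(c)) for a, b, c in d["comorbidity_pairs"]
            ]
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_effects"] = [list(t) for t in d["planted_effects"]]
        d["comorbidity_pairs"] = [list(t) for t in d["comorbidity_pairs"]]
        return d


@dataclass
class ReferenceTables:
    """Format-compatible single-drug, drug-pair and gene-set references."""

    offsides: pd.DataFrame  # drug_id, term_id, term_name
    twosides: pd.DataFrame  # drug_a, drug_b, term_id, term_name, severity
    genesets: "object"      # comorbidity.GeneSetCollection


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    drug_map: pd.DataFrame      # drug_raw, drug_id
    dx_map: pd.DataFrame        # dx_code, disease_id, disease_name, neuropsychiatric_flag
    truth: dict


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location whose [lo, hi]-truncated normal mean equals ``target_mean``."""

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(
        optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo + 1e-6, hi - 1e-6)
    )


def _sample_ages(rng: np.random.Generator, n: int, mean: float, cfg: CohortConfig) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    loc = _truncnorm_loc(mean, cfg.age_sd, cfg.age_min, cfg.age_max)
    a = (cfg.age_min - loc) / cfg.age_sd
    b = (cfg.age_max - loc) / cfg.age_sd
    ages = sps.truncnorm.rvs(a, b, loc=loc, scale=cfg.age_sd, size=n, random_state=rng)
    return np.clip(np.rint(ages), cfg.age_min, cfg.age_max).astype(int)


def _exact_binary(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """n draws with exactly round(frac * n) ones, in random order."""
    k = int(round(frac * n))
    out = np.zeros(n, dtype=bool)
    out[:k] = True
    rng.shuffle(out)
    return out


def _largest_remainder(fracs: dict[str, float], n: int) -> dict[str, int]:
    labels = sorted(fracs)
    raw = {lab: fracs[lab] * n for lab in labels}
    counts = {lab: int(math.floor(raw[lab])) for lab in labels}
    short = n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: (raw[l] - counts[l], l), reverse=True)[:short]:
        counts[lab] += 1
    return counts


def _nb_counts(
    rng: np.random.Generator,
    n: int,
    mean: float,
    size: float,
    cap: int,
    target_total: int,
) -> np.ndarray:
    """Negative-binomial counts nudged so the group total hits target_total."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if target_total > cap * n:
        raise CohortConfigError("rx_mean_cases", "target prescriptions exceed vocabulary capacity")
    mean = max(mean, 1e-9)
    p = size / (size + mean)
    counts = np.minimum(rng.negative_binomial(size, p, n), cap).astype(int)
    delta = int(target_total - counts.sum())
    while delta != 0:
        i = int(rng.integers(n))
        if delta > 0 and counts[i] < cap:
            counts[i] += 1
            delta -= 1
        elif delta < 0 and counts[i] > 0:
            counts[i] -= 1
            delta += 1
    return counts


def _weighted_sample_rows(
    rng: np.random.Generator, weights: np.ndarray, counts: np.ndarray
) -> list[np.ndarray]:
    """Per-row weighted sampling without replacement (Efraimidis-Spirakis keys)."""
    n, m = counts.size, weights.size
    if n == 0:
        return []
    keys = np.log(rng.random((n, m))) / weights  # larger key = picked earlier
    order = np.argsort(-keys, axis=1)
    return [order[i, : counts[i]] for i in range(n)]


def _joint_prob_from_or(pa: float, pb: float, orr: float) -> float:
    """P(A and B) given the margins and the odds ratio (Plackett construction)."""
    if abs(orr - 1.0) < 1e-12:
        return pa * pb
    s = 1.0 + (pa + pb) * (orr - 1.0)
    disc = s * s - 4.0 * orr * (orr - 1.0) * pa * pb
    p11 = (s - math.sqrt(disc)) / (2.0 * (orr - 1.0))
    return float(min(max(p11, 0.0), min(pa, pb)))


# ---------------------------------------------------------------------------
# main operations
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (patients, prescriptions, diagnoses).

    Deterministic in (config, seed): the same configuration always produces
    identical tables.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_patients
    n_cases = config.n_cases
    n_controls = n - n_cases

    # case/control labels in randomized patient order
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True
    rng.shuffle(is_case)
    patient_id = np.array([f"P{i + 1:06d}" for i in range(n)])

    # demographics per group
    age = np.zeros(n, dtype=int)
    sex_male = np.zeros(n, dtype=bool)
    for mask, age_mean, male_frac in (
        (is_case, config.age_mean_cases, config.male_frac_cases),
        (~is_case, config.age_mean_controls, config.male_frac_controls),
    ):
        k = int(mask.sum())
        age[mask] = _sample_ages(rng, k, age_mean, config)
        sex_male[mask] = _exact_binary(rng, k, male_frac)

    race = np.array([""] * n, dtype=object)
    if config.race_fractions:
        counts = _largest_remainder(config.race_fractions, n)
        pool = np.concatenate([[lab] * c for lab, c in sorted(counts.items())]) if n else np.array([])
        rng.shuffle(pool)
        race = pool.astype(object)

    # dates: index admission during the configured year
    admit_day = rng.integers(0, 365, size=n)
    los = 1 + rng.poisson(9.0, size=n)
    base = pd.Timestamp(f"{config.year}-01-01")
    admit = base + pd.to_timedelta(admit_day, unit="D")
    discharge = admit + pd.to_timedelta(los, unit="D")
    gap = rng.integers(1, 31, size=n)  # cases readmit within 1..30 days
    readmit = discharge + pd.to_timedelta(gap, unit="D")
    readmit = pd.Series(readmit).where(pd.Series(is_case), pd.NaT)

    # ---- prescriptions ----------------------------------------------------
    names = config.drug_names()
    weights = config.popularity_weights()
    planted = {drug: lor for drug, lor in config.planted_effects}
    planted_idx = [names.index(d) for d in planted]
    free_idx = np.array([j for j in range(config.n_drugs) if j not in set(planted_idx)])
    free_w = weights[free_idx]
    free_w = free_w / free_w.sum() if free_idx.size else free_w

    # planted exposures: Bernoulli with group-tilted probability
    exposure_rows: list[list[int]] = [[] for _ in range(n)]
    planted_truth = {}
    for drug in planted:
        j = names.index(drug)
        p0 = config.planted_base_exposure(drug)
        logit0 = math.log(p0 / (1.0 - p0))
        p1 = 1.0 / (1.0 + math.exp(-(logit0 + planted[drug])))
        prob = np.where(is_case, p1, p0)
        exposed = rng.random(n) < prob
        for i in np.flatnonzero(exposed):
            exposure_rows[i].append(j)
        planted_truth[drug] = {
            "log_odds_ratio": planted[drug],
            "odds_ratio": math.exp(planted[drug]),
            "exposure_prob_controls": p0,
            "exposure_prob_cases": p1,
            "n_exposed": int(exposed.sum()),
        }

    # fill with non-planted drugs, pinning the group totals
    planted_counts = np.array([len(r) for r in exposure_rows])
    for mask, mean in ((is_case, config.rx_mean_cases), (~is_case, config.rx_mean_controls)):
        k = int(mask.sum())
        if k == 0:
            continue
        target = int(round(mean * k)) - int(planted_counts[mask].sum())
        target = max(target, 0)
        fill_mean = max(mean - planted_counts[mask].mean(), 0.05)
        fills = _nb_counts(rng, k, fill_mean, config.rx_dispersion, free_idx.size, target)
        rows = _weighted_sample_rows(rng, free_w, fills)
        for i, picks in zip(np.flatnonzero(mask), rows):
            exposure_rows[i].extend(free_idx[picks].tolist())

    rx_patient: list[str] = []
    rx_raw: list[str] = []
    rx_id: list[str] = []
    for i in range(n):
        for j in sorted(exposure_rows[i]):
            name = names[j]
            u = rng.random()
            if name in BRAND_SYNONYMS and u < 0.15:
                raw = BRAND_SYNONYMS[name]
            elif u < 0.45:
                raw = name.upper()
            elif u < 0.60:
                raw = name.capitalize()
            else:
                raw = name
            rx_patient.append(patient_id[i])
            rx_raw.append(raw)
            rx_id.append(name)

    prescriptions = pd.DataFrame(
        {"patient_id": rx_patient, "drug_raw": rx_raw, "drug_id": rx_id}
    )

    # ---- diagnoses --------------------------------------------------------
    disease_rows = DISEASE_TABLE[: config.n_diseases]
    prevalence = {d: p for d, _, _, p, _ in disease_rows}
    code = {d: c for d, c, _, _, _ in disease_rows}
    dname = {d: nm for d, _, nm, _, _ in disease_rows}
    has: dict[str, np.ndarray | None] = {d: None for d in prevalence}
    for da, db, orr in config.comorbidity_pairs:
        pa, pb = prevalence[da], prevalence[db]
        if has[da] is not None and has[db] is not None:
            raise CohortConfigError(
                "comorbidity_pairs", f"both diseases of ({da}, {db}) already constrained"
            )
        if has[da] is None and has[db] is None:
            p11 = _joint_prob_from_or(pa, pb, orr)
            probs = np.clip([p11, pa - p11, pb - p11, 1.0 - pa - pb + p11], 0.0, None)
            cells = rng.choice(4, size=n, p=probs / probs.sum())
            has[da] = (cells == 0) | (cells == 1)
            has[db] = (cells == 0) | (cells == 2)
        else:
            # one partner already assigned (shared across pairs): tilt the
            # free disease conditional on the assigned one so both planted
            # odds ratios hold marginally
            if has[da] is not None:
                da, db, pa, pb = db, da, pb, pa
            p11 = _joint_prob_from_or(pa, pb, orr)
            p1 = p11 / pb if pb > 0 else 0.0
            p0 = (pa - p11) / (1.0 - pb) if pb < 1 else 0.0
            prob = np.where(has[db], p1, p0)
            has[da] = rng.random(n) < prob
    for d, p in prevalence.items():
        if has[d] is None:
            has[d] = rng.random(n) < p

    dx_patient: list[str] = []
    dx_code: list[str] = []
    dx_name: list[str] = []
    for d in prevalence:
        for i in np.flatnonzero(has[d]):
            dx_patient.append(patient_id[i])
            dx_code.append(code[d])
            dx_name.append(dname[d])
    diagnoses = (
        pd.DataFrame({"patient_id": dx_patient, "dx_code": dx_code, "dx_name": dx_name})
        .sort_values(["patient_id", "dx_code"], kind="stable")
        .reset_index(drop=True)
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age": age,
            "sex": np.where(sex_male, "male", "female"),
            "race": race,
            "admit_date": pd.Series(admit).dt.date,
            "discharge_date": pd.Series(discharge).dt.date,
            "readmit_date": pd.Series(readmit).dt.date,
            "readmitted_30d": is_case,
        }
    )

    # normalization map: canonical names plus brand synonyms
    map_raw = list(names) + [BRAND_SYNONYMS[d] for d in names if d in BRAND_SYNONYMS]
    map_id = list(names) + [d for d in names if d in BRAND_SYNONYMS]
    drug_map = pd.DataFrame({"drug_raw": map_raw, "drug_id": map_id})

    dx_map = pd.DataFrame(
        {
            "dx_code": [c for _, c, _, _, _ in disease_rows],
            "disease_id": [d for d, _, _, _, _ in disease_rows],
            "disease_name": [nm for _, _, nm, _, _ in disease_rows],
            "neuropsychiatric_flag": [int(f) for _, _, _, _, f in disease_rows],
        }
    )

    truth = {
        "config": config.to_dict(),
        "planted_drug_effects": planted_truth,
        "planted_comorbidity_pairs": [list(t) for t in config.comorbidity_pairs],
        "n_prescriptions": int(len(prescriptions)),
    }
    return SyntheticCohort(patients, prescriptions, diagnoses, drug_map, dx_map, truth)


def generate_reference_tables(
    config: CohortConfig,
    *,
    max_terms_per_drug: int = 3,
    n_interaction_pairs: int = 250,
    n_genes: int = 500,
    set_size: int = 45,
    planted_overlaps: list[tuple[str, str, int]] | None = None,
) -> ReferenceTables:
    """Synthetic single-drug side-effect, drug-pair interaction and gene-set
    references, format-compatible with the real public databases they emulate.

    ``planted_overlaps`` plants an exact shared-gene count between two disease
    sets (default: cardiomyopathy/anxiety_disorder share 37 genes and
    coronary_artery_disease/schizophrenia share 25).
    """
    from .comorbidity import GeneSetCollection  # local import, avoids a cycle

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    names = config.drug_names()
    n_terms = len(SIDE_EFFECT_TERMS)
    term_ids = [f"SE{i + 1:03d}" for i in range(n_terms)]
    term_w = np.arange(1, n_terms + 1, dtype=float) ** -0.8
    term_w /= term_w.sum()

    # primary reference: terms drawn from the first 50 of the vocabulary
    prim_pool = np.arange(50)
    rows = []
    for drug in names:
        k = int(rng.integers(0, max_terms_per_drug + 1))
        if k == 0:
            continue
        w = term_w[prim_pool] / term_w[prim_pool].sum()
        picks = rng.choice(prim_pool, size=min(k, prim_pool.size), replace=False, p=w)
        for t in sorted(picks):
            rows.append((drug, term_ids[t], SIDE_EFFECT_TERMS[t]))
    offsides = pd.DataFrame(rows, columns=["drug_id", "term_id", "term_name"])

    # interaction reference: popular-drug-biased pairs, terms from index >= 20
    sec_pool = np.arange(20, n_terms)
    drug_w = config.popularity_weights()
    severities = ["contraindication", "serious", "significant", "minor"]
    seen = set()
    rows = []
    attempts = 0
    while len(seen) < n_interaction_pairs and attempts < 50 * n_interaction_pairs:
        attempts += 1
        i, j = rng.choice(config.n_drugs, size=2, replace=False, p=drug_w)
        a, b = sorted((names[i], names[j]))
        w = term_w[sec_pool] / term_w[sec_pool].sum()
        t = int(rng.choice(sec_pool, p=w))
        key = (a, b, term_ids[t])
        if key in seen:
            continue
        seen.add(key)
        sev = severities[int(rng.integers(len(severities)))]
        rows.append((a, b, term_ids[t], SIDE_EFFECT_TERMS[t], sev))
    twosides = pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "term_id", "term_name", "severity"]
    ).sort_values(["drug_a", "drug_b", "term_id"], kind="stable").reset_index(drop=True)

    # gene sets over a finite universe, with planted pairwise overlaps
    if planted_overlaps is None:
        planted_overlaps = [
            ("cardiomyopathy", "anxiety_disorder", 37),
            ("coronary_artery_disease", "schizophrenia", 25),
        ]
    universe = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    diseases = [d for d, *_ in DISEASE_TABLE[: config.n_diseases]]
    sets: dict[str, set[str]] = {d: set() for d in diseases}
    available = list(universe)
    rng.shuffle(available)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > len(available):
            raise CohortConfigError("n_diseases", "gene universe too small for requested sets")
        out = available[cursor : cursor + k]
        cursor += k
        return out

    for da, db, k in planted_overlaps:
        if da not in sets or db not in sets:
            raise CohortConfigError("comorbidity_pairs", f"unknown disease in planted overlap ({da}, {db})")
        shared = take(k)
        sets[da].update(shared)
        sets[db].update(shared)
        sets[da].update(take(max(set_size - len(sets[da]), 0)))
        sets[db].update(take(max(set_size - len(sets[db]), 0)))
    for d in diseases:
        if not sets[d]:
            sets[d] = set(rng.choice(universe, size=set_size, replace=False))
    genesets = GeneSetCollection(
        sets={d: frozenset(g) for d, g in sets.items()}, universe=frozenset(universe)
    )
    return ReferenceTables(offsides=offsides, twosides=twosides, genesets=genesets)


def write_cohort(cohort: SyntheticCohort, directory, refs: ReferenceTables | None = None) -> list[str]:
    """Write the cohort (and optionally the reference tables) as TSV/GMT files.

    Returns the list of file names written.  Files round-trip losslessly
    through the ingest module.
    """
    import json
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    patients = cohort.patients.drop(columns=["readmitted_30d"], errors="ignore").copy()
    for col in ("admit_date", "discharge_date", "readmit_date"):
        patients[col] = patients[col].map(lambda d: "" if pd.isna(d) else d.isoformat())
    pre = cohort.prescriptions.copy()
    pre["drug_id"] = ""  # canonical ids are assigned by normalization on ingest

    tables = {
        "patients.tsv": patients,
        "prescriptions.tsv": pre,
        "diagnoses.tsv": cohort.diagnoses,
        "drugmap.tsv": cohort.drug_map,
        "dxmap.tsv": cohort.dx_map,
    }
    if refs is not None:
        tables["offsides.tsv"] = refs.offsides
        tables["twosides.tsv"] = refs.twosides
    for fname, df in tables.items():
        df.to_csv(out / fname, sep="\t", index=False, lineterminator="\n")
        written.append(fname)
    if refs is not None:
        refs.genesets.to_gmt(out / "genesets.gmt")
        written.append("genesets.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    written.append("truth.json")
    return written
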