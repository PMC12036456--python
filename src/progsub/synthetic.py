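"""Synthetic longitudinal EHR cohorts with planted progression subphenotypes.

The real study population (MCI patients converting to Alzheimer's dementia,
observed through routine-care EHRs) is private, so every downstream stage is
exercised on simulated cohorts.  The simulator plants the structure the
method is supposed to recover:

* per-patient irregular encounter times over up to ten years of observation,
* a three-stage progression (preclinical -> MCI -> AD) with stage-onset
  diagnosis codes recorded at encounters,
* subphenotype-specific comorbidity-code prevalence profiles,
* subphenotype-specific MCI->AD transition-time distributions
  (gamma, parameterized by mean/sd, truncated below at one day), and
* subphenotype-specific constant post-AD death hazards.

Cohort inclusion/exclusion filtering mirrors the study design: an MCI
diagnosis, age >= 50 at first MCI, no AD code before MCI, at least one year
of records before and after the index (first MCI) date, and a conversion
time above six months for converters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab

SCHEMA_PREFIX = "# progsub-schema:"

SEX_CATEGORIES = ("F", "M")
RACE_CATEGORIES = ("NHW", "NHB", "Hispanic", "Other")
SMOKING_CATEGORIES = ("current", "former", "non-smoker", "other")

# Default per-subphenotype MCI->AD transition-time (mean, sd) in days and
# post-AD daily death hazards.  Means/sds follow the reported range for four
# progression subphenotypes (805-1236 day means with large spreads); hazards
# give the slower-progressing, comorbidity-heavy groups worse 5-year survival.
DEFAULT_TRANSITION_DAYS = ((854.0, 577.0), (1236.0, 725.0), (952.0, 628.0), (805.0, 563.0))
DEFAULT_POST_AD_HAZARD = (1.0 / 2400, 1.0 / 1100, 1.0 / 1300, 1.0 / 2600)


@dataclass(frozen=True)
class Encounter:
    date: date
    diagnosis_codes: tuple[str, ...] = ()
    drug_codes: tuple[str, ...] = ()
    bmi: float | None = None
    systolic: float | None = None
    diastolic: float | None = None
    smoking: str | None = None


@dataclass
class PatientTimeline:
    """One patient's demographics, dated encounters and stage-onset dates."""

    patient_id: str
    birth_date: date
    sex: str
    race_ethnicity: str
    encounters: list[Encounter]
    first_mci_date: date | None = None
    first_ad_date: date | None = None
    death_date: date | None = None
    true_subphenotype: int | None = None

    def __post_init__(self) -> None:
        dates = [e.date for e in self.encounters]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("encounter dates must be non-decreasing")
        if (
            self.first_ad_date is not None
            and self.first_mci_date is not None
            and self.first_ad_date < self.first_mci_date
        ):
            raise ValueError("first_ad_date must be >= first_mci_date")
        if self.death_date is not None and dates and self.death_date < dates[-1]:
            raise ValueError("death_date must be >= last encounter date")

    def age_at(self, when: date) -> float:
        return (when - self.birth_date).days / 365.25


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 300
    n_subphenotypes: int = 4
    code_vocabulary: tuple[str, ...] = ()
    # patient-level condition prevalence: P(a patient of subphenotype i has
    # the chronic condition j); a possessed condition is coded at each
    # encounter with probability code_recurrence
    prevalence_profiles: np.ndarray | None = None  # (n_subphenotypes, n_codes)
    code_recurrence: float = 0.6
    transition_time_days: tuple[tuple[float, float], ...] = DEFAULT_TRANSITION_DAYS
    pre_mci_years: tuple[float, float] = (1.0, 3.0)
    encounter_gap_days: tuple[float, float] = (105.0, 50.0)
    post_ad_hazard: tuple[float, ...] = DEFAULT_POST_AD_HAZARD
    age_at_entry: tuple[float, float] = (72.0, 8.88)
    sex_probs: tuple[float, ...] = (0.6166, 0.3834)
    race_probs: tuple[float, ...] = (0.6483, 0.1648, 0.1085, 0.0784)
    # long enough that the slowest planted transition distribution is
    # effectively fully observed, so planted means are recoverable
    observation_years: float = 12.0
    entry_window_days: int = 1095
    vitals_prob: float = 0.9
    smoking_probs: tuple[float, ...] = (0.08, 0.22, 0.65, 0.05)
    stage_code_prob: float = 0.8  # MCI/AD code recurrence after onset
    anti_dementia_prob: float = 0.35  # N06D prescriptions after first MCI
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.code_vocabulary:
            self.code_vocabulary = default_code_vocabulary()
        if self.prevalence_profiles is None:
            self.prevalence_profiles = default_prevalence_profiles(
                self.n_subphenotypes, self.code_vocabulary
            )
        self.prevalence_profiles = np.asarray(self.prevalence_profiles, dtype=float)
        # adapt the class defaults to a non-default subphenotype count
        n = self.n_subphenotypes
        if self.transition_time_days == DEFAULT_TRANSITION_DAYS and len(
                self.transition_time_days) != n:
            self.transition_time_days = tuple(
                DEFAULT_TRANSITION_DAYS[i % len(DEFAULT_TRANSITION_DAYS)] for i in range(n))
        if self.post_ad_hazard == DEFAULT_POST_AD_HAZARD and len(self.post_ad_hazard) != n:
            self.post_ad_hazard = tuple(
                DEFAULT_POST_AD_HAZARD[i % len(DEFAULT_POST_AD_HAZARD)] for i in range(n))

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_subphenotypes < 1:
            raise ValueError("n_subphenotypes must be >= 1")
        if self.prevalence_profiles.shape != (self.n_subphenotypes, len(self.code_vocabulary)):
            raise ValueError("prevalence_profiles shape must be (n_subphenotypes, n_codes)")
        if np.any(self.prevalence_profiles < 0) or np.any(self.prevalence_profiles > 1):
            raise ValueError("prevalence_profiles values must lie in [0, 1]")
        if len(self.transition_time_days) != self.n_subphenotypes:
            raise ValueError("transition_time_days needs one (mean, sd) per subphenotype")
        for mean, sd in self.transition_time_days:
            if mean <= 0 or sd <= 0:
                raise ValueError("transition_time_days means and sds must be positive")
        if len(self.post_ad_hazard) != self.n_subphenotypes:
            raise ValueError("post_ad_hazard needs one rate per subphenotype")
        if any(h <= 0 for h in self.post_ad_hazard):
            raise ValueError("post_ad_hazard rates must be positive")
        for name, probs in (("sex_probs", self.sex_probs), ("race_probs", self.race_probs),
                            ("smoking_probs", self.smoking_probs)):
            if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.pre_mci_years[0] < 0 or self.pre_mci_years[1] < self.pre_mci_years[0]:
            raise ValueError("pre_mci_years must satisfy 0 <= min <= max")
        if self.encounter_gap_days[0] <= 0 or self.encounter_gap_days[1] < 0:
            raise ValueError("encounter_gap_days mean must be positive, sd nonnegative")
        for name, p in (("vitals_prob", self.vitals_prob),
                        ("code_recurrence", self.code_recurrence),
                        ("stage_code_prob", self.stage_code_prob),
                        ("anti_dementia_prob", self.anti_dementia_prob)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def default_code_vocabulary() -> tuple[str, ...]:
    """Comorbidity + drug codes available to the generator (stage codes excluded)."""
    dx = sorted(c for c in vocab.DEMO_ICD_TO_PHECODE
                if c not in vocab.MCI_CODES and c not in vocab.AD_CODES
                and not c[0].isdigit())  # keep one source code per Phecode (ICD-10 style)
    rx = sorted(c for c in vocab.DEMO_DRUG_TO_ATC3 if c != "rx:donepezil" and c != "rx:memantine")
    return tuple(dx + rx)


# Signature comorbidity groups giving each subphenotype a distinct profile:
# cardio/musculoskeletal fast progressors, an infection/hematopoietic group,
# a mood/digestive/neoplasm group, and a hypertensive/metabolic group.
_SIGNATURES = (
    ("I48.91", "I25.10", "M19.90", "M54.5", "rx:metoprolol", "rx:ibuprofen"),
    ("N39.0", "D64.9", "G47.00", "R53.83", "rx:nitrofurantoin", "rx:sertraline"),
    ("F32.9", "F41.9", "K21.9", "D49.9", "rx:escitalopram", "rx:omeprazole"),
    ("I10", "E78.5", "E11.9", "K59.00", "rx:amlodipine", "rx:metformin"),
)


def default_prevalence_profiles(
    n_subphenotypes: int,
    vocabulary: tuple[str, ...],
    signature_prob: float = 0.9,
    background_prob: float = 0.05,
) -> np.ndarray:
    """Distinct per-subphenotype patient-level condition prevalences.

    Essential hypertension is prevalent everywhere (the dominant cohort
    feature); each subphenotype additionally carries its signature chronic
    conditions at high prevalence against a low shared background.
    """
    profiles = np.full((n_subphenotypes, len(vocabulary)), background_prob)
    idx = {c: j for j, c in enumerate(vocabulary)}
    for i in range(n_subphenotypes):
        for code in _SIGNATURES[i % len(_SIGNATURES)]:
            if code in idx:
                profiles[i, idx[code]] = signature_prob
    if "I10" in idx:
        profiles[:, idx["I10"]] = np.maximum(profiles[:, idx["I10"]], 0.55)
    return profiles


def _gamma_from_mean_sd(rng: np.random.Generator, mean: float, sd: float) -> float:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def simulate_cohort(spec: CohortSpec) -> list[PatientTimeline]:
    """Draw a reproducible cohort of patient timelines from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    origin = date(2012, 1, 1)
    vocab_arr = list(spec.code_vocabulary)
    is_drug = np.array([c.startswith("rx:") for c in vocab_arr])
    timelines: list[PatientTimeline] = []

    for i in range(spec.n_patients):
        sub = int(rng.integers(spec.n_subphenotypes))
        entry = origin + timedelta(days=int(rng.integers(spec.entry_window_days)))
        age0 = float(rng.normal(*spec.age_at_entry))
        birth = entry - timedelta(days=int(round(age0 * 365.25)))
        sex = SEX_CATEGORIES[int(rng.choice(len(SEX_CATEGORIES), p=spec.sex_probs))]
        race = RACE_CATEGORIES[int(rng.choice(len(RACE_CATEGORIES), p=spec.race_probs))]

        pre_days = rng.uniform(*spec.pre_mci_years) * 365.25
        trans_days = max(1.0, _gamma_from_mean_sd(rng, *spec.transition_time_days[sub]))
        mci_offset = pre_days
        ad_offset = pre_days + trans_days
        death_offset = ad_offset + rng.exponential(1.0 / spec.post_ad_hazard[sub])
        obs_end = spec.observation_years * 365.25
        horizon = min(death_offset, obs_end)

        # irregular encounter schedule from entry to the horizon,
        # strictly increasing integer day offsets (one encounter per day)
        offsets: list[int] = [0]
        while True:
            gap = max(1.0, rng.normal(*spec.encounter_gap_days))
            nxt = max(offsets[-1] + 1, int(round(offsets[-1] + gap)))
            if nxt > horizon:
                break
            offsets.append(nxt)

        # chronic condition set drawn once per patient; possessed conditions
        # recur in the coding at each encounter
        has_condition = rng.random(len(vocab_arr)) < spec.prevalence_profiles[sub]
        encounters: list[Encounter] = []
        first_mci: date | None = None
        first_ad: date | None = None
        for off in offsets:
            d = entry + timedelta(days=off)
            draws = has_condition & (rng.random(len(vocab_arr)) < spec.code_recurrence)
            dx = [c for c, hit, drug in zip(vocab_arr, draws, is_drug) if hit and not drug]
            rx = [c for c, hit, drug in zip(vocab_arr, draws, is_drug) if hit and drug]
            stage_mci = off >= mci_offset
            stage_ad = off >= ad_offset
            if stage_ad:
                if first_ad is None or rng.random() < spec.stage_code_prob:
                    dx.append("G30.9")
                    if first_ad is None:
                        first_ad = d
            elif stage_mci:
                if first_mci is None or rng.random() < spec.stage_code_prob:
                    dx.append("G31.84")
                    if first_mci is None:
                        first_mci = d
            if stage_mci and rng.random() < spec.anti_dementia_prob:
                rx.append("rx:donepezil")
            has_vitals = rng.random() < spec.vitals_prob
            enc = Encounter(
                date=d,
                diagnosis_codes=tuple(sorted(set(dx))),
                drug_codes=tuple(sorted(set(rx))),
                bmi=float(np.clip(rng.normal(27.5, 4.5), 15, 55)) if has_vitals else None,
                systolic=float(np.clip(rng.normal(131, 16), 85, 220)) if has_vitals else None,
                diastolic=float(np.clip(rng.normal(78, 10), 45, 130)) if has_vitals else None,
                smoking=SMOKING_CATEGORIES[int(rng.choice(4, p=spec.smoking_probs))]
                if has_vitals else None,
            )
            encounters.append(enc)
        # AD onset requires an encounter at/after ad_offset; a patient whose
        # observation ends first never receives the AD diagnosis.
        death = None
        if death_offset <= obs_end and first_ad is not None:
            death = entry + timedelta(days=int(np.ceil(death_offset)))

        timelines.append(
            PatientTimeline(
                patient_id=f"P{i:05d}",
                birth_date=birth,
                sex=sex,
                race_ethnicity=race,
                encounters=encounters,
                first_mci_date=first_mci,
                first_ad_date=first_ad,
                death_date=death,
                true_subphenotype=sub,
            )
        )
    return timelines


@dataclass(frozen=True)
class InclusionCriteria:
    """Thresholds of the cohort filters (days)."""

    min_age_years: float = 50.0
    lookback_days: int = 365
    followup_days: int = 365
    min_conversion_days: int = 183  # "more than six months"


#: Fixed rule order used to attribute each excluded patient to its first
#: failing rule, funnel-style.
EXCLUSION_RULES = (
    "no_mci_diagnosis",
    "age_under_minimum",
    "ad_before_mci",
    "insufficient_lookback_or_followup",
    "conversion_within_six_months",
)


def _first_failing_rule(t: PatientTimeline, c: InclusionCriteria) -> str | None:
    if t.first_mci_date is None:
        return "no_mci_diagnosis"
    if t.age_at(t.first_mci_date) < c.min_age_years:
        return "age_under_minimum"
    if t.first_ad_date is not None and t.first_ad_date < t.first_mci_date:
        return "ad_before_mci"
    if not t.encounters:
        return "insufficient_lookback_or_followup"
    first, last = t.encounters[0].date, t.encounters[-1].date
    if (t.first_mci_date - first).days < c.lookback_days or (
        last - t.first_mci_date
    ).days < c.followup_days:
        return "insufficient_lookback_or_followup"
    if (
        t.first_ad_date is not None
        and (t.first_ad_date - t.first_mci_date).days <= c.min_conversion_days
    ):
        return "conversion_within_six_months"
    return None


def apply_inclusion_criteria(
    timelines: list[PatientTimeline],
    criteria: InclusionCriteria = InclusionCriteria(),
) -> tuple[list[PatientTimeline], dict[str, int]]:
    """Apply the cohort filters; never raises.

    Returns the included timelines and a per-rule count of exclusions,
    each excluded patient attributed to the first failing rule in
    :data:`EXCLUSION_RULES` order.
    """
    counts = {rule: 0 for rule in EXCLUSION_RULES}
    included = []
    for t in timelines:
        rule = _first_failing_rule(t, criteria)
        if rule is None:
            included.append(t)
        else:
            counts[rule] += 1
    return included, counts


# ---------------------------------------------------------------------------
# Delimited-text table I/O (simplified PCORnet-style schema)
# ---------------------------------------------------------------------------

_TABLES = {
    "demographic": ["patid", "birth_date", "sex", "race_ethnicity"],
    "encounter": ["patid", "date"],
    "diagnosis": ["patid", "date", "code", "code_type"],
    "prescribing": ["patid", "date", "drug_code"],
    "vital": ["patid", "date", "bmi", "systolic", "diastolic", "smoking"],
    "death": ["patid", "death_date"],
    "truth": ["patid", "subphenotype", "first_mci_date", "first_ad_date", "death_date"],
}


def _write_table(df: pd.DataFrame, path: Path, name: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX} {name} v1\n")
        df.to_csv(fh, index=False)


def read_table(path: Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        expected = f"{SCHEMA_PREFIX} {name} v1"
        if header != expected:
            raise ValueError(f"{path}: schema mismatch: got {header!r}, expected {expected!r}")
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLES[name] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_cohort_tables(timelines: list[PatientTimeline], directory) -> dict[str, Path]:
    """Write the cohort as delimited-text tables; round-trips through
    :func:`read_cohort_tables`.  The ``truth`` table (planted labels and
    stage dates) is only written when the simulator set them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list] = {name: [] for name in _TABLES}
    for t in timelines:
        rows["demographic"].append((t.patient_id, t.birth_date.isoformat(), t.sex, t.race_ethnicity))
        for e in t.encounters:
            d = e.date.isoformat()
            rows["encounter"].append((t.patient_id, d))
            for code in e.diagnosis_codes:
                code_type = "09" if code[0].isdigit() else "10"
                rows["diagnosis"].append((t.patient_id, d, code, code_type))
            for code in e.drug_codes:
                rows["prescribing"].append((t.patient_id, d, code))
            if e.bmi is not None or e.systolic is not None or e.smoking is not None:
                rows["vital"].append((
                    t.patient_id, d,
                    "" if e.bmi is None else repr(e.bmi),
                    "" if e.systolic is None else repr(e.systolic),
                    "" if e.diastolic is None else repr(e.diastolic),
                    e.smoking or "",
                ))
        if t.death_date is not None:
            rows["death"].append((t.patient_id, t.death_date.isoformat()))
        if t.true_subphenotype is not None:
            rows["truth"].append((
                t.patient_id, t.true_subphenotype,
                "" if t.first_mci_date is None else t.first_mci_date.isoformat(),
                "" if t.first_ad_date is None else t.first_ad_date.isoformat(),
                "" if t.death_date is None else t.death_date.isoformat(),
            ))
    paths = {}
    for name, cols in _TABLES.items():
        if name == "truth" and not rows["truth"]:
            continue
        df = pd.DataFrame(rows[name], columns=cols)
        paths[name] = directory / f"{name}.csv"
        _write_table(df, paths[name], name)
    return paths


def _parse_date(s: str) -> date | None:
    return None if s == "" else date.fromisoformat(s)


def read_cohort_tables(directory) -> list[PatientTimeline]:
    """Reconstruct patient timelines from tables written by
    :func:`write_cohort_tables`.

    Stage-onset dates are re-derived from the MCI/AD diagnosis code sets, so
    labeling can never disagree with the recorded diagnoses.
    """
    directory = Path(directory)
    demo = read_table(directory / "demographic.csv", "demographic")
    enc = read_table(directory / "encounter.csv", "encounter")
    dx = read_table(directory / "diagnosis.csv", "diagnosis")
    rx = read_table(directory / "prescribing.csv", "prescribing")
    vit = read_table(directory / "vital.csv", "vital")
    death_path = directory / "death.csv"
    death = read_table(death_path, "death") if death_path.exists() else pd.DataFrame(columns=_TABLES["death"])
    truth_path = directory / "truth.csv"
    truth = read_table(truth_path, "truth") if truth_path.exists() else None

    dx_map: dict[tuple[str, str], list[str]] = {}
    for r in dx.itertuples(index=False):
        dx_map.setdefault((r.patid, r.date), []).append(r.code)
    rx_map: dict[tuple[str, str], list[str]] = {}
    for r in rx.itertuples(index=False):
        rx_map.setdefault((r.patid, r.date), []).append(r.drug_code)
    vit_map = {(r.patid, r.date): r for r in vit.itertuples(index=False)}
    enc_map: dict[str, list[str]] = {}
    for r in enc.itertuples(index=False):
        enc_map.setdefault(r.patid, []).append(r.date)
    death_map = {r.patid: _parse_date(r.death_date) for r in death.itertuples(index=False)}
    truth_map = {}
    if truth is not None:
        truth_map = {r.patid: int(r.subphenotype) for r in truth.itertuples(index=False)}

    timelines = []
    for r in demo.itertuples(index=False):
        pid = r.patid
        encounters = []
        first_mci = first_ad = None
        for ds in sorted(enc_map.get(pid, [])):
            d = date.fromisoformat(ds)
            codes = tuple(sorted(set(dx_map.get((pid, ds), []))))
            drugs = tuple(sorted(set(rx_map.get((pid, ds), []))))
            v = vit_map.get((pid, ds))
            encounters.append(Encounter(
                date=d, diagnosis_codes=codes, drug_codes=drugs,
                bmi=None if v is None or v.bmi == "" else float(v.bmi),
                systolic=None if v is None or v.systolic == "" else float(v.systolic),
                diastolic=None if v is None or v.diastolic == "" else float(v.diastolic),
                smoking=None if v is None or v.smoking == "" else v.smoking,
            ))
            if first_mci is None and any(c in vocab.MCI_CODES for c in codes):
                first_mci = d
            if first_ad is None and any(c in vocab.AD_CODES for c in codes):
                first_ad = d
        timelines.append(PatientTimeline(
            patient_id=pid,
            birth_date=date.fromisoformat(r.birth_date),
            sex=r.sex,
            race_ethnicity=r.race_ethnicity,
            encounters=encounters,
            first_mci_date=first_mci,
            first_ad_date=first_ad,
            death_date=death_map.get(pid),
            true_subphenotype=truth_map.get(pid),
        ))
    timelines.sort(key=lambda t: t.patient_id)
    return timelines


def timelines_equal(a: list[PatientTimeline], b: list[PatientTimeline]) -> bool:
    return [dataclasses.asdict(t) for t in a] == [dataclasses.asdict(t) for t in b]
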