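"""Enhanced encounter representations.

Each encounter is encoded as a binary vector concatenating one-hot
demographics (uniform age bins, sex, race-ethnicity), Phecode indicators for
diagnoses and ATC level-3 indicators for medications recorded within a
three-month look-back window, and one-hot discretized vitals (BMI category,
ACC/AHA blood-pressure class, smoking status).  Alongside each vector we
carry the patient's stage on the AD continuum at that encounter
(preclinical, MCI, AD) and the stage at the chronologically next encounter,
which is the supervision target for the outcome-oriented encoder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .synthetic import PatientTimeline
from .vocab import DEMO_DRUG_TO_ATC3, DEMO_ICD_TO_PHECODE

STAGES = ("preclinical", "MCI", "AD")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
BP_CLASSES = ("normal", "elevated", "stage1", "stage2", "crisis")
SMOKING_CATEGORIES = ("current", "former", "non-smoker", "other")
SEX_CATEGORIES = ("F", "M")
RACE_CATEGORIES = ("NHW", "NHB", "Hispanic", "Other")

AGE_ORIGIN = 50.0
AGE_BIN_WIDTH = 5.0
N_AGE_BINS = 9  # 50-54 ... 90+, top bin open-ended
DEFAULT_LOOKBACK_DAYS = 91  # three-month window, half-open (t-91, t]


def discretize_bmi(bmi: float | None) -> str | None:
    """BMI (kg/m^2) -> category; half-open bins (underweight < 18.5 <= normal
    < 25 <= overweight < 30 <= obese)."""
    if bmi is None:
        return None
    if bmi <= 0 or math.isnan(bmi):
        raise ValueError(f"invalid BMI measurement: {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def _bp_component_class(value: float, thresholds: tuple[float, float, float, float]) -> int:
    crisis, stage2, stage1, elevated = thresholds
    if value > crisis:
        return 4
    if value >= stage2:
        return 3
    if value >= stage1:
        return 2
    if elevated is not None and value >= elevated:
        return 1
    return 0


def discretize_bp(systolic: float | None, diastolic: float | None) -> str | None:
    """ACC/AHA 2017 classification; the more severe component wins.

    normal <120/<80, elevated 120-129/<80, stage 1 130-139 or 80-89,
    stage 2 >=140 or >=90, crisis >180 or >120.
    """
    if systolic is None and diastolic is None:
        return None
    if systolic is None or diastolic is None:
        warnings.warn("one blood-pressure reading missing; treating vitals as missing")
        return None
    if systolic <= 0 or diastolic <= 0:
        raise ValueError(f"invalid blood pressure: {systolic}/{diastolic}")
    sys_cls = _bp_component_class(systolic, (180.0, 140.0, 130.0, 120.0))
    dia_cls = _bp_component_class(diastolic, (120.0, 90.0, 80.0, None))
    return BP_CLASSES[max(sys_cls, dia_cls)]


def bin_age(age_years: float, bin_width: float = AGE_BIN_WIDTH,
            origin: float = AGE_ORIGIN, n_bins: int = N_AGE_BINS) -> int:
    """Uniform-width age bin index, clipped to [0, n_bins-1]."""
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    idx = math.floor((age_years - origin) / bin_width)
    return int(min(max(idx, 0), n_bins - 1))


def map_codes(codes, mapping: dict[str, str]) -> tuple[frozenset[str], int]:
    """Roll source codes up through a mapping table.

    Unmapped codes are dropped and counted (second return value); many-to-one
    rollups collapse to a single target code.
    """
    mapped = set()
    unmapped = 0
    for c in codes:
        target = mapping.get(c)
        if target is None:
            unmapped += 1
        else:
            mapped.add(target)
    return frozenset(mapped), unmapped


def assign_stage(timeline: PatientTimeline, when: date) -> str:
    """Stage on the AD continuum at a given date.

    Boundaries are inclusive for the later stage: the index (first MCI) date
    is MCI, the first AD date is AD.
    """
    if timeline.first_mci_date is None:
        raise ValueError(f"{timeline.patient_id}: no first MCI date")
    if when < timeline.first_mci_date:
        return "preclinical"
    if timeline.first_ad_date is None or when < timeline.first_ad_date:
        return "MCI"
    return "AD"


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered, block-partitioned coordinate system of the encounter vectors."""

    blocks: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def names(self) -> list[str]:
        return [f"{b}:{n}" for b, feats in self.blocks for n in feats]

    @property
    def dimension(self) -> int:
        return sum(len(feats) for _, feats in self.blocks)

    def offset(self, block: str) -> int:
        off = 0
        for b, feats in self.blocks:
            if b == block:
                return off
            off += len(feats)
        raise KeyError(block)

    def block_features(self, block: str) -> tuple[str, ...]:
        for b, feats in self.blocks:
            if b == block:
                return feats
        raise KeyError(block)

    def index(self, block: str, feature: str) -> int:
        return self.offset(block) + self.block_features(block).index(feature)

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


def build_feature_space(
    icd_to_phecode: dict[str, str] | None = None,
    drug_to_atc3: dict[str, str] | None = None,
    n_age_bins: int = N_AGE_BINS,
) -> FeatureSpace:
    icd_to_phecode = DEMO_ICD_TO_PHECODE if icd_to_phecode is None else icd_to_phecode
    drug_to_atc3 = DEMO_DRUG_TO_ATC3 if drug_to_atc3 is None else drug_to_atc3
    phecodes = tuple(sorted(set(icd_to_phecode.values())))
    atc3 = tuple(sorted(set(drug_to_atc3.values())))
    return FeatureSpace(blocks=(
        ("age", tuple(f"bin{i}" for i in range(n_age_bins))),
        ("sex", SEX_CATEGORIES),
        ("race", RACE_CATEGORIES),
        ("phecode", phecodes),
        ("atc3", atc3),
        ("bmi", BMI_CATEGORIES),
        ("bp", BP_CLASSES),
        ("smoking", SMOKING_CATEGORIES),
    ))


@dataclass
class EncounterVector:
    """The enhanced encounter representation plus its stage labels."""

    patient_id: str
    date: date
    vector: np.ndarray  # uint8, length = FeatureSpace.dimension
    stage: str
    next_stage: str | None  # None for the patient's last encounter


def _set_onehot(vec: np.ndarray, space: FeatureSpace, block: str, feature: str | None) -> None:
    if feature is not None:
        vec[space.index(block, feature)] = 1


def build_encounter_vectors(
    timeline: PatientTimeline,
    space: FeatureSpace,
    icd_to_phecode: dict[str, str] | None = None,
    drug_to_atc3: dict[str, str] | None = None,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> list[EncounterVector]:
    """One binary vector per encounter, in chronological order.

    Code indicators fire iff the rolled-up code occurs in the half-open
    window (t - lookback_days, t]; vital one-hots use the most recent
    measurement in the same window; missing values leave their block all
    zero.  The next-encounter stage is the supervised target; the last
    encounter gets ``next_stage=None`` and is excluded from training loss.
    """
    icd_to_phecode = DEMO_ICD_TO_PHECODE if icd_to_phecode is None else icd_to_phecode
    drug_to_atc3 = DEMO_DRUG_TO_ATC3 if drug_to_atc3 is None else drug_to_atc3
    if len(timeline.encounters) < 2:
        raise ValueError(
            f"{timeline.patient_id}: need >= 2 encounters to define next-encounter outcomes"
        )
    encs = timeline.encounters
    out: list[EncounterVector] = []
    for i, enc in enumerate(encs):
        lo = enc.date - timedelta(days=lookback_days)
        window = [e for e in encs if lo < e.date <= enc.date]
        vec = np.zeros(space.dimension, dtype=np.uint8)
        _set_onehot(vec, space, "age", f"bin{bin_age(timeline.age_at(enc.date))}")
        if timeline.sex in SEX_CATEGORIES:
            _set_onehot(vec, space, "sex", timeline.sex)
        if timeline.race_ethnicity in RACE_CATEGORIES:
            _set_onehot(vec, space, "race", timeline.race_ethnicity)
        dx = {c for e in window for c in e.diagnosis_codes}
        rx = {c for e in window for c in e.drug_codes}
        phecodes, _ = map_codes(dx, icd_to_phecode)
        atc3, _ = map_codes(rx, drug_to_atc3)
        pheblock = set(space.block_features("phecode"))
        atcblock = set(space.block_features("atc3"))
        for p in phecodes & pheblock:
            vec[space.index("phecode", p)] = 1
        for a in atc3 & atcblock:
            vec[space.index("atc3", a)] = 1
        bmi = next((e.bmi for e in reversed(window) if e.bmi is not None), None)
        bp = next(
            ((e.systolic, e.diastolic) for e in reversed(window)
             if e.systolic is not None and e.diastolic is not None),
            None,
        )
        smoking = next((e.smoking for e in reversed(window) if e.smoking is not None), None)
        _set_onehot(vec, space, "bmi", discretize_bmi(bmi))
        if bp is not None:
            _set_onehot(vec, space, "bp", discretize_bp(*bp))
        if smoking in SMOKING_CATEGORIES:
            _set_onehot(vec, space, "smoking", smoking)
        stage = assign_stage(timeline, enc.date)
        next_stage = assign_stage(timeline, encs[i + 1].date) if i + 1 < len(encs) else None
        out.append(EncounterVector(timeline.patient_id, enc.date, vec, stage, next_stage))
    return out
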