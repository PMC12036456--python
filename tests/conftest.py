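from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from progsub import synthetic as syn
from progsub.featurize import build_feature_space
from progsub.synthetic import Encounter, PatientTimeline


@pytest.fixture(scope="session")
def feature_space():
    return build_feature_space()


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients, 4 planted subphenotypes, fixed seed."""
    return syn.simulate_cohort(syn.CohortSpec(n_patients=40, seed=7))


@pytest.fixture(scope="session")
def included_cohort(small_cohort):
    included, _ = syn.apply_inclusion_criteria(small_cohort)
    return included


def make_timeline(
    patient_id="T0001",
    birth=date(1940, 1, 1),
    encounter_days=(0, 200, 420, 700, 900, 1200),
    start=date(2013, 1, 1),
    mci_day=420,
    ad_day=1200,
    death_day=None,
    codes_by_day=None,
    sex="F",
    race="NHW",
):
    """Hand-built deterministic timeline; the MCI/AD onset encounters carry
    the stage-defining diagnosis codes."""
    codes_by_day = codes_by_day or {}
    encounters = []
    for d in encounter_days:
        codes = list(codes_by_day.get(d, ()))
        if mci_day is not None and d == mci_day:
            codes.append("G31.84")
        if ad_day is not None and d == ad_day:
            codes.append("G30.9")
        encounters.append(Encounter(
            date=start + timedelta(days=d),
            diagnosis_codes=tuple(sorted(codes)),
            bmi=26.0, systolic=118.0, diastolic=76.0, smoking="non-smoker",
        ))
    return PatientTimeline(
        patient_id=patient_id,
        birth_date=birth,
        sex=sex,
        race_ethnicity=race,
        encounters=encounters,
        first_mci_date=start + timedelta(days=mci_day) if mci_day is not None else None,
        first_ad_date=start + timedelta(days=ad_day) if ad_day is not None else None,
        death_date=start + timedelta(days=death_day) if death_day is not None else None,
    )


@pytest.fixture
def toy_timeline():
    return make_timeline()
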