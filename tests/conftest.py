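"""Shared fixtures: a hand-placed deterministic claims bundle, small
simulated bundles, and random-bundle builders for oracle comparisons."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from mm_lookback.claims_model import ClaimsBundle, CohortSpec, Condition, DiseaseList
from mm_lookback.synthetic_claims import default_config, generate_bundle

INDEX = date(2019, 4, 1)


def make_bundle(persons_rows, coverage_rows=(), hospital_rows=(), physician_rows=(), drug_rows=()):
    """Assemble a ClaimsBundle from plain tuples (validated)."""
    persons = pd.DataFrame(persons_rows, columns=["person_id", "birth_date", "sex", "material_dep", "social_dep", "death_date"])
    coverage = pd.DataFrame(list(coverage_rows), columns=["person_id", "start_date", "end_date"])
    hospital = pd.DataFrame(list(hospital_rows), columns=["person_id", "stay_id", "admission_date", "discharge_date", "code", "position"])
    physician = pd.DataFrame(list(physician_rows), columns=["person_id", "service_date", "code", "setting", "provider_type", "is_ed"])
    drugs = pd.DataFrame(list(drug_rows), columns=["person_id", "claim_date", "denomination"])
    return ClaimsBundle(persons, coverage, hospital, physician, drugs).validate()


@pytest.fixture(scope="session")
def cohort() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def mini_list() -> DiseaseList:
    """Three synthetic demo conditions, one with a 5-year lookback cap."""
    return DiseaseList(
        name="mini",
        conditions=(
            Condition("chf", "Heart failure", ("428",), ("I50",)),
            Condition("dep", "Depression", ("311",), ("F32",), mental=True, remitting=True),
            Condition("capped", "Capped condition", ("493",), ("J45",), overrides={"max_lookback_years": 5}),
        ),
    )


def _p(pid, birth, death=None):
    return (pid, birth, "F", "Q2", "Q3", death)


@pytest.fixture(scope="session")
def tiny_bundle() -> ClaimsBundle:
    """Hand-placed claims with known minimal lookbacks against `mini_list`.

    P1: hospital CHF claim 30 days before index          -> chf minimal LP 1
    P2: physician CHF claims 40 days apart, ~2y back     -> chf minimal LP 3
    P3: physician CHF claims 19 days apart only          -> never
    P4: physician CHF claims 760 days apart only         -> never (span > 730)
    P5: capped-condition hospital claim 11 years back    -> never (cap 5)
        and CHF physician claims at day 0 / +40 / +800   -> qualifies via (0, 40)
    P6: hospital capped-condition claim 4 years back     -> capped minimal LP 4
    """
    birth = date(1950, 6, 15)
    rows = [
        _p("P1", birth), _p("P2", birth), _p("P3", birth),
        _p("P4", birth), _p("P5", birth), _p("P6", birth),
    ]
    hospital = [
        ("P1", "S1", INDEX - timedelta(days=30), INDEX - timedelta(days=25), "I50.0", "secondary"),
        ("P5", "S2", date(2008, 4, 10), date(2008, 4, 20), "J45.1", "primary"),
        ("P6", "S3", date(2015, 5, 1), date(2015, 5, 3), "J450", "admission"),
    ]
    d0 = date(2016, 6, 1)
    physician = [
        ("P2", date(2017, 2, 1), "4280", "outpatient", "GP", False),
        ("P2", date(2017, 3, 13), "4281", "outpatient", "specialist", False),
        ("P3", date(2018, 5, 1), "4280", "outpatient", "GP", False),
        ("P3", date(2018, 5, 20), "4280", "outpatient", "GP", False),
        ("P4", date(2015, 1, 1), "4280", "outpatient", "GP", False),
        ("P4", date(2017, 1, 31), "4280", "outpatient", "GP", False),
        ("P5", d0, "4280", "outpatient", "GP", False),
        ("P5", d0 + timedelta(days=40), "4280", "outpatient", "GP", False),
        ("P5", d0 + timedelta(days=800), "4280", "outpatient", "GP", False),
    ]
    coverage = [(pid, date(1998, 4, 1), date(2020, 6, 1)) for pid, *_ in rows]
    return make_bundle(rows, coverage, hospital, physician)


@pytest.fixture(scope="session")
def small_sim():
    """Default-scenario simulated bundle at modest size (shared, read-only)."""
    cfg = default_config(n_persons=800, seed=11)
    bundle, truth = generate_bundle(cfg)
    return cfg, bundle, truth


def random_small_bundle(rng: np.random.Generator, conditions: DiseaseList, cohort: CohortSpec) -> ClaimsBundle:
    """A randomized tiny bundle (<= 20 persons, <= 50 claims) whose claim
    dates straddle all window boundaries, for oracle comparisons."""
    n = int(rng.integers(1, 21))
    persons = [
        (
            f"R{i:02d}",
            date(1940 + int(rng.integers(0, 13)), int(rng.integers(1, 13)), int(rng.integers(1, 29))),
            "F" if rng.random() < 0.5 else "M",
            "Q1", "Q1", None,
        )
        for i in range(n)
    ]
    span_days = 365 * (cohort.max_lookback_years + 1)
    codes9 = ["4280", "3110", "4930"]
    codes10 = ["I500", "F320", "J450"]
    hospital, physician = [], []
    n_claims = int(rng.integers(0, 51))
    for j in range(n_claims):
        pid = f"R{int(rng.integers(0, n)):02d}"
        d = cohort.index_date - timedelta(days=int(rng.integers(1, span_days)))
        ci = int(rng.integers(0, 3))
        code = codes10[ci] if d >= (cohort.hospital_icd10_from if rng.random() < 0.3 else cohort.physician_icd10_from) else codes9[ci]
        if rng.random() < 0.3:
            era_code = codes10[ci] if d >= cohort.hospital_icd10_from else codes9[ci]
            hospital.append((pid, f"S{j}", d, d + timedelta(days=int(rng.integers(1, 10))), era_code, "secondary"))
        else:
            era_code = codes10[ci] if d >= cohort.physician_icd10_from else codes9[ci]
            physician.append((pid, d, era_code, "outpatient", "GP", False))
    return make_bundle(persons, [], hospital, physician)
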