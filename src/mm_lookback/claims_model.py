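"""Domain types and I/O for administrative-claims bundles.

The in-memory container for a study population is a :class:`ClaimsBundle`:
a person table plus hospital, physician, drug and coverage tables sharing a
``person_id`` key, mirroring how single-payer claims registries (RAMQ /
MED-ECHO style) are linked in practice.  All tables are plain
:class:`pandas.DataFrame` objects with ISO-8601 dates, read from and written
to delimited text so that fixtures stay diffable.

Disease lists map named condition groups to ICD-9 / ICD-10 code prefixes.
Matching is prefix-based on normalised codes (upper-cased, dots stripped),
which also represents exact-code lists as full-length prefixes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "IntegrityError",
    "Condition",
    "AscertainmentRule",
    "DiseaseList",
    "CohortSpec",
    "ClaimsBundle",
    "read_claims_bundle",
    "write_claims_bundle",
    "load_disease_list",
    "code_matches",
    "normalize_code",
    "age_at",
    "years_before",
    "era_of",
]

# Québec coding-era switch dates: hospital abstracts moved to ICD-10-CA for
# discharges after fiscal 2005-06; physician claims switched on 2019-01-01.
HOSPITAL_ICD10_FROM = date(2006, 4, 1)
PHYSICIAN_ICD10_FROM = date(2019, 1, 1)

SEXES = ("F", "M")
DEPRIVATION_LEVELS = ("Q1", "Q2", "Q3", "Q4", "Q5", "missing")
DIAGNOSIS_POSITIONS = ("admission", "primary", "secondary")

PERSON_COLUMNS = ["person_id", "birth_date", "sex", "material_dep", "social_dep", "death_date"]
COVERAGE_COLUMNS = ["person_id", "start_date", "end_date"]
HOSPITAL_COLUMNS = ["person_id", "stay_id", "admission_date", "discharge_date", "code", "position"]
PHYSICIAN_COLUMNS = ["person_id", "service_date", "code", "setting", "provider_type", "is_ed"]
DRUG_COLUMNS = ["person_id", "claim_date", "denomination"]

_DATE_COLUMNS = {
    "persons": ["birth_date", "death_date"],
    "coverage": ["start_date", "end_date"],
    "hospital": ["admission_date", "discharge_date"],
    "physician": ["service_date"],
    "drugs": ["claim_date"],
}
_SCHEMAS = {
    "persons": PERSON_COLUMNS,
    "coverage": COVERAGE_COLUMNS,
    "hospital": HOSPITAL_COLUMNS,
    "physician": PHYSICIAN_COLUMNS,
    "drugs": DRUG_COLUMNS,
}


class SchemaError(ValueError):
    """A table is missing required columns or holds out-of-domain values."""


class IntegrityError(ValueError):
    """Referential or ordering constraints between tables are violated."""


# ---------------------------------------------------------------------------
# calendar helpers


def years_before(d: date, years: int) -> date:
    """Same calendar day ``years`` earlier; Feb 29 maps to Feb 28."""
    try:
        return d.replace(year=d.year - years)
    except ValueError:  # Feb 29 in a non-leap target year
        return d.replace(year=d.year - years, day=28)


def age_at(birth_date: date, at: date) -> int:
    """Completed years of age at ``at`` (floor of the calendar difference)."""
    if at < birth_date:
        raise ValueError(f"date {at} precedes birth date {birth_date}")
    had_birthday = (at.month, at.day) >= (birth_date.month, birth_date.day)
    return at.year - birth_date.year - (0 if had_birthday else 1)


def era_of(d: date, icd10_from: date) -> str:
    """Coding era ('ICD9' or 'ICD10') of a claim dated ``d``."""
    return "ICD10" if d >= icd10_from else "ICD9"


# ---------------------------------------------------------------------------
# disease lists


def normalize_code(code: str) -> str:
    """Upper-case an ICD code and strip dot punctuation and whitespace."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class AscertainmentRule:
    """Resolved case-definition parameters for one condition.

    Defaults encode the generic claims case definition: one hospital
    diagnosis in any position, or ``min_physician_claims`` physician-claim
    diagnoses on distinct days spanning at least ``min_spacing_days`` and at
    most ``max_pair_span_days``.  ``max_lookback_years`` caps the effective
    retrospective window for the condition (None = no cap).
    """

    min_physician_claims: int = 2
    min_spacing_days: int = 30
    max_pair_span_days: int = 730
    max_lookback_years: int | None = None

    def __post_init__(self) -> None:
        if self.min_physician_claims < 1:
            raise ValueError("min_physician_claims must be >= 1")
        for name in ("min_spacing_days", "max_pair_span_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_lookback_years is not None and self.max_lookback_years <= 0:
            raise ValueError("max_lookback_years must be strictly positive")


@dataclass(frozen=True)
class Condition:
    """One chronic-condition group with its ICD code prefixes per era."""

    condition_id: str
    label: str
    icd9_patterns: tuple[str, ...]
    icd10_patterns: tuple[str, ...]
    mental: bool = False
    remitting: bool = False
    overrides: Mapping[str, int] | None = None
    disease_specific: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.icd9_patterns or not self.icd10_patterns:
            raise ValueError(f"condition {self.condition_id!r} needs at least one pattern per era")
        object.__setattr__(self, "icd9_patterns", tuple(normalize_code(p) for p in self.icd9_patterns))
        object.__setattr__(self, "icd10_patterns", tuple(normalize_code(p) for p in self.icd10_patterns))
        for source in (self.overrides, self.disease_specific):
            if source:
                bad = set(source) - set(f.name for f in dataclasses.fields(AscertainmentRule))
                if bad:
                    raise ValueError(f"unknown override keys for {self.condition_id!r}: {sorted(bad)}")
                if any(v is not None and v <= 0 for v in source.values()):
                    raise ValueError(f"override values for {self.condition_id!r} must be strictly positive")

    def patterns(self, era: str) -> tuple[str, ...]:
        return self.icd9_patterns if era == "ICD9" else self.icd10_patterns

    def rule(self, use_disease_specific: bool = False) -> AscertainmentRule:
        """Resolve overrides (and optionally disease-specific ones) into a rule."""
        params: dict = {}
        if self.overrides:
            params.update(self.overrides)
        if use_disease_specific and self.disease_specific:
            params.update(self.disease_specific)
        return AscertainmentRule(**params)


def code_matches(code: str, condition: Condition, era: str) -> bool:
    """True iff ``code`` starts with one of the condition's prefixes for ``era``.

    Matching is case-insensitive and ignores dot punctuation, so 'I50.0'
    matches the prefix 'I50'.
    """
    norm = normalize_code(code)
    return any(norm.startswith(p) for p in condition.patterns(era))


@dataclass(frozen=True)
class DiseaseList:
    """A named catalogue of condition groups counted toward multimorbidity."""

    name: str
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        ids = [c.condition_id for c in self.conditions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate condition_id(s) in list {self.name!r}: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def get(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def replace_conditions(self, conditions: Iterable[Condition], name: str | None = None) -> "DiseaseList":
        return DiseaseList(name=name or self.name, conditions=tuple(conditions))


def load_disease_list(config_path: str | Path) -> DiseaseList:
    """Parse and validate a disease-list YAML config.

    Schema::

        name: L20
        conditions:
          - id: heart_failure
            label: Heart failure
            icd9: ["428"]
            icd10: ["I50"]
            mental: false            # optional
            remitting: false         # optional
            overrides: {max_lookback_years: 5}          # optional
            disease_specific: {min_physician_claims: 2} # optional
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "conditions" not in raw:
        raise SchemaError(f"{config_path}: expected a mapping with a 'conditions' key")
    conditions = []
    for entry in raw["conditions"]:
        missing = {"id", "label", "icd9", "icd10"} - set(entry)
        if missing:
            raise SchemaError(f"{config_path}: condition entry missing keys {sorted(missing)}")
        conditions.append(
            Condition(
                condition_id=str(entry["id"]),
                label=str(entry["label"]),
                icd9_patterns=tuple(str(p) for p in entry["icd9"]),
                icd10_patterns=tuple(str(p) for p in entry["icd10"]),
                mental=bool(entry.get("mental", False)),
                remitting=bool(entry.get("remitting", False)),
                overrides=entry.get("overrides"),
                disease_specific=entry.get("disease_specific"),
            )
        )
    return DiseaseList(name=str(raw.get("name", Path(config_path).stem)), conditions=tuple(conditions))


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortSpec:
    """Cohort definition: index date, minimum age and retrospective depth.

    The study design is an over-65 cohort at a fiscal-year index date with a
    one-year outcome follow-up and up to 20 retrospective years of claims.
    Coding-era switch dates are carried here so synthetic scenarios can move
    them.
    """

    index_date: date = date(2019, 4, 1)
    followup_end: date = date(2020, 3, 31)
    min_age_years: int = 66
    max_lookback_years: int = 20
    hospital_icd10_from: date = HOSPITAL_ICD10_FROM
    physician_icd10_from: date = PHYSICIAN_ICD10_FROM

    def __post_init__(self) -> None:
        if self.followup_end <= self.index_date:
            raise ValueError("followup_end must be after index_date")
        if self.max_lookback_years < 1:
            raise ValueError("max_lookback_years must be >= 1")

    def lookback_window(self, lp: int) -> tuple[date, date]:
        """Half-open retrospective window [index − lp years, index)."""
        if not 1 <= lp <= self.max_lookback_years:
            raise ValueError(f"lookback {lp} outside 1..{self.max_lookback_years}")
        return years_before(self.index_date, lp), self.index_date

    def lp_boundaries(self) -> list[date]:
        """Window start dates for LP = 1..max_lookback_years (descending)."""
        return [years_before(self.index_date, lp) for lp in range(1, self.max_lookback_years + 1)]


# ---------------------------------------------------------------------------
# bundle


@dataclass
class ClaimsBundle:
    """Linked claim tables for one study population.

    Tables: ``persons`` (one row per person, death date folded in),
    ``coverage`` (public drug-plan intervals), ``hospital`` (long format, one
    row per discharge diagnosis with its position), ``physician`` (one
    diagnosis per claim) and ``drugs`` (one row per pharmacy claim).
    """

    persons: pd.DataFrame
    coverage: pd.DataFrame
    hospital: pd.DataFrame
    physician: pd.DataFrame
    drugs: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "coverage": self.coverage,
            "hospital": self.hospital,
            "physician": self.physician,
            "drugs": self.drugs,
        }

    def cohort_persons(self, cohort: CohortSpec) -> pd.DataFrame:
        """Persons meeting the cohort's age floor and alive at index date."""
        p = self.persons
        ages = p["birth_date"].map(lambda b: age_at(b, cohort.index_date))
        alive = p["death_date"].isna() | (p["death_date"] >= cohort.index_date)
        return p.loc[(ages >= cohort.min_age_years) & alive].reset_index(drop=True)

    def validate(self) -> "ClaimsBundle":
        _validate_bundle(self)
        return self


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in _SCHEMAS[name]})
    if name == "physician":
        df["is_ed"] = pd.Series(dtype=bool)
    return df


def empty_bundle() -> ClaimsBundle:
    return ClaimsBundle(**{name: _empty_table(name) for name in _SCHEMAS})


def _validate_bundle(bundle: ClaimsBundle) -> None:
    for name, df in bundle.tables().items():
        missing = [c for c in _SCHEMAS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"table {name!r} missing column(s): {missing}")
    persons = bundle.persons
    if persons["person_id"].duplicated().any():
        dupes = persons.loc[persons["person_id"].duplicated(), "person_id"].tolist()
        raise IntegrityError(f"duplicate person_id(s) in persons table: {dupes[:10]}")
    known = set(persons["person_id"])
    for name in ("coverage", "hospital", "physician", "drugs"):
        ids = bundle.tables()[name]["person_id"]
        orphans = sorted(set(ids) - known)
        if orphans:
            raise IntegrityError(f"table {name!r} references unknown person_id(s): {orphans[:10]}")
    has_death = persons["death_date"].notna()
    if (persons.loc[has_death, "death_date"] < persons.loc[has_death, "birth_date"]).any():
        raise IntegrityError("death_date precedes birth_date for some persons")
    hosp = bundle.hospital
    if len(hosp) and (hosp["discharge_date"] < hosp["admission_date"]).any():
        raise IntegrityError("hospital discharge before admission")
    if len(hosp):
        n_dx = hosp.groupby("stay_id").size()
        if (n_dx > 31).any():
            raise IntegrityError("hospital stay carries more than 31 diagnoses")
    cov = bundle.coverage.sort_values(["person_id", "start_date"])
    if len(cov):
        prev_end = cov.groupby("person_id")["end_date"].shift()
        if (cov["start_date"] <= prev_end).any():
            raise IntegrityError("overlapping drug-coverage intervals")


def _to_dates(series: pd.Series) -> pd.Series:
    out = pd.to_datetime(series, format="ISO8601", errors="raise")
    return pd.Series(
        [ts.date() if not pd.isna(ts) else None for ts in out], index=series.index, dtype=object
    )


def read_claims_bundle(directory: str | Path) -> ClaimsBundle:
    """Read a bundle from ``<directory>/{persons,coverage,hospital,physician,drugs}.csv``.

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for orphan claims or ordering violations.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in _SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s): {missing}")
        df = df[columns].copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = _to_dates(df[col].replace("", pd.NA))
        if name == "physician":
            df["is_ed"] = df["is_ed"].str.lower().isin(("true", "1", "yes"))
        tables[name] = df
    bundle = ClaimsBundle(**tables)
    _validate_bundle(bundle)
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write all bundle tables as CSV under ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        out = df.copy()
        for col in _DATE_COLUMNS[name]:
            out[col] = out[col].map(lambda d: d.isoformat() if isinstance(d, date) else "")
        out.to_csv(directory / f"{name}.csv", index=False)
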