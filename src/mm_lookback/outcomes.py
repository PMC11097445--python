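"""One-year health-outcome indicators built from follow-up claims.

Six binary outcomes are measured over the follow-up year [index date,
follow-up end]:

* ``death`` — all-cause mortality;
* ``hospitalisation`` — at least one hospital admission;
* ``polypharmacy`` — at least 10 distinct medications claimed, by
  common-denomination (active-ingredient) identifier;
* ``ed_frequent`` — at least 3 emergency-department visits, where one visit
  collapses all ED claims occurring on up to 2 consecutive days;
* ``gp_frequent`` — at least 7 general-practitioner visits;
* ``sp_frequent`` — at least 10 specialist visits.

A GP/SP visit is one claim-day per provider type (same-day claims count
once); ED-flagged claims are kept out of the GP/SP counts.  Non-mortality
outcomes are analysed only in persons alive through follow-up end with
continuous public drug-plan coverage over the whole follow-up year
(``eligible_nonmortality``).
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .claims_model import ClaimsBundle, CohortSpec

__all__ = [
    "collapse_ed_visits",
    "count_distinct_medications",
    "build_outcomes",
    "OUTCOME_NAMES",
    "THRESHOLDS",
]

OUTCOME_NAMES = ("death", "hospitalisation", "polypharmacy", "ed_frequent", "gp_frequent", "sp_frequent")
THRESHOLDS = {"polypharmacy": 10, "ed_frequent": 3, "gp_frequent": 7, "sp_frequent": 10}


def collapse_ed_visits(ed_claim_dates: Iterable[date]) -> int:
    """Number of ED visit episodes under greedy 2-consecutive-day grouping.

    A visit begins at the earliest unassigned claim date d and absorbs every
    claim on d and d+1; grouping proceeds left to right.
    """
    days = sorted({d.toordinal() for d in ed_claim_dates})
    visits = 0
    i = 0
    while i < len(days):
        visits += 1
        start = days[i]
        while i < len(days) and days[i] <= start + 1:
            i += 1
    return visits


def count_distinct_medications(denominations: Iterable[str]) -> int:
    """Distinct common-denomination identifiers among follow-up drug claims."""
    return len(set(denominations))


def _covers_followup(intervals: list[tuple[date, date]], start: date, end: date) -> bool:
    """True iff the union of coverage intervals contains every day of [start, end]."""
    need = start
    for s, e in sorted(intervals):
        if s > need:
            return False
        if e >= need:
            need = e + timedelta(days=1)
        if need > end:
            return True
    return need > end


def build_outcomes(bundle: ClaimsBundle, cohort: CohortSpec) -> pd.DataFrame:
    """Outcome indicators, raw counts and eligibility per cohort person.

    Returns a frame indexed by ``person_id`` with the six boolean outcomes,
    the underlying counts (``n_stays``, ``n_medications``, ``ed_visits``,
    ``gp_visits``, ``sp_visits``) and ``eligible_nonmortality``.
    """
    persons = bundle.cohort_persons(cohort)
    idx = pd.Index(persons["person_id"], name="person_id")
    start, end = cohort.index_date, cohort.followup_end

    death = persons.set_index("person_id")["death_date"].map(
        lambda d: isinstance(d, date) and start <= d <= end
    )
    alive_through = persons.set_index("person_id")["death_date"].map(
        lambda d: not isinstance(d, date) or d > end
    )

    def _in_followup(df: pd.DataFrame, col: str) -> pd.DataFrame:
        if df.empty:
            return df
        m = df[col].map(lambda d: start <= d <= end) & df["person_id"].isin(idx)
        return df.loc[m]

    hosp = _in_followup(bundle.hospital, "admission_date")
    n_stays = hosp.groupby("person_id")["stay_id"].nunique().reindex(idx, fill_value=0)

    drugs = _in_followup(bundle.drugs, "claim_date")
    n_meds = (
        drugs.groupby("person_id")["denomination"]
        .agg(count_distinct_medications)
        .reindex(idx, fill_value=0)
        .astype(int)
    )

    phys = _in_followup(bundle.physician, "service_date")
    is_ed = phys["is_ed"].astype(bool) if len(phys) else pd.Series(dtype=bool)
    ed_visits = (
        phys.loc[is_ed].groupby("person_id")["service_date"].agg(collapse_ed_visits).reindex(idx, fill_value=0)
        if len(phys)
        else pd.Series(0, index=idx)
    ).astype(int)

    def _visit_count(provider: str) -> pd.Series:
        if not len(phys):
            return pd.Series(0, index=idx, dtype=int)
        sub = phys.loc[~is_ed & (phys["provider_type"] == provider)]
        return (
            sub.drop_duplicates(["person_id", "service_date"])
            .groupby("person_id")
            .size()
            .reindex(idx, fill_value=0)
            .astype(int)
        )

    gp_visits = _visit_count("GP")
    sp_visits = _visit_count("specialist")

    cov_rows = bundle.coverage[bundle.coverage["person_id"].isin(idx)]
    covered = pd.Series(False, index=idx)
    for pid, grp in cov_rows.groupby("person_id"):
        covered.loc[pid] = _covers_followup(
            list(zip(grp["start_date"], grp["end_date"])), start, end
        )

    out = pd.DataFrame(index=idx)
    out["death"] = death.reindex(idx).astype(bool)
    out["n_stays"] = n_stays
    out["hospitalisation"] = n_stays >= 1
    out["n_medications"] = n_meds
    out["polypharmacy"] = n_meds >= THRESHOLDS["polypharmacy"]
    out["ed_visits"] = ed_visits
    out["ed_frequent"] = ed_visits >= THRESHOLDS["ed_frequent"]
    out["gp_visits"] = gp_visits
    out["gp_frequent"] = gp_visits >= THRESHOLDS["gp_frequent"]
    out["sp_visits"] = sp_visits
    out["sp_frequent"] = sp_visits >= THRESHOLDS["sp_frequent"]
    out["eligible_nonmortality"] = alive_through.reindex(idx).astype(bool) & covered
    return out
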