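"""Claims-based chronic-condition ascertainment under varying lookback periods.

A condition is considered present (the classic claims case definition) if,
within the retrospective window, either

(a) at least one hospital discharge diagnosis carries one of the condition's
    codes, in any position (admission / primary / secondary), or
(b) at least ``min_physician_claims`` physician-claim diagnoses (inpatient or
    outpatient, ED included) occur on distinct service days whose first-to-last
    span is at least ``min_spacing_days`` and at most ``max_pair_span_days``
    days (defaults 30 and 730: "two claims at least 30 days apart within two
    years").

Because retrospective windows of increasing length are nested and both a
qualifying hospital claim and a qualifying claim set remain inside every
longer window, ascertainment is monotone in the window length.  The result
is therefore stored compactly as a *minimal lookback* per person × condition:
the smallest window length L (in years) at which the condition is
ascertained; a pair absent from the table was never ascertained within the
maximum lookback.  Per-condition overrides can cap the effective window
(e.g. a 5-year cap for remitting mental disorders), in which case windows
longer than the cap are truncated to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    AscertainmentRule,
    ClaimsBundle,
    CohortSpec,
    Condition,
    DiseaseList,
    normalize_code,
)
from .disease_lists import hypertension_condition

__all__ = ["is_case", "ascertain", "AscertainmentMatrix", "apply_sensitivity_profile"]

logger = logging.getLogger(__name__)


def is_case(
    hospital_dx_dates: Iterable[date],
    physician_dx_dates: Iterable[date],
    rule: AscertainmentRule = AscertainmentRule(),
) -> bool:
    """Evaluate the case definition on window-internal claim dates.

    ``hospital_dx_dates`` / ``physician_dx_dates`` are the dates of claims
    bearing the condition's code that fall inside the (already resolved)
    lookback window.  Physician claims count once per distinct service day.
    """
    if any(True for _ in hospital_dx_dates):
        return True
    days = sorted({d.toordinal() for d in physician_dx_dates})
    m = rule.min_physician_claims
    for i, d1 in enumerate(days):
        for j in range(i + m - 1, len(days)):
            span = days[j] - d1
            if span > rule.max_pair_span_days:
                break
            if span >= rule.min_spacing_days:
                return True
    return False


@dataclass
class AscertainmentMatrix:
    """Minimal lookback (years) per ascertained person × condition pair.

    ``table`` has columns ``person_id, condition_id, minimal_lp`` and one row
    per ascertained pair; persons/conditions absent from it were never
    ascertained within ``max_lookback_years``.  ``person_ids`` is the full
    cohort (the denominator for prevalence).
    """

    table: pd.DataFrame
    person_ids: pd.Index
    condition_ids: tuple[str, ...]
    max_lookback_years: int

    def __post_init__(self) -> None:
        self.person_ids = pd.Index(self.person_ids, name="person_id")
        if len(self.table):
            bad = ~self.table["minimal_lp"].between(1, self.max_lookback_years)
            if bad.any():
                raise ValueError("minimal_lp outside 1..max_lookback_years")

    def counts_by_lp(self) -> pd.DataFrame:
        """Condition count per person (rows) at each LP 1..max (columns)."""
        n, m = len(self.person_ids), self.max_lookback_years
        counts = np.zeros((n, m), dtype=np.int32)
        if len(self.table):
            p = self.person_ids.get_indexer(self.table["person_id"])
            lp = self.table["minimal_lp"].to_numpy(dtype=int)
            np.add.at(counts, (p, lp - 1), 1)
            counts = np.cumsum(counts, axis=1)
        return pd.DataFrame(counts, index=self.person_ids, columns=range(1, m + 1))

    def minimal_lp(self, person_id: str, condition_id: str) -> int | None:
        rows = self.table[
            (self.table["person_id"] == person_id) & (self.table["condition_id"] == condition_id)
        ]
        return None if rows.empty else int(rows["minimal_lp"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        person_ids: Sequence[str],
        condition_ids: Sequence[str],
        max_lookback_years: int = 20,
    ) -> "AscertainmentMatrix":
        table = pd.read_csv(path, dtype={"person_id": str, "condition_id": str, "minimal_lp": int})
        return cls(table, pd.Index(person_ids), tuple(condition_ids), max_lookback_years)


def _match_mask(codes: np.ndarray, is_icd10: np.ndarray, condition: Condition) -> np.ndarray:
    mask = np.zeros(len(codes), dtype=bool)
    for patterns, era_mask in ((condition.icd9_patterns, ~is_icd10), (condition.icd10_patterns, is_icd10)):
        if era_mask.any():
            hit = np.zeros(len(codes), dtype=bool)
            for pat in patterns:
                hit |= np.char.startswith(codes, pat)
            mask |= hit & era_mask
    return mask


def _lp_of(day_ordinals: np.ndarray, bounds_asc: np.ndarray, max_lp: int) -> np.ndarray:
    """Minimal window length containing each (pre-index) date; 0 = never."""
    pos = np.searchsorted(bounds_asc, day_ordinals, side="right")
    return np.where(pos == 0, 0, max_lp - pos + 1)


def _qualifying_first_dates(group_idx: np.ndarray, days: np.ndarray, rule: AscertainmentRule):
    """For sorted (group, day) arrays of distinct service days, flag days that
    can start a qualifying claim set under ``rule``."""
    if len(days) == 0:
        return np.zeros(0, dtype=bool)
    span = int(rule.max_pair_span_days)
    big = int(days.max() - days.min()) + span + 2
    keys = group_idx.astype(np.int64) * big + (days - days.min())
    hi = np.searchsorted(keys, keys + span, side="right") - 1
    m = rule.min_physician_claims
    return (hi - np.arange(len(days)) >= m - 1) & (days[hi] - days >= rule.min_spacing_days)


def ascertain(
    bundle: ClaimsBundle,
    disease_list: DiseaseList,
    cohort: CohortSpec,
    use_disease_specific: bool = False,
) -> AscertainmentMatrix:
    """Compute the minimal-lookback matrix for a cohort and disease list.

    Per-condition overrides are applied; a ``max_lookback_years`` cap of C
    makes every window of length L behave as the window of length
    ``min(L, C)``, so claims older than the cap never qualify.
    """
    persons = bundle.cohort_persons(cohort)
    person_ids = pd.Index(persons["person_id"], name="person_id")
    max_lp = cohort.max_lookback_years
    bounds_desc = np.array([b.toordinal() for b in cohort.lp_boundaries()], dtype=np.int64)
    bounds_asc = bounds_desc[::-1].copy()
    index_ord = cohort.index_date.toordinal()
    hosp_switch = cohort.hospital_icd10_from.toordinal()
    phys_switch = cohort.physician_icd10_from.toordinal()

    def _prep(df: pd.DataFrame, date_col: str, switch: int):
        if df.empty:
            z = np.zeros(0, dtype=np.int64)
            return np.zeros(0, dtype="U8"), np.zeros(0, dtype=bool), z, np.zeros(0, dtype=np.int64)
        keep = df["person_id"].isin(person_ids).to_numpy()
        sub = df.loc[keep]
        days = np.array([d.toordinal() for d in sub[date_col]], dtype=np.int64)
        in_window = (days < index_ord) & (days >= bounds_desc[-1])
        sub = sub.loc[in_window]
        days = days[in_window]
        codes = np.array([normalize_code(c) for c in sub["code"]], dtype="U8")
        pidx = person_ids.get_indexer(sub["person_id"]).astype(np.int64)
        return codes, days >= switch, days, pidx

    h_codes, h_is10, h_days, h_pidx = _prep(bundle.hospital, "admission_date", hosp_switch)
    p_codes, p_is10, p_days, p_pidx = _prep(bundle.physician, "service_date", phys_switch)

    rows: list[pd.DataFrame] = []
    n_persons = len(person_ids)
    for cond in disease_list:
        rule = cond.rule(use_disease_specific)
        cap = min(rule.max_lookback_years or max_lp, max_lp)
        cap_bound = bounds_desc[cap - 1]
        best = np.zeros(n_persons, dtype=np.int64)  # latest qualifying anchor day + 1 (0 = none)

        hm = _match_mask(h_codes, h_is10, cond) & (h_days >= cap_bound)
        if hm.any():
            np.maximum.at(best, h_pidx[hm], h_days[hm] + 1)

        pm = _match_mask(p_codes, p_is10, cond) & (p_days >= cap_bound)
        if pm.any():
            grp, dys = p_pidx[pm], p_days[pm]
            order = np.lexsort((dys, grp))
            grp, dys = grp[order], dys[order]
            distinct = np.ones(len(dys), dtype=bool)
            distinct[1:] = (grp[1:] != grp[:-1]) | (dys[1:] != dys[:-1])
            grp, dys = grp[distinct], dys[distinct]
            ok = _qualifying_first_dates(grp, dys, rule)
            if ok.any():
                np.maximum.at(best, grp[ok], dys[ok] + 1)

        found = best > 0
        if not found.any():
            logger.debug("condition %s: no ascertained persons", cond.condition_id)
            continue
        lp = _lp_of(best[found] - 1, bounds_asc, max_lp)
        assert (lp >= 1).all() and (lp <= cap).all()
        rows.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[found],
                    "condition_id": cond.condition_id,
                    "minimal_lp": lp.astype(np.int16),
                }
            )
        )

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame({"person_id": pd.Series(dtype=str), "condition_id": pd.Series(dtype=str), "minimal_lp": pd.Series(dtype=np.int16)})
    )
    return AscertainmentMatrix(table, person_ids, tuple(c.condition_id for c in disease_list), max_lp)


def apply_sensitivity_profile(
    disease_list: DiseaseList,
    mental_cap_5y: bool = False,
    disease_specific: bool = False,
    add_hypertension: bool = False,
    hypertension: Condition | None = None,
) -> DiseaseList:
    """Return a modified copy of a disease list for a sensitivity analysis.

    * ``mental_cap_5y`` — cap the lookback at 5 years for every condition
      flagged ``mental`` (remitting/relapsing course).
    * ``disease_specific`` — fold each condition's ``disease_specific``
      override block into its effective overrides (core list L20 only).
    * ``add_hypertension`` — append the hypertension group to the core list
      L20 (making 21 conditions).
    """
    if disease_specific and disease_list.name != "L20":
        raise ValueError("disease-specific case definitions are available only for the core list L20")
    if add_hypertension and disease_list.name != "L20":
        raise ValueError("the hypertension variant applies only to the core list L20")

    conditions = []
    for cond in disease_list:
        overrides = dict(cond.overrides or {})
        if disease_specific and cond.disease_specific:
            overrides.update(cond.disease_specific)
        if mental_cap_5y and cond.mental:
            cap = overrides.get("max_lookback_years")
            overrides["max_lookback_years"] = 5 if cap is None else min(cap, 5)
        conditions.append(replace(cond, overrides=overrides or None))
    if add_hypertension:
        htn = hypertension if hypertension is not None else hypertension_condition()
        if any(c.condition_id == htn.condition_id for c in conditions):
            raise ValueError("hypertension already present in the list")
        conditions.append(htn)
    return disease_list.replace_conditions(conditions)
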