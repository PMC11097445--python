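"""Independent brute-force oracles used to validate the vectorised
implementations.  These deliberately re-derive everything from first
principles (explicit window enumeration, pairwise loops) and share no code
with the package internals."""

from __future__ import annotations

from datetime import date
from itertools import combinations

from mm_lookback.claims_model import ClaimsBundle, CohortSpec, Condition, DiseaseList, years_before


def oracle_case(hospital_days: list[int], physician_days: list[int], rule) -> bool:
    """Case definition by exhaustive pair enumeration over distinct days."""
    if hospital_days:
        return True
    days = sorted(set(physician_days))
    for i, j in combinations(range(len(days)), 2):
        if j - i >= rule.min_physician_claims - 1:
            span = days[j] - days[i]
            if rule.min_spacing_days <= span <= rule.max_pair_span_days:
                return True
    return False


def _norm(code: str) -> str:
    return code.strip().upper().replace(".", "")


def _matches(code: str, cond: Condition, d: date, switch: date) -> bool:
    pats = cond.icd10_patterns if d >= switch else cond.icd9_patterns
    return any(_norm(code).startswith(p) for p in pats)


def oracle_minimal_lp(
    bundle: ClaimsBundle, disease_list: DiseaseList, cohort: CohortSpec, use_disease_specific: bool = False
) -> dict[tuple[str, str], int]:
    """Minimal lookback per (person, condition) by evaluating every explicit
    window L = 1..max independently."""
    out: dict[tuple[str, str], int] = {}
    persons = bundle.cohort_persons(cohort)["person_id"]
    index = cohort.index_date
    for cond in disease_list:
        rule = cond.rule(use_disease_specific)
        cap = rule.max_lookback_years or cohort.max_lookback_years
        for pid in persons:
            for lp in range(1, cohort.max_lookback_years + 1):
                start = years_before(index, min(lp, cap))
                hosp = [
                    r.admission_date.toordinal()
                    for r in bundle.hospital.itertuples()
                    if r.person_id == pid
                    and start <= r.admission_date < index
                    and _matches(r.code, cond, r.admission_date, cohort.hospital_icd10_from)
                ]
                phys = [
                    r.service_date.toordinal()
                    for r in bundle.physician.itertuples()
                    if r.person_id == pid
                    and start <= r.service_date < index
                    and _matches(r.code, cond, r.service_date, cohort.physician_icd10_from)
                ]
                if oracle_case(hosp, phys, rule):
                    out[(pid, cond.condition_id)] = lp
                    break
    return out


def oracle_ed_visit_count(days: list[int]) -> int:
    """Minimal-interval grouping: repeatedly remove the earliest day and its
    successor day, counting groups."""
    remaining = sorted(set(days))
    count = 0
    while remaining:
        start = remaining[0]
        remaining = [d for d in remaining if d > start + 1]
        count += 1
    return count


def oracle_c_statistic(p, y) -> float:
    """O(n^2) concordance over all event/non-event pairs, ties as 1/2."""
    pos = [pi for pi, yi in zip(p, y) if yi]
    neg = [pi for pi, yi in zip(p, y) if not yi]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
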