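"""Synthetic administrative-claims generator.

Emulates the statistical structure a lookback-period analysis assumes: an
over-65 cohort at a fixed index date with age/sex/deprivation covariates;
latent chronic-condition onsets from an age-dependent exponential waiting
time (conditions are permanent once onset occurs, except groups flagged
``remitting`` which may carry an offset date); stochastic per-year emission
of coded hospital and physician claims across more than twenty retrospective
years, spanning the ICD-9 → ICD-10 coding-era switches; public drug-plan
coverage intervals with occasional gaps; and one-year outcomes drawn from a
logit-linear model on the true disease count and covariates, realised as
follow-up claims (death record, hospital stays, ED/GP/specialist visits,
pharmacy claims).

The generator's purpose is to make every downstream stage testable without
access to a claims registry; it is not calibrated to reproduce any real
population's prevalences or model performance.  A ``TruthTable`` of latent
onsets and true outcome probabilities is returned alongside the bundle so
that recovery tests need no re-simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .claims_model import (
    HOSPITAL_ICD10_FROM,
    PHYSICIAN_ICD10_FROM,
    ClaimsBundle,
    CohortSpec,
    DiseaseList,
    empty_bundle,
    years_before,
)
from .disease_lists import load_bundled_list
from .outcomes import OUTCOME_NAMES

__all__ = [
    "ConditionSim",
    "OutcomeModel",
    "SimulationConfig",
    "TruthTable",
    "generate_bundle",
    "default_config",
    "closed_form_scenario_config",
    "steep_gradient_config",
    "closed_form_ascertainment",
]

AGE_BANDS = ((66, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 99))
AGE_BAND_LABELS = ("66-69", "70-74", "75-79", "80-84", "85-89", "90+")
# Age-band mix of a typical over-65 registry cohort (youngest bands largest).
DEFAULT_AGE_WEIGHTS = (0.258, 0.279, 0.196, 0.129, 0.086, 0.052)

_NEVER = 10**7  # ordinal sentinel for "no offset"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def closed_form_ascertainment(h: float, lookback_years: int) -> float:
    """Analytic ascertainment probability 1 − (1 − h)^L for a condition
    present throughout the window, hospital-only emission (one Bernoulli
    trial per year) and a single-claim rule."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    if lookback_years < 1:
        raise ValueError("lookback must be >= 1")
    return 1.0 - (1.0 - h) ** lookback_years


@dataclass(frozen=True)
class ConditionSim:
    """Per-condition generator parameters.

    ``baseline_hazard`` is the onset hazard per year at age 65;
    ``age_slope`` its log-linear age trend.  Active conditions emit, per
    retrospective year, a hospital stay with probability ``hospital_rate``
    and Poisson(``physician_rate``) physician claims.
    """

    condition_id: str
    icd9: str
    icd10: str
    baseline_hazard: float
    age_slope: float = 0.04
    hospital_rate: float = 0.05
    physician_rate: float = 0.5
    remitting: bool = False
    remit_prob: float = 0.3
    remit_mean_years: float = 6.0


@dataclass(frozen=True)
class OutcomeModel:
    """Logit-linear true-risk model for one outcome.

    logit p = intercept + beta_count·count + beta_mm·1{count ≥ mm_threshold}
              + age-band effect + beta_male·male + beta_dep·(quintile − 1)
    with the missing-deprivation category scored at the middle quintile.
    """

    intercept: float
    beta_count: float = 0.0
    beta_mm: float = 0.0
    mm_threshold: int | None = None
    age_band_betas: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0, 1.4, 1.8)
    beta_male: float = 0.2
    beta_dep: float = 0.05


def _default_outcome_models() -> dict[str, OutcomeModel]:
    return {
        "death": OutcomeModel(intercept=-6.25, beta_count=0.30, beta_male=0.3),
        "hospitalisation": OutcomeModel(intercept=-4.15, beta_count=0.25, age_band_betas=(0, 0.15, 0.3, 0.45, 0.6, 0.75)),
        "polypharmacy": OutcomeModel(intercept=-3.00, beta_count=0.35, age_band_betas=(0, 0.1, 0.15, 0.2, 0.2, 0.2)),
        "ed_frequent": OutcomeModel(intercept=-5.05, beta_count=0.25, age_band_betas=(0, 0.1, 0.2, 0.35, 0.5, 0.6)),
        "gp_frequent": OutcomeModel(intercept=-3.90, beta_count=0.20, age_band_betas=(0, 0.05, 0.1, 0.1, 0.05, 0.0)),
        "sp_frequent": OutcomeModel(intercept=-3.65, beta_count=0.25, age_band_betas=(0, 0.0, 0.0, -0.1, -0.2, -0.3)),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; a fixed seed gives byte-identical output."""

    n_persons: int
    seed: int = 0
    index_date: date = date(2019, 4, 1)
    followup_end: date = date(2020, 3, 31)
    max_lookback_years: int = 20
    age_band_weights: tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    sex_female_prob: float = 0.552
    deprivation_missing_rate: float = 0.118
    conditions: tuple[ConditionSim, ...] = ()
    outcome_models: Mapping[str, OutcomeModel] = field(default_factory=_default_outcome_models)
    # follow-up utilisation, conditional on the drawn outcome indicator
    hosp_extra_stays: float = 0.6
    ed_base_mean: float = 0.4
    ed_frequent_extra: float = 1.5
    ed_two_day_prob: float = 0.35
    gp_base_mean: float = 2.5
    gp_frequent_extra: float = 2.0
    sp_base_mean: float = 3.0
    sp_frequent_extra: float = 3.0
    meds_base_mean: float = 5.0
    meds_poly_extra: float = 3.0
    claims_per_denomination: float = 1.0  # extra Poisson claims beyond the first
    coverage_gap_rate: float = 0.10
    background_rate: float = 0.3  # non-chronic history claims per person-year
    hospital_icd10_from: date = HOSPITAL_ICD10_FROM
    physician_icd10_from: date = PHYSICIAN_ICD10_FROM

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        if self.followup_end <= self.index_date:
            raise ValueError("followup_end must be after index_date")
        if self.max_lookback_years < 1:
            raise ValueError("max_lookback_years must be >= 1")
        w = np.asarray(self.age_band_weights, dtype=float)
        if len(w) != len(AGE_BANDS) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("age_band_weights must be 6 non-negative weights")
        for p_name in ("sex_female_prob", "deprivation_missing_rate", "coverage_gap_rate", "ed_two_day_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} must lie in [0, 1]")
        for r_name in (
            "hosp_extra_stays", "ed_base_mean", "ed_frequent_extra", "gp_base_mean",
            "gp_frequent_extra", "sp_base_mean", "sp_frequent_extra", "meds_base_mean",
            "meds_poly_extra", "claims_per_denomination", "background_rate",
        ):
            if getattr(self, r_name) < 0:
                raise ValueError(f"{r_name} must be >= 0")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate condition_id in simulation conditions")
        for c in self.conditions:
            if c.baseline_hazard < 0 or c.hospital_rate < 0 or c.physician_rate < 0:
                raise ValueError(f"negative rate for condition {c.condition_id!r}")
            if not 0.0 <= c.hospital_rate <= 1.0:
                raise ValueError(f"hospital_rate for {c.condition_id!r} must lie in [0, 1]")
        missing = set(OUTCOME_NAMES) - set(self.outcome_models)
        if missing:
            raise ValueError(f"outcome_models missing outcomes: {sorted(missing)}")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            index_date=self.index_date,
            followup_end=self.followup_end,
            max_lookback_years=self.max_lookback_years,
            hospital_icd10_from=self.hospital_icd10_from,
            physician_icd10_from=self.physician_icd10_from,
        )


@dataclass
class TruthTable:
    """Latent generator state: condition onsets and true outcome risks.

    ``onsets``: person_id, condition_id, onset_date, offset_date (empty when
    the condition never remits).  ``outcomes``: per person the true condition
    count at index plus, for each outcome, its true probability ``p_<name>``
    and the drawn indicator ``y_<name>``.
    """

    onsets: pd.DataFrame
    outcomes: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        on = self.onsets.copy()
        for col in ("onset_date", "offset_date"):
            on[col] = on[col].map(lambda d: d.isoformat() if isinstance(d, date) else "")
        on.to_csv(directory / "truth_onsets.csv", index=False)
        self.outcomes.to_csv(directory / "truth_outcomes.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        on = pd.read_csv(directory / "truth_onsets.csv", dtype={"person_id": str}, keep_default_na=False)
        for col in ("onset_date", "offset_date"):
            on[col] = on[col].map(lambda s: date.fromisoformat(s) if s else None)
        out = pd.read_csv(directory / "truth_outcomes.csv", dtype={"person_id": str})
        return cls(on, out)


def default_condition_sims(disease_list: DiseaseList) -> tuple[ConditionSim, ...]:
    """Deterministic spread of onset and emission rates across a list.

    Hazards are log-spaced (lifetime prevalences roughly 1–30%) and emission
    rates span plausible utilisation ranges; fixed stride permutations
    decorrelate the three rates from list order and from each other.
    """
    n = len(disease_list)
    sims = []
    for i, cond in enumerate(disease_list):
        t_h = ((i * 17) % n) / max(n - 1, 1)
        t_hosp = ((i * 11) % n) / max(n - 1, 1)
        t_phys = ((i * 7) % n) / max(n - 1, 1)
        sims.append(
            ConditionSim(
                condition_id=cond.condition_id,
                icd9=cond.icd9_patterns[0],
                icd10=cond.icd10_patterns[0],
                baseline_hazard=3e-4 * 40.0 ** t_h,
                hospital_rate=0.02 + 0.10 * t_hosp,
                physician_rate=0.2 + 0.6 * t_phys,
                remitting=cond.remitting,
            )
        )
    return tuple(sims)


def default_config(n_persons: int = 5000, seed: int = 0) -> SimulationConfig:
    """The default study scenario over the bundled 60-condition universe."""
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        conditions=default_condition_sims(load_bundled_list("L60")),
    )


def closed_form_scenario_config(
    n_persons: int, n_conditions: int = 10, h: float = 0.2, seed: int = 0, max_lookback_years: int = 20
) -> SimulationConfig:
    """Hospital-only emission with every condition present from early life.

    Under this scenario the empirical ascertainment prevalence at lookback L
    equals :func:`closed_form_ascertainment`\\ (h, L) up to Monte-Carlo error,
    giving an analytic oracle for the whole ascertainment pipeline.
    """
    conditions = tuple(
        ConditionSim(
            condition_id=f"cf{i:02d}",
            icd9=f"{900 + i}",
            icd10=f"X{i:02d}",
            baseline_hazard=1e6,  # onset effectively at the start of adult life
            age_slope=0.0,
            hospital_rate=h,
            physician_rate=0.0,
        )
        for i in range(n_conditions)
    )
    silent = {name: OutcomeModel(intercept=-30.0) for name in OUTCOME_NAMES}
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        max_lookback_years=max_lookback_years,
        conditions=conditions,
        outcome_models=silent,
        ed_base_mean=0.0,
        gp_base_mean=0.0,
        sp_base_mean=0.0,
        meds_base_mean=0.0,
        coverage_gap_rate=0.0,
        background_rate=0.0,
    )


def steep_gradient_config(n_persons: int = 5000, seed: int = 0) -> SimulationConfig:
    """Default scenario with a steep disease-count risk gradient on mortality,
    built to make higher-count multimorbidity definitions the better
    discriminators."""
    cfg = default_config(n_persons=n_persons, seed=seed)
    models = dict(cfg.outcome_models)
    models["death"] = OutcomeModel(intercept=-7.8, beta_count=0.8, beta_male=0.3)
    return dataclasses.replace(cfg, outcome_models=models)


# ---------------------------------------------------------------------------
# generation


def _dates_from_ordinals(ordinals: np.ndarray) -> list[date]:
    return [date.fromordinal(int(o)) for o in ordinals]


def generate_bundle(config: SimulationConfig) -> tuple[ClaimsBundle, TruthTable]:
    """Simulate a claims bundle and its truth table from ``config``."""
    config.validate()
    n = config.n_persons
    if n == 0:
        empty_truth = TruthTable(
            onsets=pd.DataFrame(columns=["person_id", "condition_id", "onset_date", "offset_date"]),
            outcomes=pd.DataFrame(
                columns=["person_id", "true_count"]
                + [f"p_{o}" for o in OUTCOME_NAMES]
                + [f"y_{o}" for o in OUTCOME_NAMES]
            ),
        )
        return empty_bundle(), empty_truth

    rng = np.random.default_rng(config.seed)
    index_ord = config.index_date.toordinal()
    end_ord = config.followup_end.toordinal()
    hosp_switch = config.hospital_icd10_from.toordinal()
    phys_switch = config.physician_icd10_from.toordinal()
    person_ids = np.array([f"P{i:07d}" for i in range(n)])

    # --- persons -----------------------------------------------------------
    weights = np.asarray(config.age_band_weights, dtype=float)
    weights = weights / weights.sum()
    band = rng.choice(len(AGE_BANDS), size=n, p=weights)
    lo = np.array([b[0] for b in AGE_BANDS])
    hi = np.array([b[1] for b in AGE_BANDS])
    age = lo[band] + rng.integers(0, hi[band] - lo[band] + 1)
    anniv = np.array([years_before(config.index_date, a).toordinal() for a in range(age.min(), age.max() + 1)])
    birth_ord = anniv[age - age.min()] - rng.integers(0, 365, size=n)
    male = rng.random(n) >= config.sex_female_prob
    dep_missing = rng.random(n) < config.deprivation_missing_rate
    mat_q = rng.integers(1, 6, size=n)
    soc_q = rng.integers(1, 6, size=n)

    # --- latent onsets -----------------------------------------------------
    ages_grid = np.arange(20, 111)
    onset_map: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    onset_rows = []
    true_count = np.zeros(n, dtype=int)
    for cond in config.conditions:
        hazard = cond.baseline_hazard * np.exp(cond.age_slope * (ages_grid - 65.0))
        cum = np.cumsum(hazard)
        e = rng.exponential(1.0, size=n)
        onset_age = 20 + np.searchsorted(cum, e)
        has = onset_age <= age
        p_idx = np.nonzero(has)[0]
        if len(p_idx) == 0:
            onset_map[cond.condition_id] = (p_idx, np.zeros(0, np.int64), np.zeros(0, np.int64))
            continue
        onset_ord = (
            birth_ord[p_idx]
            + (365.25 * onset_age[p_idx]).astype(np.int64)
            + rng.integers(0, 365, size=len(p_idx))
        )
        onset_ord = np.clip(onset_ord, birth_ord[p_idx] + 1, index_ord - 1)
        offset_ord = np.full(len(p_idx), _NEVER, dtype=np.int64)
        if cond.remitting and cond.remit_prob > 0:
            remits = rng.random(len(p_idx)) < cond.remit_prob
            durations = (rng.exponential(cond.remit_mean_years, size=int(remits.sum())) * 365.0).astype(np.int64) + 30
            offset_ord[remits] = onset_ord[remits] + durations
        onset_map[cond.condition_id] = (p_idx, onset_ord, offset_ord)
        active_at_index = offset_ord > index_ord
        true_count[p_idx[active_at_index]] += 1
        onset_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[p_idx],
                    "condition_id": cond.condition_id,
                    "onset_date": _dates_from_ordinals(onset_ord),
                    "offset_date": [
                        date.fromordinal(int(o)) if o < _NEVER else None for o in offset_ord
                    ],
                }
            )
        )

    # --- retrospective claim emission -------------------------------------
    year_bounds = [index_ord] + [
        years_before(config.index_date, y).toordinal() for y in range(1, config.max_lookback_years + 1)
    ]
    h_person: list[np.ndarray] = []
    h_adm: list[np.ndarray] = []
    h_los: list[np.ndarray] = []
    h_code: list[np.ndarray] = []
    p_person: list[np.ndarray] = []
    p_svc: list[np.ndarray] = []
    p_code: list[np.ndarray] = []

    def _codes(prefix9: str, prefix10: str, day_ords: np.ndarray, switch: int) -> np.ndarray:
        suffix = rng.integers(0, 10, size=len(day_ords)).astype(str)
        is10 = day_ords >= switch
        return np.where(is10, np.char.add(prefix10, suffix), np.char.add(prefix9, suffix))

    for cond in config.conditions:
        p_idx, onset_ord, offset_ord = onset_map[cond.condition_id]
        if len(p_idx) == 0:
            continue
        for y in range(1, config.max_lookback_years + 1):
            ws, we = year_bounds[y], year_bounds[y - 1]
            active = (onset_ord < we) & (offset_ord > ws)
            if not active.any():
                continue
            ap = p_idx[active]
            alo = np.maximum(onset_ord[active], ws)
            ahi = np.minimum(offset_ord[active], we)
            span = ahi - alo
            if cond.hospital_rate > 0:
                hit = rng.random(len(ap)) < cond.hospital_rate
                if hit.any():
                    adm = alo[hit] + (rng.random(int(hit.sum())) * span[hit]).astype(np.int64)
                    h_person.append(ap[hit])
                    h_adm.append(adm)
                    h_los.append(rng.integers(1, 15, size=len(adm)))
                    h_code.append(_codes(cond.icd9, cond.icd10, adm, hosp_switch))
            if cond.physician_rate > 0:
                k = rng.poisson(cond.physician_rate, size=len(ap))
                tot = int(k.sum())
                if tot:
                    rep = np.repeat(np.arange(len(ap)), k)
                    svc = alo[rep] + (rng.random(tot) * span[rep]).astype(np.int64)
                    p_person.append(ap[rep])
                    p_svc.append(svc)
                    p_code.append(_codes(cond.icd9, cond.icd10, svc, phys_switch))

    # background (non-chronic) history claims
    bg_person: list[np.ndarray] = []
    bg_svc: list[np.ndarray] = []
    if config.background_rate > 0:
        for y in range(1, config.max_lookback_years + 1):
            ws, we = year_bounds[y], year_bounds[y - 1]
            k = rng.poisson(config.background_rate, size=n)
            tot = int(k.sum())
            if tot:
                rep = np.repeat(np.arange(n), k)
                bg_person.append(rep)
                bg_svc.append(ws + (rng.random(tot) * (we - ws)).astype(np.int64))

    # --- outcomes ----------------------------------------------------------
    dep_score = np.where(dep_missing, 2.0, mat_q - 1.0)
    p_true: dict[str, np.ndarray] = {}
    y_drawn: dict[str, np.ndarray] = {}
    for name in OUTCOME_NAMES:
        m = config.outcome_models[name]
        eta = (
            m.intercept
            + m.beta_count * true_count
            + np.asarray(m.age_band_betas)[band]
            + m.beta_male * male
            + m.beta_dep * dep_score
        )
        if m.mm_threshold is not None:
            eta = eta + m.beta_mm * (true_count >= m.mm_threshold)
        p_true[name] = _sigmoid(eta)
        y_drawn[name] = rng.random(n) < p_true[name]

    death_ord = np.full(n, 0, dtype=np.int64)
    died = y_drawn["death"]
    death_ord[died] = index_ord + rng.integers(1, end_ord - index_ord + 1, size=int(died.sum()))
    avail_hi = np.where(died, death_ord, end_ord + 1)  # exclusive upper bound for follow-up claims

    # --- follow-up utilisation --------------------------------------------
    fu_h_person: list[int] = []
    fu_h_adm: list[int] = []
    fu_p_person: list[int] = []
    fu_p_svc: list[int] = []
    fu_p_is_ed: list[bool] = []
    fu_p_provider: list[str] = []
    d_person: list[int] = []
    d_day: list[int] = []
    d_denom: list[str] = []

    n_stays = np.where(y_drawn["hospitalisation"], 1 + rng.poisson(config.hosp_extra_stays, n), 0)
    ed_counts = np.where(
        y_drawn["ed_frequent"],
        3 + rng.poisson(config.ed_frequent_extra, n),
        np.minimum(rng.poisson(config.ed_base_mean, n), 2),
    )
    gp_counts = np.where(
        y_drawn["gp_frequent"],
        7 + rng.poisson(config.gp_frequent_extra, n),
        np.minimum(rng.poisson(config.gp_base_mean, n), 6),
    )
    sp_counts = np.where(
        y_drawn["sp_frequent"],
        10 + rng.poisson(config.sp_frequent_extra, n),
        np.minimum(rng.poisson(config.sp_base_mean, n), 9),
    )
    med_counts = np.where(
        y_drawn["polypharmacy"],
        10 + rng.poisson(config.meds_poly_extra, n),
        np.minimum(rng.poisson(config.meds_base_mean, n), 9),
    )

    for i in range(n):
        lo_d, hi_d = index_ord, int(avail_hi[i])
        n_days = hi_d - lo_d
        if n_days <= 0:
            continue
        if n_stays[i]:
            for adm in lo_d + rng.integers(0, n_days, size=int(n_stays[i])):
                fu_h_person.append(i)
                fu_h_adm.append(int(adm))
        if ed_counts[i]:
            grid = np.arange(lo_d, hi_d, 3)
            starts = rng.choice(grid, size=min(int(ed_counts[i]), len(grid)), replace=False)
            for s in starts:
                fu_p_person.append(i)
                fu_p_svc.append(int(s))
                fu_p_is_ed.append(True)
                fu_p_provider.append("GP")
                if rng.random() < config.ed_two_day_prob and s + 1 < hi_d:
                    fu_p_person.append(i)
                    fu_p_svc.append(int(s) + 1)
                    fu_p_is_ed.append(True)
                    fu_p_provider.append("GP")
        for count, provider in ((gp_counts[i], "GP"), (sp_counts[i], "specialist")):
            if count:
                days = rng.choice(n_days, size=min(int(count), n_days), replace=False) + lo_d
                for s in days:
                    fu_p_person.append(i)
                    fu_p_svc.append(int(s))
                    fu_p_is_ed.append(False)
                    fu_p_provider.append(provider)
        if med_counts[i]:
            for j in range(int(med_counts[i])):
                n_claims = 1 + rng.poisson(config.claims_per_denomination)
                for day in lo_d + rng.integers(0, n_days, size=n_claims):
                    d_person.append(i)
                    d_day.append(int(day))
                    d_denom.append(f"DEN{j:04d}")

    # --- coverage ----------------------------------------------------------
    cov_start = years_before(config.index_date, config.max_lookback_years + 1).toordinal()
    cov_end = end_ord + 60
    gap = rng.random(n) < config.coverage_gap_rate
    gap_start = index_ord + 10 + rng.integers(0, max(end_ord - index_ord - 170, 1), size=n)
    gap_len = rng.integers(30, 121, size=n)
    cov_person: list[int] = []
    cov_s: list[int] = []
    cov_e: list[int] = []
    for i in range(n):
        if gap[i]:
            cov_person += [i, i]
            cov_s += [cov_start, int(gap_start[i] + gap_len[i])]
            cov_e += [int(gap_start[i] - 1), cov_end]
        else:
            cov_person.append(i)
            cov_s.append(cov_start)
            cov_e.append(cov_end)

    # --- assemble ----------------------------------------------------------
    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "birth_date": _dates_from_ordinals(birth_ord),
            "sex": np.where(male, "M", "F"),
            "material_dep": np.where(dep_missing, "missing", np.char.add("Q", mat_q.astype(str))),
            "social_dep": np.where(dep_missing, "missing", np.char.add("Q", soc_q.astype(str))),
            "death_date": [date.fromordinal(int(o)) if o else None for o in death_ord],
        }
    )

    hp = np.concatenate(h_person) if h_person else np.zeros(0, dtype=int)
    ha = np.concatenate(h_adm) if h_adm else np.zeros(0, dtype=np.int64)
    hl = np.concatenate(h_los) if h_los else np.zeros(0, dtype=np.int64)
    hc = np.concatenate(h_code) if h_code else np.zeros(0, dtype="U8")
    fu_hp = np.asarray(fu_h_person, dtype=int)
    fu_ha = np.asarray(fu_h_adm, dtype=np.int64)
    all_hp = np.concatenate([hp, fu_hp])
    all_ha = np.concatenate([ha, fu_ha])
    all_hl = np.concatenate([hl, rng.integers(1, 15, size=len(fu_hp))])
    fu_codes = (
        _codes("V58", "Z51", fu_ha, hosp_switch) if len(fu_hp) else np.zeros(0, dtype="U8")
    )
    all_hc = np.concatenate([hc, fu_codes])
    positions = rng.choice(["admission", "primary", "secondary"], size=len(all_hp), p=[0.15, 0.45, 0.40])
    hospital = pd.DataFrame(
        {
            "person_id": person_ids[all_hp],
            "stay_id": [f"S{j:07d}" for j in range(len(all_hp))],
            "admission_date": _dates_from_ordinals(all_ha),
            "discharge_date": _dates_from_ordinals(all_ha + all_hl),
            "code": all_hc,
            "position": positions,
        }
    )

    cp = np.concatenate(p_person) if p_person else np.zeros(0, dtype=int)
    cs = np.concatenate(p_svc) if p_svc else np.zeros(0, dtype=np.int64)
    cc = np.concatenate(p_code) if p_code else np.zeros(0, dtype="U8")
    bp = np.concatenate(bg_person) if bg_person else np.zeros(0, dtype=int)
    bs = np.concatenate(bg_svc) if bg_svc else np.zeros(0, dtype=np.int64)
    bc = _codes("V70", "Z00", bs, phys_switch) if len(bs) else np.zeros(0, dtype="U8")
    fp = np.asarray(fu_p_person, dtype=int)
    fs = np.asarray(fu_p_svc, dtype=np.int64)
    fc = _codes("V70", "Z00", fs, phys_switch) if len(fs) else np.zeros(0, dtype="U8")
    all_pp = np.concatenate([cp, bp, fp])
    all_ps = np.concatenate([cs, bs, fs])
    all_pc = np.concatenate([cc, bc, fc])
    setting = np.where(rng.random(len(all_pp)) < 0.9, "outpatient", "inpatient")
    provider = np.concatenate(
        [
            np.where(rng.random(len(cp)) < 0.55, "GP", "specialist"),
            np.full(len(bp), "GP"),
            np.asarray(fu_p_provider, dtype="U10") if len(fp) else np.zeros(0, dtype="U10"),
        ]
    )
    is_ed = np.concatenate(
        [np.zeros(len(cp) + len(bp), dtype=bool), np.asarray(fu_p_is_ed, dtype=bool)]
    )
    physician = pd.DataFrame(
        {
            "person_id": person_ids[all_pp],
            "service_date": _dates_from_ordinals(all_ps),
            "code": all_pc,
            "setting": setting,
            "provider_type": provider,
            "is_ed": is_ed,
        }
    )

    drugs = pd.DataFrame(
        {
            "person_id": person_ids[np.asarray(d_person, dtype=int)] if d_person else np.zeros(0, dtype="U10"),
            "claim_date": _dates_from_ordinals(np.asarray(d_day, dtype=np.int64)),
            "denomination": d_denom,
        }
    )
    coverage = pd.DataFrame(
        {
            "person_id": person_ids[np.asarray(cov_person, dtype=int)],
            "start_date": _dates_from_ordinals(np.asarray(cov_s, dtype=np.int64)),
            "end_date": _dates_from_ordinals(np.asarray(cov_e, dtype=np.int64)),
        }
    )

    bundle = ClaimsBundle(
        persons=persons, coverage=coverage, hospital=hospital, physician=physician, drugs=drugs
    ).validate()

    outcome_truth = pd.DataFrame({"person_id": person_ids, "true_count": true_count})
    for name in OUTCOME_NAMES:
        outcome_truth[f"p_{name}"] = p_true[name]
    for name in OUTCOME_NAMES:
        outcome_truth[f"y_{name}"] = y_drawn[name].astype(int)
    onsets = (
        pd.concat(onset_rows, ignore_index=True)
        if onset_rows
        else pd.DataFrame(columns=["person_id", "condition_id", "onset_date", "offset_date"])
    )
    return bundle, TruthTable(onsets=onsets, outcomes=outcome_truth)
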