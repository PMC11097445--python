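"""Logistic outcome-prediction sweep and performance metrics.

For every combination of multimorbidity criterion (MM2+/MM3+/MM4+), disease
list, lookback period and outcome, a logistic model is fit with the
multimorbidity indicator plus baseline covariates (age band, sex, material
and social deprivation as categorical terms), and compared with a
covariates-only baseline model.  Performance is measured in-sample
(apparent performance) by:

* the c-statistic — concordance probability / area under the ROC curve —
  with a 95% confidence interval from the DeLong variance estimator;
* the scaled Brier score, 1 − BS/BS_ref where BS_ref uses the constant
  event-rate predictor (0 = no better than the event rate, 1 = perfect);
* calibration intercept (fixed-slope, offset parameterisation:
  calibration-in-the-large) and calibration slope (coefficient of logit p
  when refitting the outcome on it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr as scipy_qr
from scipy.special import logit
from scipy.stats import norm, rankdata

from .ascertainment import AscertainmentMatrix, ascertain
from .claims_model import ClaimsBundle, CohortSpec, DiseaseList, age_at
from .outcomes import OUTCOME_NAMES, build_outcomes
from .synthetic_claims import AGE_BANDS, AGE_BAND_LABELS

__all__ = [
    "fit_logistic",
    "c_statistic",
    "scaled_brier",
    "calibration",
    "covariate_frame",
    "design_matrix",
    "run_sweep",
    "maximal_performance",
    "compare_models",
    "C_DIFFERENCE_THRESHOLD",
]

# a c-statistic difference larger than this is treated as meaningful
C_DIFFERENCE_THRESHOLD = 0.010

STRATA = ("all", "age66_79", "age80plus", "female", "male")

_CLAMP_EPS = 1e-12


@dataclass
class LogisticFit:
    probabilities: np.ndarray
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    separation: bool


def fit_logistic(design: pd.DataFrame | np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary ``y`` on ``design``.

    ``design`` must already contain the intercept column.  Raises
    ``ValueError`` for a constant outcome and ``RuntimeError`` when the
    optimiser does not converge.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant: logistic model undefined")
    model = sm.Logit(y, np.asarray(design, dtype=float))
    separation = False
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            # singular Hessian or (quasi-)separation: flag and fall back to a
            # gradient-based optimiser
            separation = True
            res = None
        if res is None or not res.mle_retvals.get("converged", True):
            res = model.fit(disp=0, maxiter=1000, method="bfgs", gtol=1e-6)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit failed to converge (n={len(y)}, events={int(y.sum())})"
        )
    names = design.columns if isinstance(design, pd.DataFrame) else range(np.asarray(design).shape[1])
    p = np.clip(res.predict(np.asarray(design, dtype=float)), _CLAMP_EPS, 1 - _CLAMP_EPS)
    # flag (quasi-)separation: fitted probabilities numerically at the boundary
    if np.any(p <= 1e-10) or np.any(p >= 1 - 1e-10):
        separation = True
    with np.errstate(all="ignore"):
        bse = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        probabilities=p,
        params=pd.Series(np.asarray(res.params, dtype=float), index=list(names)),
        bse=pd.Series(bse, index=list(names)),
        llf=float(res.llf),
        converged=converged,
        separation=separation,
    )


def c_statistic(p: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Concordance probability with a DeLong 95% confidence interval.

    Among all event/non-event pairs, the fraction where the event received
    the higher prediction, ties counted 1/2.  Returns (c, ci_low, ci_high);
    the interval is NaN when either class has fewer than two members.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y).astype(bool)
    pos, neg = p[y], p[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    ranks_all = rankdata(np.concatenate([pos, neg]))
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if m < 2 or n < 2:
        return float(auc), float("nan"), float("nan")
    v10 = (ranks_all[:m] - rankdata(pos)) / n  # structural components (events)
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m  # non-events
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def scaled_brier(p: np.ndarray, y: np.ndarray) -> float:
    """1 − BS/BS_ref, the Brier score scaled by the event-rate predictor."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    bs_ref = np.mean((ybar - y) ** 2)
    if bs_ref == 0:
        raise ValueError("outcome is constant: scaled Brier undefined")
    return float(1.0 - np.mean((p - y) ** 2) / bs_ref)


def calibration(p: np.ndarray, y: np.ndarray, eps: float = _CLAMP_EPS) -> tuple[float, float]:
    """Calibration intercept and slope of predictions ``p`` against ``y``.

    Slope: coefficient of logit(p) in a logistic refit of y.  Intercept:
    intercept of a logistic fit of y with logit(p) as a fixed offset
    (calibration-in-the-large).  Predictions are clamped to (eps, 1−eps).
    """
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant: calibration undefined")
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise ValueError("degenerate predictions: logit(p) is constant")
    fam = sm.families.Binomial()
    const = np.ones_like(lp)
    slope_fit = sm.GLM(y, np.column_stack([const, lp]), family=fam).fit()
    intercept_fit = sm.GLM(y, const[:, None], family=fam, offset=lp).fit()
    return float(intercept_fit.params[0]), float(slope_fit.params[1])


def compare_models(c_a: float, c_b: float, threshold: float = C_DIFFERENCE_THRESHOLD) -> bool:
    """True when the two c-statistics differ by more than ``threshold``."""
    return abs(float(c_a) - float(c_b)) > threshold


# ---------------------------------------------------------------------------
# design construction


def _age_band_label(age: int) -> str:
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age <= hi:
            return label
    return AGE_BAND_LABELS[-1] if age > AGE_BANDS[-1][1] else AGE_BAND_LABELS[0]


def covariate_frame(persons: pd.DataFrame, cohort: CohortSpec) -> pd.DataFrame:
    """Baseline covariates per person: age band, sex, deprivation quintiles."""
    ages = persons["birth_date"].map(lambda b: age_at(b, cohort.index_date))
    return pd.DataFrame(
        {
            "age": ages.to_numpy(),
            "age_band": pd.Categorical(ages.map(_age_band_label), categories=AGE_BAND_LABELS),
            "sex": pd.Categorical(persons["sex"], categories=["F", "M"]),
            "material_dep": pd.Categorical(
                persons["material_dep"], categories=["Q1", "Q2", "Q3", "Q4", "Q5", "missing"]
            ),
            "social_dep": pd.Categorical(
                persons["social_dep"], categories=["Q1", "Q2", "Q3", "Q4", "Q5", "missing"]
            ),
        },
        index=pd.Index(persons["person_id"], name="person_id"),
    )


def design_matrix(cov: pd.DataFrame, mm: np.ndarray | None = None) -> pd.DataFrame:
    """Dummy-coded design with intercept.

    Constant columns are dropped so that age bands collapse automatically
    inside age strata, and aliased (perfectly collinear) dummies — e.g. the
    joint missing-deprivation category appearing in both quintile factors —
    are removed by a rank-revealing QR.
    """
    dummies = pd.get_dummies(
        cov[["age_band", "sex", "material_dep", "social_dep"]], drop_first=True, dtype=float
    )
    dummies = dummies.loc[:, dummies.nunique() > 1]
    X = pd.concat([pd.Series(1.0, index=cov.index, name="const"), dummies], axis=1)
    arr = X.to_numpy(dtype=float)
    _, r, piv = scipy_qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    X = X.iloc[:, keep]
    if mm is not None:
        X["mm"] = np.asarray(mm, dtype=float)
    return X


# ---------------------------------------------------------------------------
# factorial sweep


def _stratum_mask(name: str, cov: pd.DataFrame) -> np.ndarray:
    if name == "all":
        return np.ones(len(cov), dtype=bool)
    if name == "age66_79":
        return (cov["age"] <= 79).to_numpy()
    if name == "age80plus":
        return (cov["age"] >= 80).to_numpy()
    if name == "female":
        return (cov["sex"] == "F").to_numpy()
    if name == "male":
        return (cov["sex"] == "M").to_numpy()
    raise ValueError(f"unknown stratum {name!r}; choose from {STRATA}")


_RESULT_COLUMNS = [
    "stratum", "outcome", "list", "criterion", "lp", "baseline", "n", "n_events",
    "mm_prevalence", "c", "c_lo", "c_hi", "scaled_brier", "cal_intercept",
    "cal_slope", "converged", "flagged",
]


def _metric_row(base: dict, X: pd.DataFrame, y: np.ndarray) -> dict:
    row = dict(base)
    row["n"] = len(y)
    row["n_events"] = int(y.sum())
    if y.min() == y.max():
        row.update({k: np.nan for k in ("c", "c_lo", "c_hi", "scaled_brier", "cal_intercept", "cal_slope")})
        row["converged"] = False
        row["flagged"] = True
        return row
    try:
        fit = fit_logistic(X, y)
    except RuntimeError:
        row.update({k: np.nan for k in ("c", "c_lo", "c_hi", "scaled_brier", "cal_intercept", "cal_slope")})
        row["converged"] = False
        row["flagged"] = True
        return row
    c, lo, hi = c_statistic(fit.probabilities, y)
    try:
        ci, cs = calibration(fit.probabilities, y)
    except ValueError:
        ci, cs = np.nan, np.nan
    row.update(
        c=c, c_lo=lo, c_hi=hi,
        scaled_brier=scaled_brier(fit.probabilities, y),
        cal_intercept=ci, cal_slope=cs,
        converged=fit.converged, flagged=fit.separation,
    )
    return row


def run_sweep(
    bundle: ClaimsBundle,
    lists: Mapping[str, DiseaseList],
    cohort: CohortSpec,
    criteria: Sequence[int] = (2, 3, 4),
    lps: Sequence[int] | None = None,
    strata: Sequence[str] = ("all",),
    use_disease_specific: bool = False,
    outcome_table: pd.DataFrame | None = None,
    matrices: Mapping[str, AscertainmentMatrix] | None = None,
) -> pd.DataFrame:
    """Fit the full factorial of multimorbidity models plus baselines.

    One row per (stratum, outcome, list, criterion, lp) plus, per stratum and
    outcome, a covariates-only baseline row.  Non-mortality outcomes are
    restricted to persons alive through follow-up with continuous drug-plan
    coverage.  With the default 3 lists × 3 criteria × 20 LPs × 6 outcomes
    and ``strata=("all",)`` the non-baseline row count is 1080.
    """
    lps = list(lps) if lps is not None else list(range(1, cohort.max_lookback_years + 1))
    persons = bundle.cohort_persons(cohort)
    cov = covariate_frame(persons, cohort)
    if outcome_table is None:
        outcome_table = build_outcomes(bundle, cohort)
    outcome_table = outcome_table.reindex(cov.index)
    if matrices is None:
        matrices = {
            name: ascertain(bundle, dl, cohort, use_disease_specific=use_disease_specific)
            for name, dl in lists.items()
        }
    counts = {name: m.counts_by_lp().reindex(cov.index).to_numpy() for name, m in matrices.items()}

    rows: list[dict] = []
    for stratum in strata:
        smask = _stratum_mask(stratum, cov)
        for outcome in OUTCOME_NAMES:
            if outcome == "death":
                emask = smask
            else:
                emask = smask & outcome_table["eligible_nonmortality"].to_numpy()
            sub_cov = cov.loc[emask]
            y = outcome_table.loc[emask, outcome].to_numpy(dtype=float)
            base = {"stratum": stratum, "outcome": outcome, "list": "", "criterion": 0,
                    "lp": 0, "baseline": True, "mm_prevalence": np.nan}
            X_base = design_matrix(sub_cov)
            rows.append(_metric_row(base, X_base, y))
            for list_name in lists:
                cnt = counts[list_name][emask]
                for k in criteria:
                    for lp in lps:
                        mm = cnt[:, lp - 1] >= k
                        spec = {"stratum": stratum, "outcome": outcome, "list": list_name,
                                "criterion": k, "lp": lp, "baseline": False,
                                "mm_prevalence": float(mm.mean()) if len(mm) else np.nan}
                        rows.append(_metric_row(spec, X_base.assign(mm=mm.astype(float)), y))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def maximal_performance(
    results: pd.DataFrame, tol: float = 0.001, expected_lps: Sequence[int] | None = None
) -> pd.DataFrame:
    """Maximal c-statistic per (stratum, list, criterion, outcome).

    Reports the maximum, the shortest LP at which it is reached (ties broken
    toward the shortest), and the band of LPs whose c-statistic lies within
    ``tol`` of the maximum.  Raises ``ValueError`` when the LP grid of a
    group is incomplete.
    """
    mm = results.loc[~results["baseline"].astype(bool)]
    expected = sorted(expected_lps) if expected_lps is not None else sorted(mm["lp"].unique())
    out = []
    for (stratum, list_name, k, outcome), grp in mm.groupby(
        ["stratum", "list", "criterion", "outcome"], sort=True, observed=True
    ):
        have = sorted(grp["lp"].unique())
        missing = sorted(set(expected) - set(have))
        if missing:
            raise ValueError(
                f"incomplete LP grid for ({list_name}, MM{k}+, {outcome}): missing LPs {missing}"
            )
        grp = grp.sort_values("lp")
        c = grp["c"].to_numpy()
        lp = grp["lp"].to_numpy()
        c_max = np.nanmax(c)
        lp_at_max = int(lp[np.nanargmax(c)])  # argmax returns first hit = shortest LP
        band = lp[c >= c_max - tol]
        out.append(
            {
                "stratum": stratum, "list": list_name, "criterion": k, "outcome": outcome,
                "c_max": float(c_max), "lp_at_max": lp_at_max,
                "band_min": int(band.min()), "band_max": int(band.max()),
                "band_lps": ",".join(str(int(b)) for b in band),
            }
        )
    return pd.DataFrame(out)
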