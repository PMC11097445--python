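"""Logistic fitting, discrimination/calibration metrics and the sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from mm_lookback.disease_lists import load_bundled_list
from mm_lookback.prediction import (
    c_statistic,
    calibration,
    compare_models,
    covariate_frame,
    design_matrix,
    fit_logistic,
    maximal_performance,
    run_sweep,
    scaled_brier,
)
from .oracles import oracle_c_statistic


class TestFitLogistic:
    def test_intercept_only_recovers_event_rate(self):
        y = np.array([1, 0, 0, 0] * 25)
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.probabilities == pytest.approx(np.full(100, 0.25), abs=1e-6)

    def test_two_by_two_odds_ratio_closed_form(self):
        # cells (a,b;c,d) = (30,10;20,40): OR = 30*40/(10*20) = 6
        x = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        fit = fit_logistic(pd.DataFrame({"const": np.ones(100), "x": x}), y)
        assert np.exp(fit.params["x"]) == pytest.approx(6.0, rel=1e-5)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_nested_model_never_loses_likelihood(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.random(n) < 0.4
        y = rng.random(n) < expit(-1.5 + 1.0 * x)
        base = pd.DataFrame({"const": np.ones(n)})
        small = fit_logistic(base, y)
        big = fit_logistic(base.assign(mm=x.astype(float)), y)
        assert big.llf >= small.llf - 1e-9


class TestCStatistic:
    def test_perfect_ranking(self):
        c, lo, hi = c_statistic([0.9, 0.1], [1, 0])
        assert c == 1.0

    def test_all_ties_give_half(self):
        c, *_ = c_statistic([0.3] * 10, [1, 0] * 5)
        assert c == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        p = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)  # ties likely
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        c, lo, hi = c_statistic(p, y)
        assert c == pytest.approx(oracle_c_statistic(p, y), abs=1e-12)
        assert lo <= c <= hi

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        p = rng.random(500)
        y = rng.random(500) < p
        c, *_ = c_statistic(p, y)
        assert c == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(60)
        y = rng.random(60) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        c1, *_ = c_statistic(p, y)
        c2, *_ = c_statistic(expit(3 * logit(np.clip(p, 1e-9, 1 - 1e-9)) + 1), y)
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestScaledBrier:
    def test_event_rate_predictor_scores_zero(self):
        y = np.array([1, 1, 0, 0, 0])
        assert scaled_brier(np.full(5, y.mean()), y) == pytest.approx(0.0)

    def test_perfect_predictor_scores_one(self):
        y = np.array([1, 0, 1, 0])
        assert scaled_brier(y.astype(float), y) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert scaled_brier([0.8, 0.4], [1, 0]) == pytest.approx(0.6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            scaled_brier([0.5, 0.5], [1, 1])


class TestCalibration:
    def test_true_probabilities_are_calibrated(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.05, 0.95, size=50_000)
        y = rng.random(50_000) < p
        intercept, slope = calibration(p, y)
        assert intercept == pytest.approx(0.0, abs=0.05)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_logit_doubling_halves_the_slope(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(0.05, 0.95, size=50_000)
        y = rng.random(50_000) < p
        p_miscal = expit(2.0 * logit(p))
        _, slope = calibration(p_miscal, y)
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration(np.full(100, 0.3), np.r_[np.ones(50), np.zeros(50)])


class TestCompareModels:
    @pytest.mark.parametrize(
        "a, b, expected", [(0.798, 0.779, True), (0.700, 0.705, False), (0.7, 0.7, False)]
    )
    def test_threshold(self, a, b, expected):
        assert compare_models(a, b) is expected


class TestSweep:
    @pytest.fixture(scope="class")
    def sweep_inputs(self, small_sim):
        cfg, bundle, _ = small_sim
        lists = {n: load_bundled_list(n) for n in ("L20",)}
        return cfg, bundle, lists

    def test_tiny_sweep_contract(self, sweep_inputs):
        """On a small bundle the sweep completes, has the right row count
        and every c lies in [0, 1]."""
        cfg, bundle, lists = sweep_inputs
        res = run_sweep(bundle, lists, cfg.cohort_spec(), criteria=(2, 3), lps=(1, 5, 10))
        mm = res[~res.baseline]
        assert len(mm) == 1 * 2 * 3 * 6
        assert res.baseline.sum() == 6
        ok = mm.c.dropna()
        assert ((ok >= 0) & (ok <= 1)).all()
        assert (mm.c_lo.dropna() <= mm.c.dropna()).all()
        assert (mm.c.dropna() <= mm.c_hi.dropna()).all()

    def test_sweep_is_deterministic(self, sweep_inputs):
        cfg, bundle, lists = sweep_inputs
        a = run_sweep(bundle, lists, cfg.cohort_spec(), criteria=(2,), lps=(3,))
        b = run_sweep(bundle, lists, cfg.cohort_spec(), criteria=(2,), lps=(3,))
        pd.testing.assert_frame_equal(a, b)

    def test_age_strata_partition_cohort(self, sweep_inputs):
        cfg, bundle, lists = sweep_inputs
        res = run_sweep(
            bundle, lists, cfg.cohort_spec(), criteria=(2,), lps=(5,),
            strata=("all", "age66_79", "age80plus"),
        )
        death = res[(res.outcome == "death") & res.baseline].set_index("stratum")
        assert death.loc["age66_79", "n"] + death.loc["age80plus", "n"] == death.loc["all", "n"]


class TestMaximalPerformance:
    def _results(self, c_by_lp, lps=range(1, 21)):
        return pd.DataFrame(
            {
                "stratum": "all", "outcome": "death", "list": "L20", "criterion": 3,
                "lp": list(lps), "baseline": False, "c": c_by_lp,
            }
        )

    def test_monotone_curve_peaks_at_longest_lp(self):
        res = self._results(np.linspace(0.6, 0.8, 20))
        row = maximal_performance(res).iloc[0]
        assert row.lp_at_max == 20
        assert row.c_max == pytest.approx(0.8)

    def test_flat_curve_ties_break_to_shortest_lp(self):
        res = self._results([0.7] * 20)
        row = maximal_performance(res).iloc[0]
        assert row.lp_at_max == 1
        assert (row.band_min, row.band_max) == (1, 20)

    def test_band_uses_0p001_tolerance(self):
        c = [0.70] * 20
        c[9] = 0.710  # max at LP 10
        c[10] = 0.7095  # within 0.001 of the max
        row = maximal_performance(self._results(c)).iloc[0]
        assert row.lp_at_max == 10
        assert row.band_lps == "10,11"

    def test_random_curves_match_linear_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            c = rng.uniform(0.6, 0.8, size=20)
            row = maximal_performance(self._results(c)).iloc[0]
            assert row.c_max == pytest.approx(c.max())
            assert row.lp_at_max == int(np.argmax(c)) + 1
            assert row.band_lps == ",".join(
                str(i + 1) for i in range(20) if c[i] >= c.max() - 0.001
            )

    def test_incomplete_lp_grid_rejected(self):
        res = self._results([0.7] * 19, lps=list(range(1, 20)))
        with pytest.raises(ValueError, match="missing LPs"):
            maximal_performance(res, expected_lps=range(1, 21))


def test_steep_count_gradient_favours_higher_criteria():
    """When mortality risk rises steeply with the true disease count, the
    MM3+/MM4+ definitions discriminate at least as well as MM2+."""
    from mm_lookback.synthetic_claims import generate_bundle, steep_gradient_config

    cfg = steep_gradient_config(n_persons=4000, seed=29)
    bundle, _ = generate_bundle(cfg)
    res = run_sweep(
        bundle, {"L60": load_bundled_list("L60")}, cfg.cohort_spec(), criteria=(2, 3, 4), lps=(10,)
    )
    death = res[(res.outcome == "death") & ~res.baseline].set_index("criterion")
    assert max(death.loc[3, "c"], death.loc[4, "c"]) >= death.loc[2, "c"]


def test_design_matrix_collapses_bands_within_stratum(small_sim):
    cfg, bundle, _ = small_sim
    cov = covariate_frame(bundle.cohort_persons(cfg.cohort_spec()), cfg.cohort_spec())
    X_all = design_matrix(cov)
    X_young = design_matrix(cov[cov.age <= 79])
    assert sum(c.startswith("age_band") for c in X_all.columns) == 5
    assert sum(c.startswith("age_band") for c in X_young.columns) == 2
    # the joint missing-deprivation category must appear only once
    missing_cols = [c for c in X_all.columns if c.endswith("missing")]
    assert len(missing_cols) == 1
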