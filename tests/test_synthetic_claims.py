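"""Synthetic-claims generator: determinism, structure and analytic recovery."""

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

from mm_lookback.ascertainment import ascertain
from mm_lookback.claims_model import write_claims_bundle
from mm_lookback.disease_lists import load_bundled_list
from mm_lookback.synthetic_claims import (
    SimulationConfig,
    TruthTable,
    closed_form_ascertainment,
    closed_form_scenario_config,
    default_config,
    generate_bundle,
)


class TestClosedForm:
    @pytest.mark.parametrize("h, L, expected", [(0.0, 5, 0.0), (1.0, 1, 1.0), (0.2, 10, 1 - 0.8**10)])
    def test_values(self, h, L, expected):
        assert closed_form_ascertainment(h, L) == pytest.approx(expected)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            closed_form_ascertainment(1.2, 5)
        with pytest.raises(ValueError):
            closed_form_ascertainment(0.5, 0)


class TestGenerator:
    def test_zero_persons_gives_empty_bundle_and_truth(self):
        cfg = dataclasses.replace(default_config(0, seed=1))
        bundle, truth = generate_bundle(cfg)
        assert len(bundle.persons) == 0
        assert len(truth.onsets) == 0 and len(truth.outcomes) == 0

    def test_fixed_seed_reproduces_byte_identical_output(self, tmp_path):
        cfg = default_config(300, seed=5)
        b1, t1 = generate_bundle(cfg)
        b2, t2 = generate_bundle(cfg)
        write_claims_bundle(b1, tmp_path / "a")
        write_claims_bundle(b2, tmp_path / "b")
        for name in ("persons", "coverage", "hospital", "physician", "drugs"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (tmp_path / "b" / f"{name}.csv").read_bytes()
        pd.testing.assert_frame_equal(t1.outcomes, t2.outcomes)

    def test_different_seeds_differ(self):
        b1, _ = generate_bundle(default_config(200, seed=1))
        b2, _ = generate_bundle(default_config(200, seed=2))
        assert not b1.persons.equals(b2.persons)

    def test_zero_emission_rates_yield_no_condition_claims(self):
        cfg = closed_form_scenario_config(200, n_conditions=3, h=0.0, seed=3)
        bundle, truth = generate_bundle(cfg)
        assert len(bundle.hospital) == 0
        assert len(bundle.physician) == 0
        assert len(truth.onsets) > 0  # conditions exist latently

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="sex_female_prob"):
            dataclasses.replace(default_config(10), sex_female_prob=1.5).validate()
        with pytest.raises(ValueError, match="n_persons"):
            SimulationConfig(n_persons=-1).validate()

    def test_coding_era_switches_with_claim_date(self, small_sim):
        """Codes before each switch date come from the ICD-9 prefix set,
        codes after from the ICD-10 set (hospital switches in 2006,
        physician claims in 2019)."""
        cfg, bundle, _ = small_sim
        icd9 = {c.icd9 for c in cfg.conditions} | {"V70", "V58"}
        icd10 = {c.icd10 for c in cfg.conditions} | {"Z00", "Z51"}

        def _check(df, date_col, switch):
            pre = df.loc[df[date_col] < switch, "code"]
            post = df.loc[df[date_col] >= switch, "code"]
            assert pre.str[:3].isin(icd9).all()
            assert post.str[:3].isin(icd10).all()

        _check(bundle.hospital, "admission_date", date(2006, 4, 1))
        _check(bundle.physician, "service_date", date(2019, 1, 1))

    def test_cohort_all_eligible_age(self, small_sim):
        cfg, bundle, _ = small_sim
        assert len(bundle.cohort_persons(cfg.cohort_spec())) == cfg.n_persons

    def test_outcome_frequencies_match_truth_probabilities(self, small_sim):
        """Drawn outcome rates sit within 3 binomial SEs of the mean true
        probability per outcome."""
        _, _, truth = small_sim
        for name in ("death", "hospitalisation", "polypharmacy"):
            p = truth.outcomes[f"p_{name}"].to_numpy()
            y = truth.outcomes[f"y_{name}"].to_numpy()
            se = np.sqrt(np.sum(p * (1 - p))) / len(p)
            assert abs(y.mean() - p.mean()) < 3 * se + 1e-12

    def test_truth_table_round_trips(self, small_sim, tmp_path):
        _, _, truth = small_sim
        truth.write(tmp_path)
        back = TruthTable.read(tmp_path)
        assert len(back.onsets) == len(truth.onsets)
        pd.testing.assert_frame_equal(
            back.outcomes, truth.outcomes, check_dtype=False, check_exact=False, atol=1e-12
        )


class TestClosedFormRecovery:
    def test_hospital_only_ascertainment_matches_analytic_curve(self, mini_list, cohort):
        """With hospital-only emission and always-present conditions the
        empirical ascertainment probability at each LP tracks 1-(1-h)^L
        within 3 Monte-Carlo SEs."""
        h, n, n_cond = 0.15, 1500, 4
        cfg = closed_form_scenario_config(n, n_conditions=n_cond, h=h, seed=21)
        bundle, _ = generate_bundle(cfg)
        dl = load_bundled_list("L60").replace_conditions(
            [
                dataclasses.replace(
                    load_bundled_list("L60").conditions[0],
                    condition_id=c.condition_id, icd9_patterns=(c.icd9,), icd10_patterns=(c.icd10,),
                )
                for c in cfg.conditions
            ],
            name="cf",
        )
        counts = ascertain(bundle, dl, cfg.cohort_spec()).counts_by_lp()
        n_pairs = n * n_cond
        for lp in (1, 3, 5, 10, 20):
            empirical = counts[lp].sum() / n_pairs
            expected = closed_form_ascertainment(h, lp)
            se = np.sqrt(expected * (1 - expected) / n_pairs)
            assert abs(empirical - expected) < 3 * se + 5e-4


def test_default_scenario_prevalence_decelerates(small_sim):
    """Prevalence-vs-LP growth is fastest in the first years and decelerates
    beyond 10 years, the qualitative saturation pattern."""
    cfg, bundle, _ = small_sim
    from mm_lookback.prevalence import prevalence_curve

    matrix = ascertain(bundle, load_bundled_list("L31"), cfg.cohort_spec())
    curve = prevalence_curve(matrix, 2)
    early = curve.loc[curve.lp.between(2, 5), "rel_change"].mean()
    late = curve.loc[curve.lp.between(11, 20), "rel_change"].mean()
    assert late < early
    assert (np.diff(curve["prevalence"]) >= 0).all()
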