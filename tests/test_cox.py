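"""Prentice-weighted Cox core: oracle equivalence, risk sets, invariances."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize_scalar

import casecohort as cc
from casecohort.cox import SingularInformationError, _loglik_breslow, build_design_matrix

from conftest import clean_config, r_coxph_oracle, single_locus


def full_cohort_analysis_set(n=1500, seed=17):
    cfg = clean_config(
        n_individuals=n,
        covariate_effects={"bmi_group": 0.5, "sex": 0.3},
        seed=seed,
    )
    coh = cc.simulate_cohort(cfg)
    coh["subcohort_flag"] = 1
    return cc.assemble_analysis_set(coh, timescale="age")


class TestOracleEquivalence:
    def test_full_cohort_matches_lifelines(self):
        a = full_cohort_analysis_set()
        fit = cc.fit_prentice_cox(a, ["bmi_group", "sex", "diet_score"])
        cph = CoxPHFitter()
        cph.fit(
            a[["entry_time", "exit_time", "event", "bmi_group", "sex", "diet_score"]],
            duration_col="exit_time",
            event_col="event",
            entry_col="entry_time",
        )
        np.testing.assert_allclose(fit.params.values, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se(robust=False).values, cph.standard_errors_.values, atol=1e-6)

    def test_full_cohort_matches_r_survival_including_robust(self, tmp_path):
        a = full_cohort_analysis_set()
        covs = ["bmi_group", "sex", "diet_score"]
        fit = cc.fit_prentice_cox(a, covs)
        beta, naive, robust = r_coxph_oracle(a, covs, tmp_path)
        np.testing.assert_allclose(fit.params.values, beta, atol=1e-6)
        np.testing.assert_allclose(fit.se(robust=False).values, naive, atol=1e-6)
        np.testing.assert_allclose(fit.se(robust=True).values, robust, atol=1e-6)

    def test_efron_ties_match_lifelines(self):
        a = full_cohort_analysis_set(n=800, seed=23)
        a["exit_time"] = a["entry_time"] + np.ceil(a["exit_time"] - a["entry_time"])  # force ties
        fit = cc.fit_prentice_cox(a, ["bmi_group", "sex"], ties="efron")
        cph = CoxPHFitter()
        cph.fit(
            a[["entry_time", "exit_time", "event", "bmi_group", "sex"]],
            duration_col="exit_time",
            event_col="event",
            entry_col="entry_time",
        )
        np.testing.assert_allclose(fit.params.values, cph.params_.values, atol=1e-5)


class TestPrenticeRiskSets:
    def test_hand_built_pseudolikelihood(self):
        # sub-cohort member A at risk throughout; sub-cohort case B fails at
        # t=3; outside case C fails at t=4 and enters only there.  The
        # pseudo-likelihood is
        #   [x_B b - log(e^{x_A b}+e^{x_B b})] + [x_C b - log(e^{x_A b}+e^{x_C b})]
        data = pd.DataFrame(
            {
                "participant_id": ["A", "B", "C"],
                "entry_time": [0.0, 0.0, 0.0],
                "exit_time": [5.0, 3.0, 4.0],
                "event": [0, 1, 1],
                "role": ["subcohort_noncase", "subcohort_case", "outside_case"],
                "x": [0.2, 1.0, -0.5],
            }
        )
        xa, xb, xc = 0.2, 1.0, -0.5

        def nll(b):
            return -(
                xb * b
                - np.log(np.exp(xa * b) + np.exp(xb * b))
                + xc * b
                - np.log(np.exp(xa * b) + np.exp(xc * b))
            )

        oracle = minimize_scalar(nll, bounds=(-5, 5), method="bounded").x
        fit = cc.fit_prentice_cox(data, ["x"])
        assert abs(fit.params["x"] - oracle) < 1e-5
        assert np.isclose(fit.log_pseudolikelihood, -nll(fit.params["x"]))

    def test_outside_case_excluded_from_earlier_risk_sets(self):
        # moving C's failure before B's changes B's risk set contribution
        base = pd.DataFrame(
            {
                "participant_id": ["A", "B", "C"],
                "entry_time": [0.0, 0.0, 0.0],
                "exit_time": [5.0, 3.0, 4.0],
                "event": [0, 1, 1],
                "role": ["subcohort_noncase", "subcohort_case", "outside_case"],
                "x": [0.2, 1.0, -0.5],
            }
        )
        self_prentice = cc.fit_prentice_cox(base, ["x"], scheme="self-prentice")
        prentice = cc.fit_prentice_cox(base, ["x"], scheme="prentice")
        assert not np.isclose(self_prentice.params["x"], prentice.params["x"])


class TestNumericalBehaviour:
    def test_constant_covariate_has_zero_coefficient(self):
        a = full_cohort_analysis_set(n=400, seed=5)
        a["flat"] = 3.0
        fit = cc.fit_prentice_cox(a, ["flat", "sex"])
        assert fit.params["flat"] == 0.0
        assert np.exp(fit.params["flat"]) == 1.0

    def test_pseudolikelihood_increases_from_null(self):
        a = full_cohort_analysis_set(n=600, seed=6)
        fit = cc.fit_prentice_cox(a, ["bmi_group"])
        X = build_design_matrix(a, ["bmi_group"]).to_numpy()
        entry = a["entry_time"].to_numpy()
        # replicate the internal epsilon-entry shift for the null evaluation
        from casecohort.cox import _prentice_entry

        entry = _prentice_entry(entry, a["exit_time"].to_numpy(), a["event"].to_numpy(), a["role"].to_numpy())
        ll0, *_ = _loglik_breslow(np.zeros(1), X, entry, a["exit_time"].to_numpy(), a["event"].to_numpy(float), np.ones(len(a)))
        assert fit.converged
        assert fit.log_pseudolikelihood >= ll0

    def test_followup_time_shift_invariance(self):
        cfg = clean_config(n_individuals=1200, covariate_effects={"bmi_group": 0.4}, seed=8)
        coh = cc.simulate_cohort(cfg)
        sel = cc.select_subcohort(coh, 0.15, seed=1)
        a = cc.assemble_analysis_set(sel, timescale="followup")
        fit = cc.fit_prentice_cox(a, ["bmi_group"])
        b = a.copy()
        b["entry_time"] += 7.5
        b["exit_time"] += 7.5
        fit2 = cc.fit_prentice_cox(b, ["bmi_group"])
        np.testing.assert_allclose(fit.params.values, fit2.params.values, rtol=1e-8)

    def test_collinear_columns_named(self):
        a = full_cohort_analysis_set(n=300, seed=9)
        a["dup"] = a["bmi_group"]
        with pytest.raises(SingularInformationError, match="collinear"):
            cc.fit_prentice_cox(a, ["bmi_group", "dup"])

    def test_no_events_rejected(self):
        a = full_cohort_analysis_set(n=300, seed=10)
        a["event"] = 0
        with pytest.raises(ValueError):
            cc.fit_prentice_cox(a, ["sex"])

    def test_duplicated_rows_leave_robust_se_unchanged(self):
        # doubling every row halves naive variance but per-participant
        # grouping leaves the sandwich variance essentially unchanged
        a = full_cohort_analysis_set(n=500, seed=12)
        fit = cc.fit_prentice_cox(a, ["bmi_group"])
        dup = pd.concat([a, a]).reset_index(drop=True)
        fit2 = cc.fit_prentice_cox(dup, ["bmi_group"])
        assert fit2.se(robust=False)["bmi_group"] < 0.75 * fit.se(robust=False)["bmi_group"]
        assert abs(fit2.se(robust=True)["bmi_group"] - fit.se(robust=True)["bmi_group"]) < 0.05 * fit.se(robust=True)["bmi_group"]

    def test_barlow_weights_require_fraction(self):
        a = full_cohort_analysis_set(n=300, seed=13)
        with pytest.raises(ValueError):
            cc.fit_prentice_cox(a, ["sex"], scheme="barlow")
        fit = cc.fit_prentice_cox(a, ["sex"], scheme="barlow", subcohort_fraction=1.0)
        assert fit.converged


class TestHrSummary:
    def test_null_beta_gives_unit_hr(self):
        a = full_cohort_analysis_set(n=400, seed=14)
        fit = cc.fit_prentice_cox(a, ["sex"])
        fit.params["sex"] = 0.0
        hr, lo, hi = cc.hr_summary(fit, "sex")
        assert hr == 1.0 and lo < 1.0 < hi

    def test_per_sd_scaling(self):
        a = full_cohort_analysis_set(n=400, seed=15)
        fit = cc.fit_prentice_cox(a, ["sex"])
        fit.params["sex"] = np.log(1.08)
        hr, _, _ = cc.hr_summary(fit, "sex", scale="per_sd", sd_value=4.37)
        assert np.isclose(hr, np.exp(4.37 * np.log(1.08)))
        assert round(hr, 2) == 1.40  # printed value 1.41 reflects unrounded beta
        per_allele, _, _ = cc.hr_summary(fit, "sex", scale="per_allele")
        assert np.isclose(per_allele, 1.08)

    def test_invalid_sd(self):
        a = full_cohort_analysis_set(n=400, seed=16)
        fit = cc.fit_prentice_cox(a, ["sex"])
        with pytest.raises(ValueError):
            cc.hr_summary(fit, "sex", scale="per_sd", sd_value=0.0)


def test_stratified_baseline_mode_runs():
    a = full_cohort_analysis_set(n=1000, seed=18)
    fit = cc.fit_prentice_cox(a, ["bmi_group"], strata="country")
    plain = cc.fit_prentice_cox(a, ["bmi_group"])
    assert fit.converged
    # same data, different baseline handling: estimates should be close
    assert abs(fit.params["bmi_group"] - plain.params["bmi_group"]) < 0.2
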