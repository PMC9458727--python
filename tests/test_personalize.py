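import math

import numpy as np
import pandas as pd
import pytest

from adcascade.cohort import CohortTable, DpsParams
from adcascade.model import evaluate_f
from adcascade.personalize import (cohort_personalization_report,
                                   eligible_subjects, fit_personalized,
                                   predict_and_score)
from adcascade.scoring import prediction_accuracy
from adcascade.synthetic import GeneratorConfig, generate_cohort

SENSITIVE = ("w_A1", "w_A2", "w_T4", "w_T5", "w_N4", "w_N5", "w_C3", "w_C5")


def _cohort_from_model(params, n_subjects, n_visits, noise_sd, seed):
    cfg = GeneratorConfig(seed=seed, n_subjects=n_subjects, truth=params,
                          visits_range=(n_visits, n_visits),
                          noise_sd={k: noise_sd for k in "ATNC"})
    return generate_cohort(cfg)


class TestScoring:
    @pytest.mark.parametrize("held, pred, expected", [
        (2.0, 2.0, 100.0), (2.0, 1.9, 95.0), (2.0, 2.1, 95.0),
    ])
    def test_prediction_accuracy_arithmetic(self, held, pred, expected):
        assert prediction_accuracy(held, pred) == pytest.approx(expected)

    def test_zero_held_out_undefined(self):
        assert math.isnan(prediction_accuracy(0.0, 0.3))


class TestEligibility:
    def test_counts_and_monotonicity(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 12, 5, 0.0, seed=21)
        omega = eligible_subjects(cohort, bundle.dps)
        assert set(omega) <= set(cohort.subjects) and omega

    def test_subject_with_three_measurements_excluded(self, lmci_ad_params):
        df = pd.DataFrame([
            ("s1", j, 70.0 + j, "CN", k, 0.1 * j)
            for j in range(1, 5) for k in "ATNC"
        ], columns=["subject_id", "visit", "age_years", "group", "biomarker", "value"])
        df = df[~((df.biomarker == "N") & (df.visit == 4))]  # only 3 N values
        cohort = CohortTable(df, scale="normalized")
        dps = DpsParams(alpha={"s1": 0.2}, beta={"s1": -15.0})
        assert eligible_subjects(cohort, dps) == []

    def test_non_monotone_denoised_series_excluded(self, monkeypatch):
        """Criterion 2: a biomarker whose denoised values wiggle in DPS
        disqualifies the subject."""
        rows = []
        vals = {"A": [0.1, 0.3, 0.2, 0.4], "T": [0.1, 0.2, 0.3, 0.4],
                "N": [0.1, 0.2, 0.3, 0.4], "C": [0.1, 0.2, 0.3, 0.4]}
        for j in range(1, 5):
            for k in "ATNC":
                rows.append(("s1", j, 70.0 + j, "CN", k, vals[k][j - 1]))
        cohort = CohortTable(pd.DataFrame(
            rows, columns=["subject_id", "visit", "age_years", "group",
                           "biomarker", "value"]), scale="normalized")
        dps = DpsParams(alpha={"s1": 0.2}, beta={"s1": -15.0})
        # force the raw (non-monotone) series through: the denoiser itself is
        # monotone whenever its sigmoid fit succeeds
        import adcascade.personalize as mod
        monkeypatch.setattr(mod, "denoise_subject", lambda s, y: (np.asarray(y), True))
        assert eligible_subjects(cohort, dps) == []


class TestPersonalizedFit:
    def test_population_data_is_fixed_point(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 6, 5, 0.0, seed=22)
        omega = eligible_subjects(cohort, bundle.dps)
        sid = omega[0]
        fit = fit_personalized(cohort, bundle.dps, sid, lmci_ad_params, SENSITIVE)
        for name in SENSITIVE:
            assert fit.w2[name] == pytest.approx(lmci_ad_params[name], rel=1e-3)

    def test_single_parameter_perturbation_recovery(self, lmci_ad_params):
        """A +8% shift of w_A1 in the generating model is recovered from one
        subject's noiseless visits."""
        perturbed = lmci_ad_params.with_updates(
            {"w_A1": 1.08 * lmci_ad_params["w_A1"]})
        cohort, bundle = _cohort_from_model(perturbed, 8, 5, 0.0, seed=23)
        omega = eligible_subjects(cohort, bundle.dps)
        sid = max(omega, key=lambda s: np.ptp(
            bundle.dps.s(s, cohort.subject(s)["age_years"].to_numpy())))
        fit = fit_personalized(cohort, bundle.dps, sid, lmci_ad_params, ("w_A1",))
        assert fit.w2["w_A1"] == pytest.approx(perturbed["w_A1"], rel=0.02)

    def test_empty_sensitive_set_returns_population(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 4, 5, 0.0, seed=24)
        sid = eligible_subjects(cohort, bundle.dps)[0]
        fit = fit_personalized(cohort, bundle.dps, sid, lmci_ad_params, ())
        assert fit.w2 == lmci_ad_params and fit.flags

    def test_pinning_of_non_sensitive_parameters(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 4, 5, 0.02, seed=25)
        sid = eligible_subjects(cohort, bundle.dps)[0]
        fit = fit_personalized(cohort, bundle.dps, sid, lmci_ad_params, SENSITIVE)
        for name, val in lmci_ad_params.to_dict().items():
            if name not in SENSITIVE and name != "y0":
                assert fit.w2[name] == val  # bitwise


class TestPrediction:
    def test_noise_free_limit_full_accuracy(self, lmci_ad_params):
        """PA -> 100% for subjects following the population model exactly."""
        cohort, bundle = _cohort_from_model(lmci_ad_params, 6, 5, 0.0, seed=26)
        omega = eligible_subjects(cohort, bundle.dps)
        fit = fit_personalized(cohort, bundle.dps, omega[0], lmci_ad_params, SENSITIVE)
        fit = predict_and_score(fit, cohort, bundle.dps)
        for k in "ATNC":
            assert fit.pa_ode[k] == pytest.approx(100.0, abs=0.5)

    def test_pa_never_exceeds_100(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 6, 5, 0.05, seed=27)
        per_subject, _ = cohort_personalization_report(
            cohort, lmci_ad_params, SENSITIVE, bundle.dps)
        pa_cols = [c for c in per_subject.columns if c.startswith("pa_")]
        assert (per_subject[pa_cols].fillna(-1) <= 100.0 + 1e-9).all().all()

    def test_report_shapes_and_group_summary(self, lmci_ad_params):
        cohort, bundle = _cohort_from_model(lmci_ad_params, 6, 5, 0.03, seed=28)
        per_subject, summary = cohort_personalization_report(
            cohort, lmci_ad_params, SENSITIVE, bundle.dps)
        assert {"subject_id", "group", "n_visits", "dps_span"} <= set(per_subject.columns)
        assert set(summary["stat"]) <= {"mean", "sd"}

    def test_more_visits_do_not_hurt(self, lmci_ad_params):
        """Mean PA with 6 visits >= mean PA with 4 visits - 1pp (2 seeds)."""
        means = {4: [], 6: []}
        for seed in (1, 2):
            for n_visits in (4, 6):
                cohort, bundle = _cohort_from_model(lmci_ad_params, 5, n_visits,
                                                    0.03, seed=seed)
                per_subject, _ = cohort_personalization_report(
                    cohort, lmci_ad_params, SENSITIVE, bundle.dps)
                if len(per_subject):
                    cols = [f"pa_ode_{k}" for k in "ATNC"]
                    means[n_visits].append(
                        np.nanmean(per_subject[cols].to_numpy()))
        assert np.mean(means[6]) >= np.mean(means[4]) - 1.0
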