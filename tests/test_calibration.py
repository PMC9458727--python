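import numpy as np
import pytest

from adcascade.calibration import (CalibrationState, DegenerateDesignError,
                                   bootstrap_band, calibrate, compute_sigma,
                                   fit_dps, fit_weights, refit_weights_fixed_dps)
from adcascade.cohort import DpsParams
from adcascade.model import WEIGHT_NAMES, evaluate_f
from adcascade.synthetic import GeneratorConfig, generate_cohort


class TestSigma:
    def test_arithmetic(self):
        # RSS 2.0, 10 observations, 2 subjects -> 2.0 / |10 - 4 - 4|
        r = np.sqrt([0.5, 0.5, 0.5, 0.5])
        assert compute_sigma(r, 10, 2) == pytest.approx(1.0)

    def test_perfect_fit_gives_zero(self):
        assert compute_sigma(np.zeros(12), 12, 2) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(DegenerateDesignError):
            compute_sigma(np.ones(8), 8, 2)

    def test_noise_doubling_scales_sigma(self, lmci_ad_params):
        """Doubling observation noise roughly quadruples sigma_k."""
        from adcascade.model import _dense_solution
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = rng.uniform(-8, 14, 60)
            truth = _dense_solution(lmci_ad_params)(s)[3]
            eps = rng.normal(0, 1, 60)
            r1 = 0.03 * eps
            r2 = 0.06 * eps + truth * 0  # same draws, doubled scale
            ratios.append(compute_sigma(r2, 60, 10) / compute_sigma(r1, 60, 10))
        assert 3.0 <= np.mean(ratios) <= 5.0


class TestFitWeights:
    def test_fixed_point_at_truth(self, small_noiseless_cohort, lmci_ad_params):
        cohort, bundle = small_noiseless_cohort
        w = fit_weights(cohort, bundle.dps, lmci_ad_params, multi_start=False)
        # fitting solves run at rtol 1e-7, which bounds the fixed-point drift
        assert np.max(np.abs(w.as_array() - lmci_ad_params.as_array())) < 1e-3

    def test_underdetermined_block_flagged(self, lmci_ad_params):
        import pandas as pd
        from adcascade.calibration import fit_weights_with_flags
        from adcascade.cohort import CohortTable
        df = pd.DataFrame({
            "subject_id": ["s1"] * 4, "visit": [1, 2, 3, 4],
            "age_years": [70.0, 71.0, 72.0, 73.0], "group": ["CN"] * 4,
            "biomarker": ["C"] * 4, "value": [0.01, 0.02, 0.03, 0.04]})
        cohort = CohortTable(df, scale="normalized")
        dps = DpsParams(alpha={"s1": 1.0}, beta={"s1": -70.0})
        _, flags = fit_weights_with_flags(cohort, dps, lmci_ad_params)
        assert any("underdetermined" in f for f in flags)

    def test_cohort_size_improves_recovery(self, lmci_ad_params):
        """Weight-vector recovery error shrinks from n=50 to n=200 (2 seeds,
        l2-norm relative error; per-weight ratios are dominated by the
        near-zero cognition weights, which sit below the noise floor)."""
        errs = {50: [], 200: []}
        truth = lmci_ad_params.as_array()
        for seed in (0, 1):
            for n in (50, 200):
                cfg = GeneratorConfig(seed=seed, n_subjects=n, visits_range=(4, 5))
                cohort, bundle = generate_cohort(cfg)
                w = fit_weights(cohort, bundle.dps, lmci_ad_params, multi_start=False)
                errs[n].append(np.linalg.norm(w.as_array() - truth)
                               / np.linalg.norm(truth))
        assert np.mean(errs[200]) <= np.mean(errs[50])


class TestFitDps:
    def test_noiseless_recovery(self, small_noiseless_cohort, lmci_ad_params):
        cohort, bundle = small_noiseless_cohort
        sigma = {k: 1.0 for k in "ATNC"}
        sid = cohort.subjects[0]
        sub = cohort.subject(sid)
        a, b, flag = fit_dps(sub["age_years"].to_numpy(), sub["value"].to_numpy(),
                             sub["biomarker"].to_numpy(), lmci_ad_params, sigma)
        at, bt = bundle.dps.alpha[sid], bundle.dps.beta[sid]
        assert abs(a - at) / at < 0.02
        ages = sub["age_years"].to_numpy()
        assert np.max(np.abs((a * ages + b) - (at * ages + bt))) < 0.05

    def test_objective_zero_at_truth(self, small_noiseless_cohort, lmci_ad_params):
        from adcascade.model import _dense_solution
        cohort, bundle = small_noiseless_cohort
        sid = cohort.subjects[1]
        sub = cohort.subject(sid)
        s = bundle.dps.s(sid, sub["age_years"].to_numpy())
        sol = _dense_solution(lmci_ad_params)
        pred = np.array([sol(np.atleast_1d(si))["ATNC".index(k)][0]
                         for si, k in zip(s, sub["biomarker"])])
        assert np.max(np.abs(pred - sub["value"].to_numpy())) < 1e-7

    def test_sigma_weighting_directional(self, lmci_ad_params):
        """Shrinking one biomarker's sigma pulls the warp toward fitting it."""
        ages = np.array([72.0, 73.0, 74.0, 75.0] * 2)
        ks = np.array(["A"] * 4 + ["C"] * 4)
        # A observations consistent with s(t) = t - 70; C observations with
        # s(t) = t - 64 (conflict), so the weighting decides the compromise
        a_vals = evaluate_f("A", ages[:4] - 70.0, lmci_ad_params)
        c_vals = evaluate_f("C", ages[4:] - 64.0, lmci_ad_params)
        vals = np.concatenate([a_vals, c_vals])

        def c_resid(sigma_c):
            a, b, _ = fit_dps(ages, vals, ks, lmci_ad_params,
                              {"A": 1.0, "T": 1.0, "N": 1.0, "C": sigma_c})
            pred = evaluate_f("C", np.clip(a * ages[4:] + b, -10, 20), lmci_ad_params)
            return float(np.sum((pred - c_vals) ** 2))

        assert c_resid(0.05) < c_resid(1.0)

    def test_too_few_observations(self, lmci_ad_params):
        with pytest.raises(ValueError):
            fit_dps([70.0], [0.1], ["A"], lmci_ad_params, {k: 1.0 for k in "ATNC"})


class TestCalibrate:
    def test_zero_rounds_returns_initialization(self, noisy_cohort, lmci_ad_params):
        cohort, bundle = noisy_cohort
        init = CalibrationState(w=lmci_ad_params, dps=bundle.dps,
                                sigma={k: 1.0 for k in "ATNC"},
                                objective=np.inf, iteration=0)
        state = calibrate(cohort, init=init, L=0)
        assert state.w == lmci_ad_params
        assert state.dps.alpha == bundle.dps.alpha


class TestRefitFixedDps:
    def test_empty_subset_rejected(self, lmci_ad_params):
        import pandas as pd
        from adcascade.cohort import CohortTable
        empty = CohortTable(pd.DataFrame(columns=[
            "subject_id", "visit", "age_years", "group", "biomarker", "value"]))
        with pytest.raises(ValueError):
            refit_weights_fixed_dps(empty, DpsParams(), lmci_ad_params)

    def test_missing_dps_rejected(self, small_noiseless_cohort, lmci_ad_params):
        cohort, _ = small_noiseless_cohort
        with pytest.raises(ValueError, match="no DPS"):
            refit_weights_fixed_dps(cohort, DpsParams(), lmci_ad_params)


class TestBootstrapBand:
    def test_noiseless_band_collapses(self, lmci_ad_params):
        cfg = GeneratorConfig(seed=13, n_subjects=25, visits_range=(4, 4),
                              noise_sd={k: 0.0 for k in "ATNC"})
        cohort, bundle = generate_cohort(cfg)
        state = CalibrationState(w=lmci_ad_params, dps=bundle.dps,
                                 sigma={k: 1.0 for k in "ATNC"},
                                 objective=0.0, iteration=1)
        band = bootstrap_band(cohort, state, B=25, seed=0,
                              s_grid=np.linspace(-10, 20, 31))
        assert np.max(band.upper - band.lower) <= 1e-3

    def test_subject_order_invariance(self, lmci_ad_params):
        cfg = GeneratorConfig(seed=14, n_subjects=12, visits_range=(4, 4),
                              noise_sd={k: 0.01 for k in "ATNC"})
        cohort, bundle = generate_cohort(cfg)
        state = CalibrationState(w=lmci_ad_params, dps=bundle.dps,
                                 sigma={k: 1.0 for k in "ATNC"},
                                 objective=0.0, iteration=1)
        grid = np.linspace(-10, 20, 16)
        b1 = bootstrap_band(cohort, state, B=20, seed=3, s_grid=grid)
        from adcascade.cohort import CohortTable
        shuffled = CohortTable(cohort.df.sample(frac=1.0, random_state=1),
                               scale="normalized")
        b2 = bootstrap_band(shuffled, state, B=20, seed=3, s_grid=grid)
        assert np.allclose(b1.lower, b2.lower) and np.allclose(b1.upper, b2.upper)

    def test_small_b_rejected(self, lmci_ad_params, small_noiseless_cohort):
        cohort, bundle = small_noiseless_cohort
        state = CalibrationState(w=lmci_ad_params, dps=bundle.dps,
                                 sigma={k: 1.0 for k in "ATNC"},
                                 objective=0.0, iteration=1)
        with pytest.raises(ValueError):
            bootstrap_band(cohort, state, B=10)
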