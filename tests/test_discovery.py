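import numpy as np
import pytest

from adcascade.discovery import (DesignSystem, build_design, discover_model,
                                 lasso_fit, _ols_refit)
from adcascade.model import (BIOMARKERS, EQUATION_SLICES, UPSTREAM,
                             build_library, _rhs_core)
from adcascade.sigmoid import SigmoidParams

# exponent tuples are (own, upstream)
CONST, OWN, OWN2 = (0, 0), (1, 0), (2, 0)
UP, UP2, CROSS = (0, 1), (0, 2), (1, 1)


def _true_system(params, equation, m=4, grid_size=301):
    """Design built from the exact ODE trajectory and exact derivatives:
    the well-posed structure-recovery setting."""
    from adcascade.model import solve_model
    grid = np.linspace(-10, 20, grid_size)
    tr = solve_model(params, s_eval=grid)
    derivs = _rhs_core(tr.values.T, params.as_array()[:, None])
    mode = "single" if equation == "A" else "pair"
    spec = build_library(m, mode)
    own = tr.values[:, BIOMARKERS.index(equation)]
    up_name = UPSTREAM[equation]
    up = (tr.values[:, BIOMARKERS.index(up_name)] if up_name
          else np.zeros_like(own))
    D = np.column_stack([own ** i * up ** j for i, j in spec.terms])
    b = derivs[BIOMARKERS.index(equation)]
    return DesignSystem(D=D, b=b, lam=0.0, grid=grid, spec=spec,
                        equation=equation,
                        labels=spec.labels(equation, up_name or ""))


class TestBuildDesign:
    def test_t_equation_has_six_columns_at_m2(self, lmci_ad_sigmoids):
        sys_ = build_design(lmci_ad_sigmoids, "T", build_library(2, "pair"))
        assert sys_.D.shape == (301, 6)
        assert len(sys_.b) == 301

    def test_constant_column_is_ones(self, lmci_ad_sigmoids):
        sys_ = build_design(lmci_ad_sigmoids, "N", build_library(2, "pair"))
        assert np.allclose(sys_.D[:, 0], 1.0)

    def test_flat_sigmoids_give_zero_target_and_rank_warning(self):
        flat = {k: SigmoidParams(0.0, 1.0, 0.0, 0.2) for k in BIOMARKERS}
        sys_ = build_design(flat, "T", build_library(2, "pair"))
        assert np.allclose(sys_.b, 0.0)
        assert "rank_deficient_columns" in sys_.diagnostics

    def test_grid_too_small_rejected(self, lmci_ad_sigmoids):
        with pytest.raises(ValueError):
            build_design(lmci_ad_sigmoids, "T", build_library(2, "pair"), grid_size=3)


class TestLassoFit:
    @pytest.fixture()
    def random_system(self):
        rng = np.random.default_rng(0)
        D = rng.normal(size=(50, 6))
        w = np.array([1.0, 0.0, 2.0, 0.0, 0.0, -1.0])
        b = D @ w + 0.01 * rng.normal(size=50)
        spec = build_library(2, "pair")
        return DesignSystem(D=D, b=b, lam=0.0, grid=np.arange(50), spec=spec,
                            equation="T", labels=spec.labels("T", "A"))

    def test_zero_penalty_matches_ols(self, random_system):
        res = lasso_fit(random_system, lam=0.0)
        ols, *_ = np.linalg.lstsq(random_system.D, random_system.b, rcond=None)
        assert np.max(np.abs(res.weights - ols)) < 1e-8

    def test_tiny_penalty_matches_ols(self, random_system):
        res = lasso_fit(random_system, lam=1e-7)
        ols, *_ = np.linalg.lstsq(random_system.D, random_system.b, rcond=None)
        assert np.max(np.abs(res.weights - ols)) < 1e-6

    def test_moderate_penalty_matches_sklearn(self, random_system):
        """Cross-check the in-house solver against the standard library."""
        from sklearn.linear_model import Lasso
        norms = np.linalg.norm(random_system.D, axis=0)
        for lam in (0.5, 5.0, 50.0):
            res = lasso_fit(random_system, lam=lam)
            sk = Lasso(alpha=lam / (2 * 50), fit_intercept=False,
                       max_iter=200_000, tol=1e-14).fit(
                random_system.D / norms, random_system.b)
            assert np.max(np.abs(res.weights - sk.coef_ / norms)) < 1e-6

    def test_zero_target_gives_zero_weights(self, random_system):
        sys0 = DesignSystem(D=random_system.D, b=np.zeros(50), lam=0.0,
                            grid=random_system.grid, spec=random_system.spec,
                            equation="T", labels=random_system.labels)
        res = lasso_fit(sys0, lam=1.0)
        assert np.allclose(res.weights, 0.0) and res.support == ()

    def test_local_optimality_probe(self, random_system):
        """Objective at the solution beats 100 random small perturbations.

        The penalty applies to unit-l2-standardized columns (the documented
        convention), so the probe evaluates the same objective.
        """
        lam = 5.0
        res = lasso_fit(random_system, lam=lam)
        norms = np.linalg.norm(random_system.D, axis=0)

        def obj(w):
            r = random_system.D @ w - random_system.b
            return r @ r + lam * np.abs(w * norms).sum()

        base = obj(res.weights)
        rng = np.random.default_rng(1)
        for _ in range(100):
            delta = rng.normal(0, 1e-4, 6)
            assert obj(res.weights + delta) >= base - 1e-9 * max(base, 1.0)

    def test_structure_recovery_amyloid_single_library(self, lmci_ad_params):
        """True support {A, A^2} recovered from an m=4 single-variable
        library; constant and cubic/quartic terms zeroed."""
        sys_ = _true_system(lmci_ad_params, "A")
        res = lasso_fit(sys_, lam=1e-7)
        assert sorted(res.support_terms) == [OWN, OWN2]
        sl = EQUATION_SLICES["A"]
        refit = _ols_refit(sys_, res.support)
        for t, wv in zip(build_library(2, "single").terms, lmci_ad_params.as_array()[sl]):
            if wv != 0:
                i = sys_.spec.terms.index(t)
                assert abs((refit[i] - wv) / wv) < 0.05

    @pytest.mark.parametrize("equation", ["T", "N", "C"])
    def test_structure_recovery_downstream_equations(self, lmci_ad_params, equation):
        """With exact trajectories and derivatives, each downstream equation's
        generating support and weights are recovered from the m=4 library."""
        sys_ = _true_system(lmci_ad_params, equation)
        res = lasso_fit(sys_, lam=1e-7)
        sl = EQUATION_SLICES[equation]
        m2_terms = build_library(2, "pair").terms
        true_terms = sorted(t for t, wv in zip(m2_terms, lmci_ad_params.as_array()[sl])
                            if wv != 0)
        assert sorted(res.support_terms) == true_terms
        refit = _ols_refit(sys_, res.support)
        for t, wv in zip(m2_terms, lmci_ad_params.as_array()[sl]):
            if wv != 0:
                i = sys_.spec.terms.index(t)
                assert abs((refit[i] - wv) / wv) < 0.05


class TestDiscoverModel:
    def test_degree_two_cascade_selects_m2(self, lmci_ad_sigmoids):
        res = discover_model(lmci_ad_sigmoids, m_max=4, lam=1e-7)
        assert res.m_star == 2
        assert res.params is not None
        # supports stay within the degree-2 cascade structure and always
        # contain the equation's own dynamics terms
        for eq in BIOMARKERS:
            sup = set(res.supports[(2, eq)])
            assert sup <= {CONST, OWN, OWN2, UP, UP2, CROSS}
            assert {OWN, OWN2} <= sup

    def test_overpenalized_model_flagged_empty(self, lmci_ad_sigmoids):
        res = discover_model(lmci_ad_sigmoids, m_max=4, lam=1e3)
        assert any("empty" in f for f in res.flags)
        assert all(len(res.supports[(4, eq)]) == 0 for eq in BIOMARKERS)

    def test_linear_library_keeps_linear_amyloid_terms(self, lmci_ad_sigmoids):
        res = discover_model(lmci_ad_sigmoids, m_max=2, lam=1e-7)
        assert set(res.supports[(1, "A")]) <= {CONST, OWN}

    def test_report_is_readable(self, lmci_ad_sigmoids):
        res = discover_model(lmci_ad_sigmoids, m_max=2, lam=1e-7)
        text = res.report()
        assert "m* = 2" in text and "dA/ds" in text
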