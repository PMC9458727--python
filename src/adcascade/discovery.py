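"""Sparse discovery of the cascade ODE structure from fitted sigmoids.

Population sigmoid fits g_k(s) act as smooth surrogates for the biomarker
trajectories.  On a uniform DPS grid we regress the analytic sigmoid
derivative dg_k/ds onto a polynomial library of the equation's own and
upstream variables and recover a sparse weight vector with an l1 (Lasso)
penalty.  Running the fit over increasing library degrees and checking that
the selected support stabilizes yields the model degree m*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model import (BIOMARKERS, CascadeParams, EQUATION_SLICES, LibrarySpec,
                    S_MAX, S_MIN, UPSTREAM, WEIGHT_NAMES, build_library)
from .sigmoid import SigmoidParams, sigmoid_derivative, sigmoid_eval

__all__ = ["DesignSystem", "LassoResult", "DiscoveryResult",
           "build_design", "lasso_fit", "discover_model"]

#: relative magnitude below which a coefficient counts as zero
ZERO_THRESHOLD = 1e-6


@dataclass
class DesignSystem:
    """Library-term design matrix D and derivative target b for one equation."""

    D: np.ndarray
    b: np.ndarray
    lam: float
    grid: np.ndarray
    spec: LibrarySpec
    equation: str
    labels: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class LassoResult:
    weights: np.ndarray
    support: tuple[int, ...]          # column indices with non-negligible weight
    support_terms: tuple[tuple[int, int], ...]
    objective: float
    n_iter: int


@dataclass
class DiscoveryResult:
    supports: dict          # (m, equation) -> tuple of exponent-term tuples
    weights: dict           # (m, equation) -> LassoResult
    m_star: int | None
    params: CascadeParams | None
    flags: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = []
        if self.m_star is None:
            lines.append("no stable library degree found")
        else:
            lines.append(f"selected model degree m* = {self.m_star}")
        for (m, eq), res in sorted(self.weights.items()):
            spec = build_library(m, "single" if eq == "A" else "pair")
            labels = spec.labels(eq, UPSTREAM[eq] or "")
            terms = ", ".join(f"{labels[i]}: {res.weights[i]:+.4g}" for i in res.support)
            lines.append(f"m={m} d{eq}/ds = {terms if terms else '(empty)'}")
        for f in self.flags:
            lines.append(f"note: {f}")
        return "\n".join(lines)


def build_design(sigmoids: dict[str, SigmoidParams], equation: str,
                 spec: LibrarySpec, grid_size: int = 301) -> DesignSystem:
    """Evaluate the candidate library on sigmoid values over a uniform DPS grid.

    The equation's variable restriction follows the cascade: the A equation
    sees A only; T sees (T, A); N sees (N, T); C sees (C, N).  The regression
    target b is the analytic sigmoid derivative of the equation's own
    variable.
    """
    if equation not in BIOMARKERS:
        raise ValueError(f"unknown equation {equation!r}")
    if grid_size < len(spec):
        raise ValueError(f"grid_size {grid_size} < library size {len(spec)}")
    grid = np.linspace(S_MIN, S_MAX, grid_size)
    own = np.asarray(sigmoid_eval(grid, sigmoids[equation]))
    up_name = UPSTREAM[equation]
    up = (np.asarray(sigmoid_eval(grid, sigmoids[up_name]))
          if up_name is not None else np.zeros_like(grid))
    D = np.column_stack([own ** i * up ** j for i, j in spec.terms])
    b = np.asarray(sigmoid_derivative(grid, sigmoids[equation]))
    diagnostics: dict = {}
    # flag rank deficiency from flat (zero-variance) sigmoid columns
    var = D.var(axis=0)
    flat = [i for i, (t, v) in enumerate(zip(spec.terms, var))
            if t != (0, 0) and v < 1e-14]
    if flat:
        diagnostics["rank_deficient_columns"] = flat
    return DesignSystem(D=D, b=b, lam=0.0, grid=grid, spec=spec,
                        equation=equation,
                        labels=spec.labels(equation, up_name or ""),
                        diagnostics=diagnostics)


def _admm_lasso(D: np.ndarray, b: np.ndarray, lam: float, rho: float = 1.0,
                tol: float = 1e-8, max_iter: int = 200_000):
    """Minimize ||D w - b||^2 + lam * ||w||_1 by ADMM, stopping at objective
    stationarity.

    Direct coordinate-descent and LARS solvers are unreliable at the very
    small penalties used for structure discovery on near-collinear polynomial
    libraries (stalled duality gaps / premature path termination).  ADMM with
    a cached Cholesky factor is dependable, but on a near-singular library a
    vanishing penalty admits long flat valleys whose formal optimum has
    physically meaningless exploding coefficients; the solver therefore
    terminates once the relative objective improvement over 50 iterations
    falls below ``tol``, returning the solution adjacent to the exact-fit
    (least-squares) point.
    """
    p = D.shape[1]
    w_ls, *_ = np.linalg.lstsq(D, b, rcond=None)
    thresh = lam / rho  # z-step soft-threshold scale
    wmax = float(np.max(np.abs(w_ls))) if p else 0.0
    # tiny-penalty regime: the threshold is below coefficient resolution, so
    # the lasso solution is the exact-fit (least-squares) point up to a
    # one-step shrinkage; chasing the formal optimum down the near-null
    # valley of an ill-conditioned library yields exploding coefficients
    if thresh < 1e-5 * wmax:
        z = np.sign(w_ls) * np.maximum(np.abs(w_ls) - thresh, 0.0)
        return z, 1, True
    chol = cho_factor(D.T @ D + 0.5 * rho * np.eye(p))
    Dtb = D.T @ b
    # w-step solves (2 D'D + rho I) w = 2 D'b + rho (z - u), halved below
    z = w_ls
    u = np.zeros(p)
    scale = max(wmax, 1.0)

    def objective(v):
        r = D @ v - b
        return float(r @ r + lam * np.abs(v).sum())

    obj = objective(z)
    for it in range(1, max_iter + 1):
        w = cho_solve(chol, Dtb + 0.5 * rho * (z - u))
        z_old = z
        v = w + u
        z = np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)
        u = u + w - z
        # primary stop: iterates converged
        if (np.max(np.abs(w - z)) < 1e-12 * scale
                and np.max(np.abs(z - z_old)) < 1e-12 * scale):
            return z, it, True
        # secondary stop: objective stationary (flat-valley regime)
        if it % 50 == 0:
            new_obj = objective(z)
            if (np.max(np.abs(w - z)) < 1e-8 * scale
                    and abs(obj - new_obj) <= tol * max(obj, 1e-30)):
                return z, it, True
            obj = new_obj
    return z, max_iter, False


def lasso_fit(system: DesignSystem, lam: float | None = None) -> LassoResult:
    """Minimize ||D w - b||^2 + lam * ||w||_1 over the library weights.

    Columns are scaled to unit l2 norm before the penalized fit (the penalty
    scale is otherwise meaningless) and coefficients are unscaled afterwards;
    the constant column is penalized like any other, matching the plain
    objective.  Support = indices with |w| >= 1e-6 * max|w|.
    """
    lam = system.lam if lam is None else float(lam)
    D, b = system.D, system.b
    n = D.shape[0]
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    Ds = D / norms
    if lam == 0.0:
        w_s, *_ = np.linalg.lstsq(Ds, b, rcond=None)
        n_iter = 0
    else:
        w_s, n_iter, converged = _admm_lasso(Ds, b, lam)
        if not converged:
            raise RuntimeError(
                f"Lasso solver failed to converge for equation "
                f"{system.equation} after {n_iter} iterations")
    w = w_s / norms
    resid = D @ w - b
    objective = float(resid @ resid + lam * np.abs(w).sum())
    wmax = np.max(np.abs(w)) if w.size else 0.0
    if wmax == 0.0:
        support = ()
    else:
        support = tuple(int(i) for i in np.flatnonzero(np.abs(w) >= ZERO_THRESHOLD * wmax))
        w = np.where(np.abs(w) >= ZERO_THRESHOLD * wmax, w, 0.0)  # numerical dust
    return LassoResult(weights=w, support=support,
                       support_terms=tuple(system.spec.terms[i] for i in support),
                       objective=objective, n_iter=n_iter)


def _ols_refit(system: DesignSystem, support: tuple[int, ...]) -> np.ndarray:
    w = np.zeros(system.D.shape[1])
    if support:
        sol, *_ = np.linalg.lstsq(system.D[:, list(support)], system.b, rcond=None)
        w[list(support)] = sol
    return w


def discover_model(sigmoids: dict[str, SigmoidParams], m_max: int = 4,
                   lam: float = 1e-7, grid_size: int = 301) -> DiscoveryResult:
    """Learn per-equation supports for m = 1..m_max and the consistent degree m*.

    m* is the smallest degree whose selected support, restricted to
    degree-<=m terms, is identical across every larger library up to m_max
    (for all four equations).  When m* = 2 the support weights are refit by
    OLS and packaged as CascadeParams (zeros off-support; y0 anchored at the
    amyloid sigmoid's value at s = -10).
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    supports: dict = {}
    weights: dict = {}
    systems: dict = {}
    flags: list[str] = []
    for m in range(1, m_max + 1):
        for eq in BIOMARKERS:
            spec = build_library(m, "single" if eq == "A" else "pair")
            sys_ = build_design(sigmoids, eq, spec, grid_size=grid_size)
            res = lasso_fit(sys_, lam=lam)
            supports[(m, eq)] = frozenset(res.support_terms)
            weights[(m, eq)] = res
            systems[(m, eq)] = sys_

    def restricted(m_prime: int, eq: str, m: int) -> frozenset:
        return frozenset(t for t in supports[(m_prime, eq)] if sum(t) <= m)

    m_star = None
    for m in range(1, m_max + 1):
        if all(restricted(mp, eq, m) == restricted(m, eq, m)
               for eq in BIOMARKERS for mp in range(m, m_max + 1)):
            m_star = m
            break
    if all(len(supports[(m_max, eq)]) == 0 for eq in BIOMARKERS):
        flags.append("all supports empty (over-penalized model)")

    params = None
    if m_star == 2:
        w_full = np.zeros(len(WEIGHT_NAMES))
        for eq in BIOMARKERS:
            res = weights[(2, eq)]
            w_refit = _ols_refit(systems[(2, eq)], res.support)
            sl = EQUATION_SLICES[eq]
            w_full[sl] = w_refit[: sl.stop - sl.start]
        y0 = max(float(sigmoid_eval(S_MIN, sigmoids["A"])), 1e-8)
        params = CascadeParams.from_array(w_full, y0)
    elif m_star is None:
        flags.append("no stable degree found; supports reported for all m")
    return DiscoveryResult(supports={k: tuple(sorted(v)) for k, v in supports.items()},
                           weights=weights, m_star=m_star, params=params, flags=flags)
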