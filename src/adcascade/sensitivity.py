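"""Variance-based (Sobol) global sensitivity of cascade outputs to the weights.

Inputs are the 21 population weights, varied independently and uniformly over
90-110% of their calibrated values; weights that are exactly zero have
degenerate ranges and are held fixed (their indices are identically 0).  The
default output is cognitive decline C evaluated at a DPS point s*.

Estimation uses Saltelli's pick-freeze scheme on a scrambled Sobol'
low-discrepancy design: with k free inputs and base sample size N (a power of
two), first- and total-order indices cost (k+2)*N model runs and closed
second-order indices a further k*N.  All model runs for one design are
solved in vectorized batches.  Monte-Carlo standard errors come from a
bootstrap over sample rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .model import CascadeParams, S_MAX, S_MIN, WEIGHT_NAMES, solve_batch

__all__ = ["ParamRanges", "SobolResult", "make_ranges", "sobol_indices",
           "sensitivity_over_dps", "select_personalized"]

BIOMARKER_INDEX = {"A": 0, "T": 1, "N": 2, "C": 3}


@dataclass(frozen=True)
class ParamRanges:
    """Per-input lower/upper bounds; zero-width inputs are fixed."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    y0: float | None = None   # carried along for the ODE model (not an input)

    def __post_init__(self):
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValueError("bounds must match names")
        if np.any(hi < lo):
            raise ValueError("upper bounds must be >= lower bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def free(self) -> np.ndarray:
        return (self.upper - self.lower) > 0

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n, f in zip(self.names, self.free) if f)

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


def make_ranges(w: CascadeParams, frac: float = 0.1) -> ParamRanges:
    """Boxes at (1-frac)..(1+frac) times each weight, reordered for negative
    weights; exact zeros get zero width and are excluded from sampling."""
    vals = w.as_array()
    lo = np.minimum((1.0 - frac) * vals, (1.0 + frac) * vals)
    hi = np.maximum((1.0 - frac) * vals, (1.0 + frac) * vals)
    return ParamRanges(names=WEIGHT_NAMES, lower=lo, upper=hi, y0=w.y0)


@dataclass
class SobolResult:
    """Indices for one model output (biomarker value at DPS s_star).

    Arrays are aligned with ``names`` (all inputs, fixed ones included with
    exact zeros).  ``second_closed[i, j]`` is the closed second-order index
    S_(i,j) (first-order effects of i and j plus their interaction); the pure
    interaction term is ``second_closed - S1_i - S1_j``.
    """

    names: tuple[str, ...]
    free: np.ndarray
    S1: np.ndarray
    S1_se: np.ndarray
    ST: np.ndarray
    ST_se: np.ndarray
    second_closed: np.ndarray | None
    biomarker: str
    s_star: float
    N: int
    n_evaluations: int

    def interaction(self) -> np.ndarray | None:
        if self.second_closed is None:
            return None
        inter = self.second_closed - self.S1[:, None] - self.S1[None, :]
        np.fill_diagonal(inter, 0.0)
        return inter

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.S1))


def _ode_model_factory(ranges: ParamRanges, s_points: np.ndarray, biomarker: str):
    """Default model: solve the cascade per sample, score biomarker at s_points."""
    base = ranges.midpoint()
    free = ranges.free
    col = BIOMARKER_INDEX[biomarker]

    def model(X_free: np.ndarray) -> np.ndarray:
        W = np.tile(base, (X_free.shape[0], 1))
        W[:, free] = X_free
        traj = solve_batch(W, ranges.y0, s_points)
        return traj[:, :, col]

    return model


def _saltelli_design(k: int, N: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    U = sampler.random(N)
    return U[:, :k], U[:, k:]


def _estimate(fA, fB, fAB, fABlist_axis=0):
    """First/total-order pick-freeze estimators; inputs shaped (N, G) and
    fAB (k, N, G)."""
    Y = np.concatenate([fA, fB], axis=0)
    mu = Y.mean(axis=0)
    V = Y.var(axis=0)
    V = np.where(V > 1e-300, V, np.inf)  # degenerate output -> zero indices
    S1 = ((fB - mu) * (fAB - fA)).mean(axis=1) / V
    ST = 0.5 * ((fA - fAB) ** 2).mean(axis=1) / V
    return S1, ST, V, mu


def _sobol_core(ranges: ParamRanges, s_points: np.ndarray, biomarker: str,
                N: int, seed: int, second_order: bool, model,
                n_boot: int = 64):
    if N < 2 or (N & (N - 1)) != 0:
        raise ValueError(f"base sample size N must be a power of two, got {N}")
    free = ranges.free
    k = int(free.sum())
    if k == 0:
        raise ValueError("no free parameters to analyze")
    lo, hi = ranges.lower[free], ranges.upper[free]
    UA, UB = _saltelli_design(k, N, seed)
    A = lo + UA * (hi - lo)
    B = lo + UB * (hi - lo)
    blocks = [A, B]
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    if second_order:
        for i in range(k):
            BAi = B.copy()
            BAi[:, i] = A[:, i]
            blocks.append(BAi)
    X = np.vstack(blocks)
    out = np.asarray(model(X), dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    G = out.shape[1]
    fA, fB = out[:N], out[N:2 * N]
    fAB = out[2 * N:(2 + k) * N].reshape(k, N, G)
    fBA = out[(2 + k) * N:].reshape(k, N, G) if second_order else None

    S1, ST, V, mu = _estimate(fA, fB, fAB)

    second = None
    if second_order:
        second = np.zeros((k, k, G))
        prodAB = fA * fB  # (N, G)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                closed = ((fBA[i] - mu) * (fAB[j] - mu) - (fA - mu) * (fB - mu)).mean(axis=0) / V
                second[i, j] = closed
        second = 0.5 * (second + second.transpose(1, 0, 2))  # symmetrize estimator noise

    # bootstrap standard errors over sample rows
    rng = np.random.default_rng(seed + 1)
    s1_bs = np.empty((n_boot, k, G))
    st_bs = np.empty((n_boot, k, G))
    for b in range(n_boot):
        idx = rng.integers(0, N, N)
        s1b, stb, _, _ = _estimate(fA[idx], fB[idx], fAB[:, idx, :])
        s1_bs[b], st_bs[b] = s1b, stb
    S1_se = s1_bs.std(axis=0, ddof=1)
    ST_se = st_bs.std(axis=0, ddof=1)

    n_evals = X.shape[0]
    results = []
    free_idx = np.flatnonzero(free)
    n_all = len(ranges.names)
    for g, s_star in enumerate(np.atleast_1d(s_points)):
        S1_full = np.zeros(n_all); S1_full[free_idx] = S1[:, g]
        ST_full = np.zeros(n_all); ST_full[free_idx] = ST[:, g]
        S1se_full = np.zeros(n_all); S1se_full[free_idx] = S1_se[:, g]
        STse_full = np.zeros(n_all); STse_full[free_idx] = ST_se[:, g]
        sec_full = None
        if second is not None:
            sec_full = np.zeros((n_all, n_all))
            sec_full[np.ix_(free_idx, free_idx)] = second[:, :, g]
        results.append(SobolResult(
            names=ranges.names, free=free.copy(), S1=S1_full, S1_se=S1se_full,
            ST=ST_full, ST_se=STse_full, second_closed=sec_full,
            biomarker=biomarker, s_star=float(s_star), N=N, n_evaluations=n_evals))
    return results


def sobol_indices(ranges: ParamRanges, output: tuple[str, float] = ("C", 0.0),
                  N: int = 2 ** 13, seed: int = 0, second_order: bool = False,
                  model=None) -> SobolResult:
    """Sobol indices of one model output.

    ``output`` is (biomarker, s*) with s* in (-10, 20].  ``model`` is a test
    hook: a callable mapping an (n, k_free) matrix of free-input samples to
    (n,) outputs, replacing the ODE solve.
    """
    biomarker, s_star = output
    if not (S_MIN < s_star <= S_MAX):
        raise ValueError(f"s* must be in ({S_MIN}, {S_MAX}], got {s_star}")
    s_points = np.array([float(s_star)])
    if model is None:
        model = _ode_model_factory(ranges, s_points, biomarker)
    return _sobol_core(ranges, s_points, biomarker, N, seed, second_order, model)[0]


def sensitivity_over_dps(ranges: ParamRanges, s_grid, N: int = 2 ** 13,
                         seed: int = 0, biomarker: str = "C",
                         second_order: bool = False, model=None) -> list[SobolResult]:
    """Index dynamics over DPS: one shared Saltelli design, each ODE solve
    scored at every grid point."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= S_MIN) or np.any(s_grid > S_MAX):
        raise ValueError(f"s_grid must lie in ({S_MIN}, {S_MAX}]")
    if model is None:
        model = _ode_model_factory(ranges, s_grid, biomarker)
    return _sobol_core(ranges, s_grid, biomarker, N, seed, second_order, model)


def select_personalized(result: SobolResult, tol: float = 0.01) -> list[str]:
    """Free parameters with first-order index >= tol, descending by index.

    Small negative estimates (estimator noise) are clamped to zero for the
    comparison only.
    """
    s1 = np.clip(result.S1, 0.0, None)
    chosen = [(result.names[i], s1[i]) for i in np.flatnonzero(result.free)
              if s1[i] >= tol]
    chosen.sort(key=lambda t: -t[1])
    return [n for n, _ in chosen]
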