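"""Alternating calibration of population weights and per-subject DPS warps.

One outer round alternates (i) per-biomarker nonlinear least squares of the
ODE weights against all observations placed at their current DPS values,
(ii) per-biomarker variance weights sigma_k, and (iii) per-subject fits of
the affine warp (alpha_i, beta_i) against the current model, weighted by
1/sigma_k.  Blocks are fitted in cascade order A -> T -> N -> C so each
equation sees up-to-date upstream dynamics.  The warp/trajectory gauge is
anchored by the fixed initial condition at s = -10 and the box constraints
alpha in (0, 4], s in [-10, 20].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cohort import CohortTable, DpsParams
from .model import (BIOMARKERS, CascadeParams, EQUATION_SLICES, S_MAX, S_MIN,
                    SolverBlowupError, WEIGHT_NAMES, _dense_solution,
                    solve_batch, solve_model)

__all__ = [
    "CalibrationState",
    "BootstrapBand",
    "DegenerateDesignError",
    "compute_sigma",
    "fit_weights",
    "fit_dps",
    "calibrate",
    "refit_weights_fixed_dps",
    "bootstrap_band",
    "default_w_init",
]

ALPHA_MIN, ALPHA_MAX = 1e-3, 4.0


class DegenerateDesignError(ValueError):
    """Cohort too small for the variance-weight denominator."""


@dataclass
class CalibrationState:
    w: CascadeParams
    dps: DpsParams
    sigma: dict[str, float]
    objective: float            # total unweighted residual sum of squares
    iteration: int
    history: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class BootstrapBand:
    s_grid: np.ndarray
    lower: np.ndarray   # (grid, 4)
    upper: np.ndarray
    coverage: float
    n_replicates: int


def compute_sigma(residuals, n_obs: int, n_subjects: int) -> float:
    """Variance weight sigma_k = RSS_k / | |I_k| - 2I - 4 | (literal form).

    The absolute value in the denominator is taken as printed; a zero
    denominator means the cohort is too small to support the correction and
    raises.  A perfect fit returns sigma = 0, which downstream DPS weighting
    treats as a switch to unweighted residuals.
    """
    r = np.asarray(residuals, dtype=float)
    denom = abs(int(n_obs) - 2 * int(n_subjects) - 4)
    if denom == 0:
        raise DegenerateDesignError(
            f"|I_k| - 2I - 4 = 0 with |I_k|={n_obs}, I={n_subjects}: "
            "cohort too small for variance weighting")
    return float(r @ r / denom)


def default_w_init(y0: float = 1e-4) -> CascadeParams:
    """Generic rising-cascade initialization: logistic self-dynamics per
    variable plus moderate upstream forcing."""
    w = {}
    for eq in BIOMARKERS:
        w[f"w_{eq}0"] = 0.0
        w[f"w_{eq}1"] = 1.0
        w[f"w_{eq}2"] = -1.0
        if eq != "A":
            w[f"w_{eq}3"] = 0.5
            w[f"w_{eq}4"] = 0.5
            w[f"w_{eq}5"] = -0.5
    return CascadeParams.from_dict({**w, "y0": y0})


# ---------------------------------------------------------------------------
# weight fitting
# ---------------------------------------------------------------------------

def _observations_by_biomarker(cohort: CohortTable, dps: DpsParams) -> dict:
    """k -> (s values, y values) with every DPS checked into [-10, 20]."""
    data = {}
    for k in BIOMARKERS:
        obs = cohort.observations(k)
        s = np.concatenate([
            dps.s(sid, grp["age_years"].to_numpy())
            for sid, grp in obs.groupby("subject_id")
        ]) if len(obs) else np.empty(0)
        y = np.concatenate([
            grp["value"].to_numpy() for _, grp in obs.groupby("subject_id")
        ]) if len(obs) else np.empty(0)
        if s.size and (s.min() < S_MIN - 1e-6 or s.max() > S_MAX + 1e-6):
            raise ValueError(f"observation DPS outside [{S_MIN}, {S_MAX}] for biomarker {k}")
        data[k] = (np.clip(s, S_MIN, S_MAX), y)
    return data


def _collocation_inits(k: str, s_obs: np.ndarray, y_obs: np.ndarray,
                       current: CascadeParams) -> list[np.ndarray]:
    """Linearized starting guesses for one equation block.

    Fits a sigmoid to the block's own (s, y) data and takes its analytic
    derivative as the regression target.  Because a sigmoid's derivative is
    exactly quadratic in the sigmoid itself, an own-terms-only least-squares
    fit is a strong spurious attractor; the candidates therefore profile
    along that degeneracy, assigning an own-terms fraction of 1, 1/2 and 0
    with the upstream columns (from the current ODE solution, already updated
    in cascade order) fitted to the remainder.
    """
    from .sigmoid import fit_sigmoid, sigmoid_derivative, sigmoid_eval
    if s_obs.size < 6 or np.ptp(s_obs) < 1e-6:
        return []
    try:
        fit = fit_sigmoid((s_obs, y_obs))
    except Exception:
        return []
    if not (fit.converged or fit.degenerate):
        return []
    grid = np.linspace(s_obs.min(), s_obs.max(), 101)
    own = np.asarray(sigmoid_eval(grid, fit.params))
    b = np.asarray(sigmoid_derivative(grid, fit.params))
    D_own = np.column_stack([np.ones_like(own), own, own ** 2])
    c_own, *_ = np.linalg.lstsq(D_own, b, rcond=None)
    if not np.all(np.isfinite(c_own)):
        return []
    if k == "A":
        return [c_own]
    up_idx = BIOMARKERS.index({"T": "A", "N": "T", "C": "N"}[k])
    # solve only up to the upstream equation (later blocks may hold unfitted
    # weights that would blow up the integration)
    wt = current.as_array().copy()
    for kd in BIOMARKERS[up_idx + 1:]:
        wt[EQUATION_SLICES[kd]] = 0.0
    try:
        up = _dense_solution(CascadeParams.from_array(wt, current.y0))(grid)[up_idx]
    except Exception:
        return [np.concatenate([c_own, np.zeros(3)])]
    D_up = np.column_stack([up, up ** 2, up * own])
    out = []
    for phi in (1.0, 0.75, 0.5, 0.25, 0.0):
        r = b - phi * (D_own @ c_own)
        c_up, *_ = np.linalg.lstsq(D_up, r, rcond=None)
        cand = np.concatenate([phi * c_own, c_up])
        if np.all(np.isfinite(cand)):
            out.append(cand)
    return out


def _fit_weights_arrays(data: dict, w_init: CascadeParams,
                        fit_y0: bool = True, multi_start: bool = True,
                        effort: int = 150, ftol: float = 1e-10,
                        xtol: float = 1e-10) -> tuple[CascadeParams, list[str]]:
    """Cascade-ordered block LM fits against (s, y) arrays per biomarker."""
    current = w_init
    flags: list[str] = []
    for k in BIOMARKERS:
        s_obs, y_obs = data[k]
        sl = EQUATION_SLICES[k]
        block_names = [f"w_{k}{j}" for j in range(sl.stop - sl.start)]
        n_par = len(block_names) + (1 if (k == "A" and fit_y0) else 0)
        if y_obs.size < n_par:
            flags.append(f"block {k} underdetermined ({y_obs.size} obs, {n_par} params); kept init")
            continue
        kidx = BIOMARKERS.index(k)
        s_uniq, s_pos = np.unique(s_obs, return_inverse=True)
        fit_y0_here = k == "A" and fit_y0
        # biomarker k does not depend on downstream equations; zeroing their
        # blocks keeps not-yet-fitted downstream weights from blowing up the
        # stacked integration
        template = current.as_array().copy()
        for kd in BIOMARKERS[kidx + 1:]:
            template[EQUATION_SLICES[kd]] = 0.0

        def to_rows(X):
            """(n, n_par) block-parameter rows -> (W (n,21), y0 (n,))."""
            X = np.atleast_2d(X)
            W = np.tile(template, (X.shape[0], 1))
            if fit_y0_here:
                W[:, sl] = X[:, :-1]
                y0 = np.exp(np.clip(X[:, -1], -30.0, 1.0))
            else:
                W[:, sl] = X
                y0 = np.full(X.shape[0], current.y0)
            return W, y0

        # integrate to the end of the model domain even when observations
        # stop earlier: weights that blow up anywhere in [-10, 20] must be
        # penalized, or later full-domain solves would fail
        s_solve = (np.append(s_uniq, S_MAX) if s_uniq[-1] < S_MAX else s_uniq)

        def predict_many(X):
            """Model values at the observations for many parameter rows; one
            stacked batch solve amortizes the integrator overhead.  Fitting
            uses a slightly looser integration tolerance than reporting
            solves; the induced parameter error is orders of magnitude below
            the recovery tolerances."""
            W, y0 = to_rows(X)
            traj = solve_batch(W, y0, s_solve, rtol=1e-7, atol=1e-9)
            return traj[:, s_pos, kidx]

        def residual(x):
            if not np.all(np.isfinite(x)):
                return np.full(y_obs.size, 1e3)
            try:
                return predict_many(x[None, :])[0] - y_obs
            except SolverBlowupError as exc:
                # sloped fill: the later the blow-up, the smaller the value,
                # so the optimizer has a gradient back toward feasibility
                s_fail = exc.s if exc.s is not None else S_MIN
                return np.full(y_obs.size, 30.0 + (S_MAX - s_fail))
            except Exception:
                return np.full(y_obs.size, 1e3)

        def jacobian(x, f0=None):
            # central differences, batched into one stacked solve; steps well
            # above the integrator's noise floor
            h = 1e-6 * np.maximum(np.abs(x), 1.0)
            eye = np.eye(x.size)
            Xp = np.vstack([x + h[j] * eye[j] for j in range(x.size)])
            Xm = np.vstack([x - h[j] * eye[j] for j in range(x.size)])
            try:
                F = predict_many(np.vstack([Xp, Xm]))
            except Exception:
                # rare blow-up on a perturbed row: slow per-column fallback
                cols = []
                for j in range(x.size):
                    cols.append((residual(x + h[j] * eye[j])
                                 - residual(x - h[j] * eye[j])) / (2 * h[j]))
                return np.column_stack(cols)
            n = x.size
            return (F[:n] - F[n:]).T / (2 * h)

        # candidate starts: current weights, plus collocation-based guesses
        # profiling the own/upstream degeneracy (first pass only; later
        # passes warm-start from the previous round's weights)
        starts = [list(current.as_array()[sl])]
        if multi_start:
            starts += [list(c) for c in _collocation_inits(k, s_obs, y_obs, current)]
        if k == "A" and fit_y0:
            log_y0 = np.log(max(current.y0, 1e-8))
            starts = [x0 + [log_y0] for x0 in starts]
        # Table-1-scale weights are O(1); the box keeps the search out of the
        # blow-up regime and away from degenerate cancelling-coefficient fits
        lo = np.full(n_par, -30.0)
        hi = np.full(n_par, 30.0)
        if k == "A" and fit_y0:
            lo[-1], hi[-1] = -30.0, 1.0  # log y0
        starts = [np.clip(np.asarray(x0, float), lo, hi) for x0 in starts]
        best = None
        # cheap exploration passes over the starts, then one full-precision
        # polish from the best point found
        explore_nfev = 30 * (n_par + 1) if len(starts) > 1 else effort * (n_par + 1)
        for x0 in starts:
            res = least_squares(residual, x0, jac=jacobian,
                                method="trf", bounds=(lo, hi), x_scale="jac",
                                xtol=xtol, ftol=ftol, max_nfev=explore_nfev)
            if best is None or res.cost < best.cost:
                best = res
        if len(starts) > 1:
            res = least_squares(residual, best.x, jac=jacobian,
                                method="trf", bounds=(lo, hi), x_scale="jac",
                                xtol=xtol, ftol=ftol, max_nfev=effort * (n_par + 1))
            if res.cost > best.cost:
                res = best
        else:
            res = best
        w = np.array(current.as_array())
        if k == "A" and fit_y0:
            w[sl] = res.x[:-1]
            y0_new = float(np.clip(np.exp(np.clip(res.x[-1], -30.0, 1.0)), 1e-8, 1.0))
            current = CascadeParams.from_array(w, y0_new)
        else:
            w[sl] = res.x
            current = CascadeParams.from_array(w, current.y0)
        if not res.success:
            flags.append(f"block {k} solver stopped without convergence flag")
    return current, flags


def fit_weights(cohort: CohortTable, dps: DpsParams, w_init: CascadeParams,
                fit_y0: bool = True, multi_start: bool = True,
                effort: int = 150) -> CascadeParams:
    """One pass of per-biomarker weight calibration with the DPS warps fixed.

    y0 is fitted jointly with the amyloid block (log-parameterized to stay
    positive).  Underdetermined blocks are left at their initial values (the
    condition is recorded on the returned parameters' fit flags via
    ``fit_weights_with_flags``).
    """
    params, _ = fit_weights_with_flags(cohort, dps, w_init, fit_y0=fit_y0,
                                       multi_start=multi_start, effort=effort)
    return params


def fit_weights_with_flags(cohort: CohortTable, dps: DpsParams, w_init: CascadeParams,
                           fit_y0: bool = True, multi_start: bool = True,
                           effort: int = 150, ftol: float = 1e-10,
                           xtol: float = 1e-10) -> tuple[CascadeParams, list[str]]:
    data = _observations_by_biomarker(cohort, dps)
    return _fit_weights_arrays(data, w_init, fit_y0=fit_y0,
                               multi_start=multi_start, effort=effort,
                               ftol=ftol, xtol=xtol)


def refit_weights_fixed_dps(cohort: CohortTable, dps: DpsParams,
                            w_init: CascadeParams, fit_y0: bool = True) -> CascadeParams:
    """Refit the 21 weights on a cohort subset with the DPS warps held fixed
    (the subset-refit step, e.g. LMCI+AD only)."""
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort subset")
    missing = [s for s in cohort.subjects if s not in dps]
    if missing:
        raise ValueError(f"no DPS parameters for subjects: {missing[:5]}")
    return fit_weights(cohort, dps, w_init, fit_y0=fit_y0)


# ---------------------------------------------------------------------------
# DPS fitting
# ---------------------------------------------------------------------------

def _model_tables(w: CascadeParams, n: int = 1501):
    s_tab = np.linspace(S_MIN, S_MAX, n)
    sol = _dense_solution(w)
    return s_tab, sol(s_tab)  # (4, n)


def fit_dps(ages, values, biomarkers, w: CascadeParams, sigma: dict[str, float],
            start: tuple[float, float] | None = None) -> tuple[float, float, bool]:
    """Fit one subject's warp (alpha, beta) by weighted least squares.

    ``ages``, ``values``, ``biomarkers`` are the subject's observations.
    sigma_k weight the residuals by 1/sigma_k; any non-positive sigma
    switches to unweighted.  The search combines a coarse grid over
    (alpha, baseline DPS) with a local bounded refinement; alpha is
    constrained to (0, 4] and beta so every visit's DPS stays in [-10, 20]
    (soft penalty during refinement, clamped and flagged afterwards).

    Returns (alpha, beta, boundary_flag).
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    ks = np.asarray(biomarkers)
    if t.size < 2:
        raise ValueError("subject needs >= 2 observations to fit a warp")
    if any(sigma.get(k, 1.0) <= 0 or not np.isfinite(sigma.get(k, 1.0)) for k in BIOMARKERS):
        wts = np.ones(t.size)
    else:
        wts = np.array([1.0 / sigma[k] for k in ks])
    kidx = np.array([BIOMARKERS.index(k) for k in ks])
    s_tab, f_tab = _model_tables(w)

    def objective(alpha, beta):
        s = np.clip(alpha * t + beta, S_MIN, S_MAX)
        pred = np.array([np.interp(si, s_tab, f_tab[ki]) for si, ki in zip(s, kidx)])
        return float(np.sum(wts * (y - pred) ** 2))

    t0, t1 = t.min(), t.max()
    cands = []
    if start is not None:
        cands.append(tuple(start))
    for alpha in np.geomspace(0.1, ALPHA_MAX, 10):
        span = alpha * (t1 - t0)
        if span > S_MAX - S_MIN:
            continue
        for s_base in np.linspace(S_MIN, S_MAX - span, 25):
            cands.append((alpha, s_base - alpha * t0))
    best = min(cands, key=lambda ab: objective(*ab))

    def resid(x):
        alpha, beta = x
        s = alpha * t + beta
        s_cl = np.clip(s, S_MIN, S_MAX)
        pred = np.array([np.interp(si, s_tab, f_tab[ki]) for si, ki in zip(s_cl, kidx)])
        pen = 10.0 * (np.maximum(0.0, s - S_MAX) + np.maximum(0.0, S_MIN - s))
        return np.concatenate([np.sqrt(wts) * (y - pred), pen])

    res = least_squares(resid, np.asarray(best, float),
                        bounds=([ALPHA_MIN, -S_MAX - ALPHA_MAX * t1], [ALPHA_MAX, S_MAX]),
                        method="trf", xtol=1e-12, ftol=1e-12)
    alpha, beta = (res.x if objective(*res.x) <= objective(*best) else np.asarray(best))
    # clamp beta into the feasible band for this alpha
    lo, hi = S_MIN - alpha * t0, S_MAX - alpha * t1
    boundary = False
    if lo > hi:  # warp cannot place all visits inside the domain
        boundary = True
        beta = 0.5 * (lo + hi)
    elif beta < lo or beta > hi:
        boundary = True
        beta = float(np.clip(beta, lo, hi))
    return float(alpha), float(beta), boundary


def _refit_weights_joint(data: dict, w_init: CascadeParams,
                         max_nfev: int = 60, ftol: float = 1e-6) -> CascadeParams:
    """One trust-region fit of all 21 weights + y0 against (s, y) arrays.

    Used for warm-started refits (bootstrap replicates) where the
    block-sequential pass would redundantly re-integrate the cascade; a
    joint fit with one batched central-difference Jacobian per iteration is
    several times cheaper at equal accuracy.
    """
    s_cat = np.concatenate([data[k][0] for k in BIOMARKERS])
    y_cat = np.concatenate([data[k][1] for k in BIOMARKERS])
    kidx = np.concatenate([np.full(data[k][0].size, BIOMARKERS.index(k))
                           for k in BIOMARKERS])
    s_uniq, s_pos = np.unique(s_cat, return_inverse=True)
    s_solve = np.append(s_uniq, S_MAX) if s_uniq[-1] < S_MAX else s_uniq
    obs_sel = (np.arange(s_cat.size), kidx)

    def predict_many(X):
        X = np.atleast_2d(X)
        W = X[:, :-1]
        y0 = np.exp(np.clip(X[:, -1], -30.0, 1.0))
        traj = solve_batch(W, y0, s_solve, rtol=1e-7, atol=1e-9)
        return traj[:, s_pos, :][:, obs_sel[0], obs_sel[1]]

    def residual(x):
        try:
            return predict_many(x[None, :])[0] - y_cat
        except SolverBlowupError as exc:
            s_fail = exc.s if exc.s is not None else S_MIN
            return np.full(y_cat.size, 30.0 + (S_MAX - s_fail))
        except Exception:
            return np.full(y_cat.size, 1e3)

    def jacobian(x):
        h = 1e-6 * np.maximum(np.abs(x), 1.0)
        n = x.size
        try:
            F = predict_many(np.vstack([x + np.diag(h), x - np.diag(h)]))
        except Exception:
            base = residual(x)
            eye = np.eye(n)
            return np.column_stack([(residual(x + h[j] * eye[j]) - base) / h[j]
                                    for j in range(n)])
        return (F[:n] - F[n:]).T / (2 * h)

    x0 = np.append(w_init.as_array(), np.log(max(w_init.y0, 1e-8)))
    lo = np.append(np.full(21, -30.0), -30.0)
    hi = np.append(np.full(21, 30.0), 1.0)
    res = least_squares(residual, np.clip(x0, lo, hi), jac=jacobian,
                        method="trf", bounds=(lo, hi), x_scale="jac",
                        ftol=ftol, xtol=1e-8, max_nfev=max_nfev)
    return CascadeParams.from_array(
        res.x[:-1], float(np.clip(np.exp(np.clip(res.x[-1], -30.0, 1.0)), 1e-8, 1.0)))


# ---------------------------------------------------------------------------
# joint refinement
# ---------------------------------------------------------------------------

def joint_refine(cohort: CohortTable, w: CascadeParams, dps: DpsParams,
                 max_nfev: int = 80) -> tuple[CascadeParams, DpsParams]:
    """Simultaneous least squares over all weights, y0 and every warp.

    Block alternation zigzags slowly along the strongly coupled
    weights-vs-warps valley; a final joint trust-region pass converges it.
    The Jacobian is finite-differenced with a sparsity pattern (each
    observation depends on the weights plus only its own subject's two warp
    parameters), so scipy groups independent columns into few evaluations.
    """
    from scipy.sparse import lil_matrix

    subjects = cohort.subjects
    n_w = len(WEIGHT_NAMES)
    idx_alpha = {sid: n_w + 1 + 2 * i for i, sid in enumerate(subjects)}
    rows = cohort.df
    ages = rows["age_years"].to_numpy()
    values = rows["value"].to_numpy()
    kidx = np.array([BIOMARKERS.index(k) for k in rows["biomarker"]])
    sub_codes = rows["subject_id"].to_numpy()
    s_tab = np.linspace(S_MIN, S_MAX, 3001)

    x0 = np.concatenate([
        w.as_array(), [np.log(max(w.y0, 1e-8))],
        np.array([[dps.alpha[sid], dps.beta[sid]] for sid in subjects]).ravel(),
    ])
    t_max = ages.max()
    lo = np.concatenate([np.full(n_w, -30.0), [-30.0],
                         np.tile([ALPHA_MIN, S_MIN - ALPHA_MAX * t_max], len(subjects))])
    hi = np.concatenate([np.full(n_w, 30.0), [1.0],
                         np.tile([ALPHA_MAX, S_MAX], len(subjects))])

    alpha_col = np.array([idx_alpha[sid] for sid in sub_codes])

    def unpack(x):
        params = CascadeParams.from_array(
            x[:n_w], float(np.exp(np.clip(x[n_w], -30.0, 1.0))))
        a = x[alpha_col]
        b = x[alpha_col + 1]
        return params, a, b

    def residual(x):
        params, a, b = unpack(x)
        s = a * ages + b
        s_cl = np.clip(s, S_MIN, S_MAX)
        try:
            f_tab = _dense_solution(params)(s_tab)
        except Exception:
            return np.full(values.size, 1e3)
        pred = np.empty(values.size)
        for ki in range(4):
            m = kidx == ki
            pred[m] = np.interp(s_cl[m], s_tab, f_tab[ki])
        pen = 3.0 * (np.maximum(0.0, s - S_MAX) + np.maximum(0.0, S_MIN - s))
        return (values - pred) + pen

    sparsity = lil_matrix((values.size, x0.size), dtype=int)
    sparsity[:, :n_w + 1] = 1
    for r in range(values.size):
        sparsity[r, alpha_col[r]] = 1
        sparsity[r, alpha_col[r] + 1] = 1

    res = least_squares(residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                        method="trf", jac_sparsity=sparsity, diff_step=1e-6,
                        x_scale="jac", xtol=1e-12, ftol=1e-12, max_nfev=max_nfev)
    params, a, b = unpack(res.x)
    # clamp each warp back into the domain-feasible band (the domain
    # constraint is only a soft penalty during the trust-region pass)
    alpha_out, beta_out = {}, {}
    for sid in subjects:
        av = float(res.x[idx_alpha[sid]])
        bv = float(res.x[idx_alpha[sid] + 1])
        t_sub = rows.loc[sub_codes == sid, "age_years"]
        lo_b, hi_b = S_MIN - av * t_sub.min(), S_MAX - av * t_sub.max()
        if lo_b <= hi_b:
            bv = float(np.clip(bv, lo_b, hi_b))
        alpha_out[sid], beta_out[sid] = av, bv
    return params, DpsParams(alpha=alpha_out, beta=beta_out)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def _severity_dps_init(cohort: CohortTable, rng: np.random.Generator) -> DpsParams:
    """Severity-ranked warp initialization with seeded jitter.

    Subjects are ranked by their mean normalized biomarker level (a crude
    severity score) and their baseline DPS spread over [-8, 12] in rank
    order; progression rates start near 1 DPS/year.  Starting with the
    cohort roughly ordered along disease time lets the alternation converge
    in a handful of rounds, where a fully random placement leaves many
    subjects in wrong local alignments.
    """
    sev = {sid: float(cohort.subject(sid)["value"].mean()) for sid in cohort.subjects}
    order = sorted(sev, key=sev.get)
    n = len(order)
    alpha, beta = {}, {}
    for rank, sid in enumerate(order):
        s_base = -8.0 + 20.0 * (rank / max(n - 1, 1)) + rng.normal(0.0, 0.5)
        a = float(np.clip(rng.uniform(0.8, 1.2), ALPHA_MIN, ALPHA_MAX))
        ages = cohort.subject(sid)["age_years"].to_numpy()
        lo, hi = S_MIN - a * ages.min(), S_MAX - a * ages.max()
        b = float(np.clip(s_base - a * ages.min(), lo, hi)) if lo <= hi else 0.5 * (lo + hi)
        alpha[sid], beta[sid] = a, b
    return DpsParams(alpha=alpha, beta=beta)


def _random_dps_init(cohort: CohortTable, rng: np.random.Generator) -> DpsParams:
    """alpha ~ U(0, 4); beta uniform over the band keeping all visits' DPS
    inside [-10, 20]."""
    alpha, beta = {}, {}
    for sid in cohort.subjects:
        ages = cohort.subject(sid)["age_years"].to_numpy()
        t0, t1 = ages.min(), ages.max()
        for _ in range(100):
            a = rng.uniform(ALPHA_MIN, ALPHA_MAX)
            lo, hi = S_MIN - a * t0, S_MAX - a * t1
            if lo <= hi:
                alpha[sid], beta[sid] = a, rng.uniform(lo, hi)
                break
        else:  # visit span too wide for any alpha drawn; use smallest rate
            a = ALPHA_MIN
            alpha[sid], beta[sid] = a, S_MIN - a * t0
    return DpsParams(alpha=alpha, beta=beta)


def _total_rss(cohort: CohortTable, dps: DpsParams,
               w: CascadeParams) -> tuple[float, dict, dict]:
    data = _observations_by_biomarker(cohort, dps)
    try:
        sol = _dense_solution(w)
    except SolverBlowupError:
        # infeasible weights (blow-up inside the domain): infinite objective
        # so monotone-acceptance guards reject this configuration
        return np.inf, {k: np.inf for k in BIOMARKERS}, \
            {k: np.empty(0) for k in BIOMARKERS}
    total, rss_k, resid_k = 0.0, {}, {}
    for k in BIOMARKERS:
        s_obs, y_obs = data[k]
        r = y_obs - sol(s_obs)[BIOMARKERS.index(k)] if y_obs.size else np.empty(0)
        resid_k[k] = r
        rss_k[k] = float(r @ r)
        total += rss_k[k]
    return total, rss_k, resid_k


def calibrate(cohort: CohortTable, init: CalibrationState | None = None,
              L: int = 10, seed: int = 0, rel_tol: float = 1e-6,
              fit_y0: bool = True, polish: bool = True,
              dps_init: str = "severity",
              multi_start: bool = True) -> CalibrationState:
    """Alternate weight fits, variance weights and DPS fits for L rounds.

    Without ``init``, DPS warps start from the seeded severity-ranked
    placement (``dps_init='severity'``; ``'random'`` draws alpha uniform in
    (0, 4] and beta uniform over the feasible band) and weights at a generic
    rising-cascade guess.  Stops early when the relative change of the total
    residual sum of squares drops below ``rel_tol``.  With ``polish`` a
    joint weights+warps trust-region pass finishes the fit (the alternation
    converges slowly along the coupled valley).  The objective history
    records the unweighted total RSS after each completed round, and after
    the polish.
    """
    rng = np.random.default_rng(seed)
    if init is None:
        w = default_w_init()
        dps = (_severity_dps_init(cohort, rng) if dps_init == "severity"
               else _random_dps_init(cohort, rng))
        sigma = {k: 1.0 for k in BIOMARKERS}
    else:
        w, dps, sigma = init.w, init.dps, dict(init.sigma)
    history: list[float] = []
    flags: list[str] = []
    n_subj = cohort.n_subjects
    obj = np.inf
    it = 0
    for l in range(1, L + 1):
        it = l
        try:
            # multi-start exploration periodically (alignment improves over
            # rounds, letting blocks escape early local minima); light warm
            # refinements in between
            redo = multi_start and (l - 1) % 4 == 0
            if not np.isfinite(obj):
                obj, _, _ = _total_rss(cohort, dps, w)
            # intermediate rounds do not need high-precision weight fits:
            # the joint polish (or final round) supplies the precision
            w_new, fflags = fit_weights_with_flags(
                cohort, dps, w, fit_y0=fit_y0, multi_start=redo,
                effort=150 if (redo or l == L) else 25,
                ftol=1e-10 if l == L else 1e-8)
            flags.extend(f"round {l}: {f}" for f in fflags)
            # monotone acceptance: the per-block fits optimize their own
            # biomarker's residuals, which can raise the total through the
            # upstream coupling -- keep the better configuration
            obj_w, _, resid_k = _total_rss(cohort, dps, w_new)
            if obj_w <= obj:
                w = w_new
            else:
                flags.append(f"round {l}: weight sweep reverted (objective)")
                obj_w, _, resid_k = obj, *_total_rss(cohort, dps, w)[1:]
            sigma = {}
            for k in BIOMARKERS:
                n_obs = len(cohort.observations(k))
                sigma[k] = (compute_sigma(resid_k[k], n_obs, n_subj)
                            if n_obs else 0.0)
            dps_new_a, dps_new_b = {}, {}
            for sid in cohort.subjects:
                sub = cohort.subject(sid)
                a, b, flagged = fit_dps(sub["age_years"].to_numpy(),
                                        sub["value"].to_numpy(),
                                        sub["biomarker"].to_numpy(), w, sigma,
                                        start=(dps.alpha[sid], dps.beta[sid]))
                if flagged:
                    flags.append(f"round {l}: subject {sid} warp at domain boundary")
                dps_new_a[sid], dps_new_b[sid] = a, b
            dps_new = DpsParams(alpha=dps_new_a, beta=dps_new_b)
            # same acceptance guard for the warp step: it minimizes the
            # 1/sigma_k-weighted objective, not the monitored unweighted one
            obj_d, _, _ = _total_rss(cohort, dps_new, w)
            if obj_d <= obj_w:
                dps = dps_new
            else:
                flags.append(f"round {l}: warp sweep reverted (objective)")
                obj_d = obj_w
        except (DegenerateDesignError, ValueError) as exc:
            raise type(exc)(f"calibration round {l}: {exc}") from exc
        new_obj = obj_d
        history.append(new_obj)
        if np.isfinite(obj) and obj > 0 and abs(obj - new_obj) / obj < rel_tol:
            obj = new_obj
            break
        obj = new_obj
    if L == 0:
        obj, _, _ = _total_rss(cohort, dps, w)
    elif polish:
        w_p, dps_p = joint_refine(cohort, w, dps)
        obj_p, _, resid_k = _total_rss(cohort, dps_p, w_p)
        if obj_p <= obj:  # guard against the post-polish feasibility clamp
            w, dps, obj = w_p, dps_p, obj_p
            for k in BIOMARKERS:
                n_obs = len(cohort.observations(k))
                sigma[k] = compute_sigma(resid_k[k], n_obs, n_subj) if n_obs else 0.0
        else:
            flags.append("polish reverted (objective)")
        history.append(obj)
    return CalibrationState(w=w, dps=dps, sigma=sigma, objective=float(obj),
                            iteration=it, history=history, flags=flags)


# ---------------------------------------------------------------------------
# residual bootstrap band
# ---------------------------------------------------------------------------

def bootstrap_band(cohort: CohortTable, state: CalibrationState, B: int = 200,
                   coverage: float = 0.95, seed: int = 0,
                   s_grid: np.ndarray | None = None,
                   effort: int = 40) -> BootstrapBand:
    """Pointwise residual-bootstrap interval around the calibrated trajectory.

    Residuals are resampled with replacement within each biomarker, added to
    the fitted values, and the weights refit (DPS fixed, warm-started at the
    calibrated weights); the pointwise ``coverage`` percentile interval over
    the B resolved trajectories forms the band.
    """
    if B < 20:
        raise ValueError("B must be >= 20 for a meaningful interval")
    rng = np.random.default_rng(seed)
    if s_grid is None:
        s_grid = np.linspace(S_MIN, S_MAX, 301)
    data = _observations_by_biomarker(cohort, state.dps)
    sol = _dense_solution(state.w)
    fitted, resid = {}, {}
    for k in BIOMARKERS:
        s_obs, y_obs = data[k]
        f = sol(s_obs)[BIOMARKERS.index(k)] if y_obs.size else np.empty(0)
        fitted[k] = f
        resid[k] = y_obs - f
    trajs = np.empty((B, s_grid.size, 4))
    for b in range(B):
        data_b = {}
        for k in BIOMARKERS:
            s_obs, y_obs = data[k]
            if y_obs.size:
                rs = resid[k][rng.integers(0, resid[k].size, resid[k].size)]
                data_b[k] = (s_obs, fitted[k] + rs)
            else:
                data_b[k] = (s_obs, y_obs)
        # warm-started joint refit; band quantiles do not need 1e-10
        # parameter precision
        w_b = _refit_weights_joint(data_b, state.w, max_nfev=effort)
        trajs[b] = solve_model(w_b, s_eval=s_grid).values
    q = (1.0 - coverage) / 2.0
    lower = np.quantile(trajs, q, axis=0)
    upper = np.quantile(trajs, 1.0 - q, axis=0)
    return BootstrapBand(s_grid=s_grid, lower=lower, upper=upper,
                         coverage=coverage, n_replicates=B)
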