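"""Personalized cascade models and leave-last-visit-out prediction.

Eligible subjects (>= 4 observations of every biomarker, each biomarker
weakly monotone in DPS after denoising) get a personal refit of the
sensitivity-selected parameter subset: the sensitive weights are re-estimated
jointly against the subject's first M-1 sigmoid-denoised points of all four
biomarkers (DPS warp and all other weights held at population values), the
last visit is predicted, and prediction accuracy PA = 100*(1 - |rel. err.|)
is scored per biomarker against the sigmoid-only baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import CohortTable, DpsParams
from .model import (BIOMARKERS, CascadeParams, S_MAX, S_MIN, WEIGHT_NAMES,
                    _dense_solution, solve_batch)
from .scoring import prediction_accuracy
from .sigmoid import InsufficientDataError, denoise_subject, sigmoid_predict_last

__all__ = ["PersonalizedFit", "eligible_subjects", "fit_personalized",
           "predict_and_score", "cohort_personalization_report"]

#: sign-aware box half-width around population values for personal refits;
#: guards against runaway fits on 3-point-per-biomarker data
BOX_FRAC = 0.5


@dataclass
class PersonalizedFit:
    subject_id: str
    sensitive: tuple[str, ...]
    w2: CascadeParams
    M: int
    dps_span: float
    pa_ode: dict[str, float] = field(default_factory=dict)
    pa_sigmoid: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _subject_series(cohort: CohortTable, dps: DpsParams, sid: str):
    """Per-biomarker (s, y) series sorted by visit for one subject."""
    sub = cohort.subject(sid)
    out = {}
    for k in BIOMARKERS:
        rows = sub[sub["biomarker"] == k].sort_values("visit")
        s = dps.s(sid, rows["age_years"].to_numpy())
        out[k] = (s, rows["value"].to_numpy())
    return out


def eligible_subjects(cohort: CohortTable, dps: DpsParams) -> list[str]:
    """Subjects with >= 4 observations of every biomarker whose denoised
    series are weakly monotone in DPS (direction free per biomarker)."""
    out = []
    for sid in cohort.subjects:
        if sid not in dps:
            continue
        series = _subject_series(cohort, dps, sid)
        ok = True
        for k in BIOMARKERS:
            s, y = series[k]
            if s.size < 4:
                ok = False
                break
            yhat, _ = denoise_subject(s, y)
            d = np.diff(yhat)
            if not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
                ok = False
                break
        if ok:
            out.append(sid)
    return out


def fit_personalized(cohort: CohortTable, dps: DpsParams, sid: str,
                     w_pop: CascadeParams, sensitive) -> PersonalizedFit:
    """Refit the sensitive weights to the subject's first M-1 denoised points.

    The objective sums squared residuals over all four biomarkers jointly
    (sensitive parameters from upstream equations propagate downstream, so a
    per-equation fit would be inconsistent).  Each sensitive weight is
    box-constrained to +-50% around its population value; non-sensitive
    weights stay bitwise at population values.
    """
    series = _subject_series(cohort, dps, sid)
    M = min(s.size for s, _ in series.values())
    if M < 4:
        raise InsufficientDataError(f"subject {sid}: needs >= 4 visits per biomarker")
    flags: list[str] = []
    train = {}
    for k in BIOMARKERS:
        s, y = series[k]
        yhat, fell_back = denoise_subject(s[:-1], y[:-1])
        if fell_back:
            flags.append(f"{k}: denoising fell back to raw values")
        train[k] = (s[:-1], yhat)
    s_all = np.concatenate([train[k][0] for k in BIOMARKERS])
    dps_span = float(series["C"][0].max() - series["C"][0].min())

    sensitive = tuple(sensitive)
    if not sensitive:
        return PersonalizedFit(sid, sensitive, w_pop, M, dps_span,
                               flags=flags + ["empty sensitive set; population model kept"])
    pop = np.array([w_pop[n] for n in sensitive])
    lo = np.minimum((1 - BOX_FRAC) * pop, (1 + BOX_FRAC) * pop)
    hi = np.maximum((1 - BOX_FRAC) * pop, (1 + BOX_FRAC) * pop)
    degenerate = hi - lo <= 0
    lo[degenerate] -= 1e-6
    hi[degenerate] += 1e-6

    base_w = w_pop.as_array()
    widx = [WEIGHT_NAMES.index(n) for n in sensitive]
    s_cat = np.clip(s_all, S_MIN, S_MAX)
    s_uniq, s_pos = np.unique(s_cat, return_inverse=True)
    kidx_cat = np.concatenate([
        np.full(train[k][0].size, BIOMARKERS.index(k)) for k in BIOMARKERS])
    y_cat = np.concatenate([train[k][1] for k in BIOMARKERS])

    # integrate to the domain end so personalized weights stay finite on all
    # of [-10, 20], not just over the training visits
    s_solve = np.append(s_uniq, S_MAX) if s_uniq[-1] < S_MAX else s_uniq

    def predict_many(X):
        X = np.atleast_2d(X)
        W = np.tile(base_w, (X.shape[0], 1))
        W[:, widx] = X
        traj = solve_batch(W, w_pop.y0, s_solve, rtol=1e-7, atol=1e-9)
        return traj[:, s_pos, :][:, np.arange(s_cat.size), kidx_cat]

    def residual(x):
        try:
            return predict_many(x)[0] - y_cat
        except Exception:
            return np.full(y_cat.size, 1e3)

    def jacobian(x):
        h = 1e-6 * np.maximum(np.abs(x), 1.0)
        eye = np.eye(x.size)
        try:
            F = predict_many(np.vstack([x + np.diag(h), x - np.diag(h)]))
        except Exception:
            base = residual(x)
            return np.column_stack([(residual(x + h[j] * eye[j]) - base) / h[j]
                                    for j in range(x.size)])
        n = x.size
        return (F[:n] - F[n:]).T / (2 * h)

    res = least_squares(residual, pop, jac=jacobian, bounds=(lo, hi),
                        method="trf", x_scale="jac",
                        xtol=1e-12, ftol=1e-12, max_nfev=2000)
    if not res.success:
        raise RuntimeError(f"personalized fit failed for subject {sid}: {res.message}")
    w2 = w_pop.with_updates(dict(zip(sensitive, (float(v) for v in res.x))))
    return PersonalizedFit(sid, sensitive, w2, M, dps_span, flags=flags)


def predict_and_score(fit: PersonalizedFit, cohort: CohortTable,
                      dps: DpsParams) -> PersonalizedFit:
    """Score the held-out last visit per biomarker for the personalized ODE
    and the sigmoid-only baseline; results stored on the fit."""
    series = _subject_series(cohort, dps, fit.subject_id)
    sol = _dense_solution(fit.w2)
    for k in BIOMARKERS:
        s, y = series[k]
        held_out = float(y[-1])
        pred = float(sol(np.clip(s[-1:], S_MIN, S_MAX))[BIOMARKERS.index(k)][0])
        fit.pa_ode[k] = prediction_accuracy(held_out, pred)
        if math.isnan(fit.pa_ode[k]):
            fit.flags.append(f"{k}: held-out value is 0; PA undefined")
        try:
            _, pa_sig, _ = sigmoid_predict_last(s, y)
        except InsufficientDataError:
            pa_sig = math.nan
            fit.flags.append(f"{k}: sigmoid baseline needs >= 5 visits")
        fit.pa_sigmoid[k] = pa_sig
    return fit


def cohort_personalization_report(cohort: CohortTable, w_pop: CascadeParams,
                                  sensitive, dps: DpsParams
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject PA table plus group mean +- SD summary.

    Returns (per_subject, summary).  per_subject has one row per eligible
    subject: visit count, DPS span of the visits, ODE PA and sigmoid-baseline
    PA for each biomarker (percent).  summary has mean and SD rows per
    diagnostic group.
    """
    omega = eligible_subjects(cohort, dps)
    rows = []
    for sid in omega:
        fit = fit_personalized(cohort, dps, sid, w_pop, sensitive)
        fit = predict_and_score(fit, cohort, dps)
        row = {"subject_id": sid, "group": cohort.subject_group(sid),
               "n_visits": fit.M, "dps_span": fit.dps_span}
        for k in BIOMARKERS:
            row[f"pa_ode_{k}"] = fit.pa_ode[k]
            row[f"pa_sigmoid_{k}"] = fit.pa_sigmoid[k]
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        return per_subject, pd.DataFrame()
    pa_cols = [c for c in per_subject.columns if c.startswith("pa_")]
    stats = []
    for grp, gdf in per_subject.groupby("group"):
        mean = gdf[pa_cols].mean()
        sd = gdf[pa_cols].std(ddof=1).fillna(0.0)
        stats.append(pd.Series({"group": grp, "stat": "mean", **mean.to_dict()}))
        stats.append(pd.Series({"group": grp, "stat": "sd", **sd.to_dict()}))
    summary = pd.DataFrame(stats)
    return per_subject, summary
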