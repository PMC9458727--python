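"""Four-parameter sigmoid trajectories: the empirical baseline model.

g(s; a, b, c, d) = a / (1 + exp(-b*(s - c))) + d

a is the magnitude scale, b the slope coefficient (its sign encodes
direction), c the horizontal position on the DPS axis and d the vertical
offset.  The module provides stable evaluation, the analytic derivative
needed as the regression target of sparse model discovery, per-subject
denoising ("sigmoid interpolation") and the last-visit baseline predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .scoring import prediction_accuracy

__all__ = [
    "SigmoidParams",
    "SigmoidFit",
    "InsufficientDataError",
    "sigmoid_eval",
    "sigmoid_derivative",
    "fit_sigmoid",
    "denoise_subject",
    "sigmoid_predict_last",
]


class InsufficientDataError(ValueError):
    """Fewer points than the four sigmoid parameters require."""


@dataclass(frozen=True)
class SigmoidParams:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not all(np.isfinite([self.a, self.b, self.c, self.d])):
            raise ValueError("sigmoid parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}

    @classmethod
    def from_dict(cls, d) -> "SigmoidParams":
        return cls(float(d["a"]), float(d["b"]), float(d["c"]), float(d["d"]))


@dataclass(frozen=True)
class SigmoidFit:
    params: SigmoidParams
    rss: float
    converged: bool
    degenerate: bool = False
    n_points: int = 0


def sigmoid_eval(s, theta: SigmoidParams):
    """Evaluate g(s); overflow-free for large |b*(s-c)| via expit."""
    s = np.asarray(s, dtype=float)
    out = theta.a * expit(theta.b * (s - theta.c)) + theta.d
    return float(out) if out.ndim == 0 else out


def sigmoid_derivative(s, theta: SigmoidParams):
    """Analytic dg/ds = a*b*sig*(1-sig); sign everywhere equals sign(a*b)."""
    s = np.asarray(s, dtype=float)
    sig = expit(theta.b * (s - theta.c))
    out = theta.a * theta.b * sig * (1.0 - sig)
    return float(out) if out.ndim == 0 else out


def _residuals(p: np.ndarray, s: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    a, b, c, d = p
    return w * (a * expit(b * (s - c)) + d - y)


def fit_sigmoid(points, weights=None) -> SigmoidFit:
    """Weighted nonlinear least-squares fit of the four-parameter sigmoid.

    ``points`` is a sequence of (s, value) pairs (or a pair of arrays).  The
    objective is multimodal, so the fit multi-starts from five deterministic,
    data-driven initializations (a = data range, d = data min, c = median s,
    b in {+-0.5, +-2} plus a slope-matched guess) and keeps the lowest
    residual sum of squares.  Non-convergence is flagged, not raised.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[1] == 2:
        s, y = pts[:, 0], pts[:, 1]
    else:
        s, y = np.asarray(points[0], float), np.asarray(points[1], float)
    if s.size < 4:
        raise InsufficientDataError(f"need >= 4 points to fit 4 parameters, got {s.size}")
    if np.allclose(s, s[0]):
        raise InsufficientDataError("all s values identical; sigmoid is unidentifiable")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    rng_y = float(np.ptp(y))
    if rng_y == 0.0:  # constant data: exact degenerate fit
        theta = SigmoidParams(0.0, 1.0, float(np.median(s)), float(y[0]))
        return SigmoidFit(theta, 0.0, True, degenerate=True, n_points=s.size)

    d0, c0 = float(np.min(y)), float(np.median(s))
    slope = float(np.polyfit(s, y, 1)[0])
    b_slope = np.clip(4.0 * slope / rng_y, -50.0, 50.0)
    starts = [np.array([rng_y, b, c0, d0]) for b in (0.5, -0.5, 2.0, -2.0)]
    starts.append(np.array([rng_y * np.sign(b_slope) if b_slope else rng_y,
                            abs(b_slope) if b_slope else 1.0, c0, d0]))

    best = None
    for p0 in starts:
        try:
            res = least_squares(_residuals, p0, args=(s, y, w), method="lm",
                                max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        theta = SigmoidParams(rng_y, 1.0, c0, d0)
        return SigmoidFit(theta, float(np.sum(_residuals(theta.as_array(), s, y, w) ** 2)),
                          converged=False, n_points=s.size)
    rss, res = best
    theta = SigmoidParams(*[float(v) for v in res.x])
    return SigmoidFit(theta, rss, converged=bool(res.success), n_points=s.size)


def denoise_subject(s_values, y_values) -> tuple[np.ndarray, bool]:
    """Per-subject sigmoid interpolation of one biomarker's visit series.

    Returns (denoised values at the subject's own DPS values, fallback flag).
    With fewer than 4 observed visits, or a failed fit, the raw values are
    returned with the fallback flag set.
    """
    s = np.asarray(s_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if s.size < 4:
        return y.copy(), True
    try:
        fit = fit_sigmoid((s, y))
    except InsufficientDataError:
        return y.copy(), True
    if not (fit.converged or fit.degenerate):
        return y.copy(), True
    return np.asarray(sigmoid_eval(s, fit.params)), False


def sigmoid_predict_last(s_values, y_values) -> tuple[float, float, SigmoidFit]:
    """Baseline forecast: fit the first M-1 points, predict the M-th.

    Uses the current biomarker's own longitudinal history only.  Returns
    (predicted value, PA score against the held-out point, fit).  Requires
    at least 5 visits so the training fit sees >= 4 points.
    """
    s = np.asarray(s_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if s.size < 5:
        raise InsufficientDataError(
            f"need >= 5 visits (>= 4 to fit, 1 held out), got {s.size}")
    fit = fit_sigmoid((s[:-1], y[:-1]))
    pred = float(sigmoid_eval(s[-1], fit.params))
    return pred, prediction_accuracy(float(y[-1]), pred), fit
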