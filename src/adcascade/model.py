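"""Four-variable polynomial cascade ODE over the disease-progression-score axis.

The model chains amyloid-beta (A), tau (T), neurodegeneration (N) and
cognitive decline (C): each equation is a degree-2 polynomial in its own
variable and its immediate upstream variable,

    dA/ds = w_A0 + w_A1*A + w_A2*A^2
    dT/ds = w_T0 + w_T1*T + w_T2*T^2 + w_T3*A + w_T4*A^2 + w_T5*A*T
    dN/ds = w_N0 + w_N1*N + w_N2*N^2 + w_N3*T + w_N4*T^2 + w_N5*T*N
    dC/ds = w_C0 + w_C1*C + w_C2*C^2 + w_C3*N + w_C4*N^2 + w_C5*N*C

integrated on s in [-10, 20] from the cascade-initiating condition
A(-10) = y0 > 0, T(-10) = N(-10) = C(-10) = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BIOMARKERS",
    "WEIGHT_NAMES",
    "S_MIN",
    "S_MAX",
    "LibrarySpec",
    "CascadeParams",
    "Trajectory",
    "DomainError",
    "SolverBlowupError",
    "build_library",
    "rhs",
    "solve_model",
    "solve_batch",
    "evaluate_f",
    "load_fixture_params",
]

BIOMARKERS = ("A", "T", "N", "C")

#: canonical weight layout: 3 amyloid weights, then 6 per downstream equation
WEIGHT_NAMES = (
    "w_A0", "w_A1", "w_A2",
    "w_T0", "w_T1", "w_T2", "w_T3", "w_T4", "w_T5",
    "w_N0", "w_N1", "w_N2", "w_N3", "w_N4", "w_N5",
    "w_C0", "w_C1", "w_C2", "w_C3", "w_C4", "w_C5",
)

S_MIN, S_MAX = -10.0, 20.0
_BLOWUP = 1.0e3  # abort integration beyond this state magnitude


class DomainError(ValueError):
    """Input outside the model's mathematical domain."""


class SolverBlowupError(RuntimeError):
    """Integration aborted because the state left the admissible region."""

    def __init__(self, message: str, s: float | None = None):
        super().__init__(message)
        self.s = s


@dataclass(frozen=True)
class LibrarySpec:
    """Polynomial candidate library for one cascade equation.

    Terms are exponent pairs ``(own, up)`` meaning ``x_own**own * x_up**up``.
    Canonical ordering (matching the printed model): constant, pure powers of
    the equation's own variable ascending, pure powers of the upstream
    variable ascending, then cross terms ordered by total degree and own
    exponent.  Single-variable libraries use ``up == 0`` throughout.
    """

    degree: int
    mode: Literal["single", "pair"]
    terms: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.terms)

    def labels(self, own: str, up: str) -> tuple[str, ...]:
        out = []
        for i, j in self.terms:
            if i == 0 and j == 0:
                out.append("1")
            else:
                bits = []
                if i:
                    bits.append(own if i == 1 else f"{own}^{i}")
                if j:
                    bits.append(up if j == 1 else f"{up}^{j}")
                out.append("*".join(bits))
        return tuple(out)


def build_library(m: int, mode: Literal["single", "pair"] = "pair") -> LibrarySpec:
    """Enumerate polynomial basis terms up to total degree ``m``.

    For ``mode='single'`` the library is {1, x, ..., x^m} (m+1 terms); for
    ``mode='pair'`` it is every monomial x^i*y^j with i+j <= m, yielding
    (m+1)(m+2)/2 terms, in the canonical order documented on LibrarySpec.
    """
    if not isinstance(m, (int, np.integer)) or m < 0:
        raise DomainError(f"library degree must be a non-negative integer, got {m!r}")
    if mode == "single":
        terms = tuple((i, 0) for i in range(m + 1))
    elif mode == "pair":
        own = [(i, 0) for i in range(1, m + 1)]
        up = [(0, j) for j in range(1, m + 1)]
        cross = [(i, j) for d in range(2, m + 1)
                 for i in range(1, d) for j in [d - i] if j >= 1]
        # order cross terms by total degree then own exponent
        terms = tuple([(0, 0)] + own + up + cross)
    else:
        raise DomainError(f"unknown library mode {mode!r}")
    return LibrarySpec(degree=int(m), mode=mode, terms=terms)


# which upstream variable feeds each equation (A is self-contained)
UPSTREAM = {"A": None, "T": "A", "N": "T", "C": "N"}

#: slice of WEIGHT_NAMES belonging to each equation
EQUATION_SLICES = {"A": slice(0, 3), "T": slice(3, 9), "N": slice(9, 15), "C": slice(15, 21)}


@dataclass(frozen=True)
class CascadeParams:
    """The 21 population weights plus the cascade-initiating level y0.

    Weight names follow the printed parameter layout (w_A0..w_C5).  y0 is the
    small positive amyloid level at s = -10 that initiates the cascade.
    """

    weights: tuple[float, ...]
    y0: float

    def __post_init__(self):
        if len(self.weights) != len(WEIGHT_NAMES):
            raise ValueError(f"expected {len(WEIGHT_NAMES)} weights, got {len(self.weights)}")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("all weights must be finite")
        if not (np.isfinite(self.y0) and self.y0 > 0):
            raise ValueError("y0 must be a (small) positive value")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))
        object.__setattr__(self, "y0", float(self.y0))

    # -- named access -----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        if name == "y0":
            return self.y0
        return self.weights[WEIGHT_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def to_dict(self) -> dict[str, float]:
        d = {n: w for n, w in zip(WEIGHT_NAMES, self.weights)}
        d["y0"] = self.y0
        return d

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CascadeParams":
        missing = [n for n in WEIGHT_NAMES + ("y0",) if n not in d]
        if missing:
            raise ValueError(f"missing parameter entries: {missing}")
        return cls(weights=tuple(float(d[n]) for n in WEIGHT_NAMES), y0=float(d["y0"]))

    @classmethod
    def from_array(cls, w: Sequence[float], y0: float) -> "CascadeParams":
        return cls(weights=tuple(float(x) for x in w), y0=y0)

    def with_updates(self, updates: dict[str, float]) -> "CascadeParams":
        d = self.to_dict()
        unknown = set(updates) - set(d)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        d.update(updates)
        return CascadeParams.from_dict(d)

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CascadeParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_fixture_params(name: str) -> CascadeParams:
    """Load a bundled calibrated parameter set.

    ``name`` is ``'full_cohort'`` (CN+LMCI+AD calibration) or ``'lmci_ad'``
    (LMCI+AD-only refit).
    """
    fname = {"full_cohort": "population_full_cohort.json",
             "lmci_ad": "population_lmci_ad.json"}.get(name)
    if fname is None:
        raise KeyError(f"unknown fixture {name!r}; use 'full_cohort' or 'lmci_ad'")
    ref = resources.files("adcascade.data").joinpath(fname)
    with ref.open() as fh:
        return CascadeParams.from_dict(json.load(fh))


@dataclass(frozen=True)
class Trajectory:
    """Solved biomarker curves on a DPS grid; columns follow BIOMARKERS."""

    s_grid: np.ndarray
    values: np.ndarray  # shape (len(s_grid), 4)

    def column(self, k: str) -> np.ndarray:
        return self.values[:, BIOMARKERS.index(k)]


def _rhs_core(y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Vectorized right-hand side; y shape (4, ...) and W shape (21, ...)."""
    A, T, N, C = y[0], y[1], y[2], y[3]
    dA = W[0] + W[1] * A + W[2] * A * A
    dT = W[3] + W[4] * T + W[5] * T * T + W[6] * A + W[7] * A * A + W[8] * A * T
    dN = W[9] + W[10] * N + W[11] * N * N + W[12] * T + W[13] * T * T + W[14] * T * N
    dC = W[15] + W[16] * C + W[17] * C * C + W[18] * N + W[19] * N * N + W[20] * N * C
    return np.stack([dA, dT, dN, dC])


def rhs(state: Sequence[float], params: CascadeParams) -> np.ndarray:
    """Evaluate (dA/ds, dT/ds, dN/ds, dC/ds) at one state."""
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise DomainError(f"state must be a 4-vector, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise DomainError("state must be finite")
    return _rhs_core(y, params.as_array())


def _check_span(s_span: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(s_span[0]), float(s_span[1])
    if not (S_MIN - 1e-12 <= lo < hi <= S_MAX + 1e-12):
        raise DomainError(f"s_span must lie within [{S_MIN}, {S_MAX}], got {s_span}")
    return lo, hi


def solve_model(
    params: CascadeParams,
    s_span: tuple[float, float] = (S_MIN, S_MAX),
    s_eval: Iterable[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the cascade from (y0, 0, 0, 0) at the start of ``s_span``.

    Uses adaptive explicit Runge-Kutta 4(5); the system is non-stiff at
    calibrated-weight scale.  Default tolerances are tight enough that a
    further halving moves trajectory values by well under 1e-6.  Integration aborts with SolverBlowupError if
    any state magnitude exceeds 1e3 (relevant when sampling perturbed
    weights).
    """
    lo, hi = _check_span(s_span)
    if s_eval is None:
        s_eval = np.linspace(lo, hi, 301)
    s_eval = np.asarray(list(s_eval) if not isinstance(s_eval, np.ndarray) else s_eval,
                        dtype=float)
    if s_eval.size and (s_eval[0] < lo - 1e-9 or s_eval[-1] > hi + 1e-9):
        raise DomainError("s_eval must lie within s_span")
    W = params.as_array()

    def fun(s, y):
        return _rhs_core(y.reshape(4), W)

    def blowup(s, y):
        return _BLOWUP - np.max(np.abs(y))

    blowup.terminal = True
    y_init = np.array([params.y0, 0.0, 0.0, 0.0])
    sol = solve_ivp(fun, (lo, hi), y_init, t_eval=s_eval, rtol=rtol, atol=atol,
                    method="RK45", events=blowup)
    if sol.status == 1:  # blow-up event fired
        s_fail = float(sol.t_events[0][0])
        raise SolverBlowupError(f"state magnitude exceeded {_BLOWUP:g} at s={s_fail:.3f}",
                                s=s_fail)
    if not sol.success:
        raise SolverBlowupError(f"integration failed: {sol.message}",
                                s=float(sol.t[-1]) if sol.t.size else lo)
    return Trajectory(s_grid=sol.t, values=sol.y.T)


@lru_cache(maxsize=64)
def _dense_solution(params: CascadeParams):
    """One dense solve per parameter set, reused by evaluate_f."""
    W = params.as_array()

    def fun(s, y):
        return _rhs_core(y.reshape(4), W)

    def blowup(s, y):
        return _BLOWUP - np.max(np.abs(y))

    blowup.terminal = True
    y_init = np.array([params.y0, 0.0, 0.0, 0.0])
    sol = solve_ivp(fun, (S_MIN, S_MAX), y_init, dense_output=True,
                    rtol=1e-9, atol=1e-11, method="RK45", events=blowup)
    if sol.status == 1:
        s_fail = float(sol.t_events[0][0])
        raise SolverBlowupError(f"state magnitude exceeded {_BLOWUP:g} at s={s_fail:.3f}",
                                s=s_fail)
    if not sol.success:
        raise SolverBlowupError(f"integration failed: {sol.message}")
    return sol.sol


def evaluate_f(k: str, s, params: CascadeParams):
    """Model solution f_k(s; w) via one cached dense solve per parameter set.

    Accepts scalar or array ``s`` in [-10, 20]; pure function of (k, s, params).
    """
    if k not in BIOMARKERS:
        raise DomainError(f"unknown biomarker {k!r}")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < S_MIN - 1e-9) or np.any(s_arr > S_MAX + 1e-9):
        raise DomainError(f"s must lie in [{S_MIN}, {S_MAX}]")
    sol = _dense_solution(params)
    vals = sol(np.clip(s_arr, S_MIN, S_MAX))[BIOMARKERS.index(k)]
    return float(vals[0]) if np.isscalar(s) or np.ndim(s) == 0 else vals


def solve_batch(
    W: np.ndarray,
    y0,
    s_eval: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    chunk: int = 4096,
) -> np.ndarray:
    """Solve the cascade for many weight vectors at once.

    Stacks ``n`` independent 4-state systems into one vector field so the
    adaptive solver amortizes across samples (step size is governed by the
    least regular sample, so per-sample accuracy is at least the requested
    tolerance).  Returns array of shape (n, len(s_eval), 4).

    Parameters
    ----------
    W : (n, 21) array of weight vectors.
    y0 : scalar or (n,) initial amyloid level(s).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    s_eval = np.asarray(s_eval, dtype=float)
    y0 = np.broadcast_to(np.asarray(y0, dtype=float), (n,))
    out = np.empty((n, s_eval.size, 4))
    for start in range(0, n, chunk):
        idx = slice(start, min(start + chunk, n))
        Wc = W[idx].T.copy()  # (21, m)
        m = Wc.shape[1]

        def fun(s, y):
            return _rhs_core(y.reshape(4, m), Wc).reshape(-1)

        def blowup(s, y):
            return _BLOWUP - np.max(np.abs(y))

        blowup.terminal = True
        y_init = np.zeros((4, m))
        y_init[0] = y0[idx]
        sol = solve_ivp(fun, (S_MIN, float(s_eval[-1])),
                        y_init.reshape(-1), t_eval=s_eval,
                        rtol=rtol, atol=atol, method="RK45", events=blowup)
        if sol.status == 1:
            s_fail = float(sol.t_events[0][0])
            raise SolverBlowupError(
                f"batch integration blew up at s={s_fail:.3f}", s=s_fail)
        if not sol.success:
            raise SolverBlowupError(f"batch integration failed: {sol.message}")
        out[idx] = sol.y.reshape(4, m, s_eval.size).transpose(1, 2, 0)
    return out
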