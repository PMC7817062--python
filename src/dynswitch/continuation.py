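"""Steady-state response curves, saddle-node points and switch thresholds.

The scalar kinetics ``F(X) = f(X)(X_T - X) - g(X) X`` define the
steady-state response of the active concentration ``X`` to either the
total protein ``X_T`` or the basal activation rate ``a``.  This module
traces those curves with a pseudo-arclength predictor–corrector (so that
folded, bistable branches are followed through their turning points),
locates the saddle-node (fold) points where a stable and an unstable
state coalesce, and derives the conventions built on them:

* ``midpoint_Xc`` — the modulation midpoint, the mean of the two fold
  X_T coordinates of the static switch;
* ``event_thresholds`` — the up/down crossing levels used by the period
  detector (the X coordinates of the left and right folds) and the
  transition-time threshold (their average).

A brute-force root scanner is included as an independent oracle, and an
exact fold finder based on the closed-form branch parametrization
``X_T(X) = X (f + g) / f`` serves as a fast path for large surveys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .params import FeedbackParams

__all__ = [
    "SaddleNode",
    "ResponseCurve",
    "steady_states_bruteforce",
    "trace_response_curve",
    "find_saddle_nodes",
    "switch_folds_exact",
    "midpoint_Xc",
    "event_thresholds",
    "bistable_region_2d",
]

_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class SaddleNode:
    """Fold point: parameter value and X at which two steady states coalesce."""

    parameter: float
    X: float


@dataclass
class ResponseCurve:
    """A continued branch of steady states versus one parameter.

    ``parameter``, ``X`` and ``stable`` are aligned arrays ordered by
    arclength along the branch; the stability flag flips exactly at the
    saddle nodes.
    """

    varied_parameter: Literal["X_T", "a"]
    parameter: np.ndarray
    X: np.ndarray
    stable: np.ndarray
    saddle_nodes: List[SaddleNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.parameter)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"parameter": self.parameter, "X": self.X, "stable": self.stable}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")

    def saddle_nodes_json(self) -> str:
        return json.dumps(
            [{"parameter": sn.parameter, "X": sn.X} for sn in self.saddle_nodes]
        )


# ---------------------------------------------------------------------------
# Scalar kinetics and derivatives

def _fg(X: np.ndarray, params: FeedbackParams, a_value: float):
    """f, g and their X-derivatives, with X clipped at 0."""
    X = np.maximum(X, 0.0)
    Kn = params.K**params.n
    Xn = np.power(X, params.n)
    f = a_value + params.b * Xn / (Kn + Xn)
    with np.errstate(divide="ignore", invalid="ignore"):
        dXn = np.where(X > 0, params.n * Xn / X, 0.0 if params.n > 1 else np.inf)
    if params.n == 1:
        dXn = np.ones_like(np.asarray(X, dtype=float))
    df = params.b * Kn * dXn / (Kn + Xn) ** 2
    Km = params.K_prime**params.m
    Xm = np.power(X, params.m)
    g = params.a_prime + params.b_prime * Km / (Km + Xm)
    with np.errstate(divide="ignore", invalid="ignore"):
        dXm = np.where(X > 0, params.m * Xm / X, 0.0 if params.m > 1 else np.inf)
    if params.m == 1:
        dXm = np.ones_like(np.asarray(X, dtype=float))
    dg = -params.b_prime * Km * dXm / (Km + Xm) ** 2
    return f, g, df, dg


def _residual(X, p, params, a_value, vary):
    """F(X; p) and its partials (F_X, F_p) for the varied parameter."""
    if vary == "X_T":
        f, g, df, dg = _fg(X, params, a_value)
        F = f * (p - X) - g * X
        F_X = df * (p - X) - f - dg * X - g
        F_p = f
    else:  # vary == "a": p is the basal rate, a_value holds the fixed X_T
        X_T = a_value
        f, g, df, dg = _fg(X, params, p)
        F = f * (X_T - X) - g * X
        F_X = df * (X_T - X) - f - dg * X - g
        F_p = X_T - X
    return F, F_X, F_p


# ---------------------------------------------------------------------------
# Brute force oracle

def steady_states_bruteforce(
    params: FeedbackParams,
    a_value: Optional[float] = None,
    X_T: float = 1.0,
    n_grid: int = 4001,
) -> List[Tuple[float, bool]]:
    """All steady states of the scalar kinetics at fixed (a, X_T).

    Scans F(X) = f(X)(X_T − X) − g(X) X for sign changes on a dense grid
    over [0, X_T] and refines each bracket by bisection.  Stability from
    the sign of dF/dX.  Serves as the independent oracle for the
    continuation code.
    """
    if X_T < 0:
        raise ValueError("X_T must be >= 0")
    a = params.a if a_value is None else a_value
    if X_T == 0.0:
        return [(0.0, True)]

    def F(X: float) -> float:
        val, _, _ = _residual(X, X_T, params, a, "X_T")
        return float(val)

    grid = np.linspace(0.0, X_T, n_grid)
    vals = np.array([F(x) for x in grid])
    roots: List[Tuple[float, bool]] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0 and grid[i] not in [r for r, _ in roots]:
            root = grid[i]
        elif lo * hi < 0:
            root = brentq(F, grid[i], grid[i + 1], xtol=1e-14)
        else:
            continue
        _, F_X, _ = _residual(root, X_T, params, a, "X_T")
        roots.append((float(root), bool(F_X < 0)))
    if vals[-1] == 0.0:
        _, F_X, _ = _residual(X_T, X_T, params, a, "X_T")
        roots.append((float(X_T), bool(F_X < 0)))
    return roots


# ---------------------------------------------------------------------------
# Pseudo-arclength continuation

class ContinuationError(RuntimeError):
    """Corrector failed to converge; carries the last good point."""

    def __init__(self, message: str, last_point: Tuple[float, float]):
        super().__init__(message)
        self.last_point = last_point


def _newton_corrector(X, p, t_X, t_p, X_pred, p_pred, params, aux, vary, tol, max_iter=12):
    """Newton iteration on (F = 0, tangent-orthogonality = 0)."""
    for _ in range(max_iter):
        F, F_X, F_p = _residual(X, p, params, aux, vary)
        N = (X - X_pred) * t_X + (p - p_pred) * t_p
        if abs(F) < tol and abs(N) < tol:
            return X, p, True
        det = F_X * t_p - F_p * t_X
        if det == 0 or not np.isfinite(det):
            return X, p, False
        dX = (-F * t_p + F_p * N) / det
        dp = (-F_X * N + F * t_X) / det
        X, p = X + dX, p + dp
    F, _, _ = _residual(X, p, params, aux, vary)
    return X, p, abs(F) < tol


def trace_response_curve(
    params: FeedbackParams,
    vary: Literal["X_T", "a"] = "X_T",
    fixed_value: Optional[float] = None,
    p_range: Tuple[float, float] = (0.0, 5.0),
    ds: float = 1e-2,
    ds_min: float = 1e-5,
    ds_max: float = 1e-1,
    max_points: int = 200_000,
) -> ResponseCurve:
    """Trace the steady-state curve versus ``X_T`` or ``a``.

    Pseudo-arclength continuation with a secant predictor and Newton
    corrector; the step is halved on corrector failure and grown back on
    easy steps, so sharp folds (Hill exponents ~5) are traversed
    robustly.  ``fixed_value`` is the value of the parameter held
    constant (``a`` when varying X_T, ``X_T`` when varying a; defaults
    to ``params.a`` in the former case).  Every returned point satisfies
    the steady-state equation to 1e-8.
    """
    p_lo, p_hi = p_range
    if not p_hi > p_lo:
        raise ValueError("p_range must be nonempty")
    if vary == "X_T":
        aux = params.a if fixed_value is None else fixed_value
        roots = steady_states_bruteforce(params, aux, max(p_lo, 1e-9))
        if not roots:
            raise ContinuationError("no starting point on branch", (np.nan, np.nan))
        X0 = roots[0][0]
        p0 = max(p_lo, 1e-9)
    else:
        if fixed_value is None:
            raise ValueError("varying a requires fixed_value = X_T")
        aux = fixed_value  # X_T held fixed
        # the branch is single-valued in X with a(X) = g X/(X_T - X) - b-Hill,
        # so start from the low-activity end (a -> 0+ as X -> 0) and let the
        # continuation climb through any folds, including ones at a < 0
        X0 = 1e-8 * aux
        f, g, _, _ = _fg(np.asarray(X0), params, 0.0)
        p0 = float(g * X0 / (aux - X0) - (f - 0.0))

    segments = [
        _trace_segment(X0, p0, +1, params, aux, vary, p_range, ds, ds_min, ds_max, max_points)
    ]
    if vary == "X_T":
        # a distant fold can put the upper/middle branches out of reach of
        # the first segment within this window: start a second segment
        # from the top of the window if states there are uncovered
        roots_hi = steady_states_bruteforce(params, aux, p_hi)
        n_hi = sum(
            1
            for i in range(len(segments[0][0]) - 1)
            if (segments[0][1][i] - p_hi) * (segments[0][1][i + 1] - p_hi) <= 0
        )
        if len(roots_hi) > max(n_hi, 1):
            segments.append(
                _trace_segment(
                    roots_hi[-1][0], p_hi, -1, params, aux, vary,
                    p_range, ds, ds_min, ds_max, max_points,
                )
            )

    nodes: List[SaddleNode] = []
    Xs_all: List[float] = []
    ps_all: List[float] = []
    for Xs, ps in segments:
        seg = ResponseCurve(vary, np.array(ps), np.array(Xs), np.zeros(len(ps), bool), [])
        nodes.extend(find_saddle_nodes(seg, params=params, aux=aux))
        Xs_all.extend(Xs)
        ps_all.extend(ps)
    parameter = np.array(ps_all)
    X_arr = np.array(Xs_all)
    _, F_X_arr, _ = _residual(X_arr, parameter, params, aux, vary)
    stable = F_X_arr < 0
    nodes.sort(key=lambda sn: sn.parameter)
    unique: List[SaddleNode] = []
    for sn in nodes:
        if not unique or abs(sn.parameter - unique[-1].parameter) > 1e-7 or abs(
            sn.X - unique[-1].X
        ) > 1e-7:
            unique.append(sn)
    return ResponseCurve(vary, parameter, X_arr, stable, unique)


def _trace_segment(X0, p0, direction, params, aux, vary, p_range, ds, ds_min, ds_max, max_points):
    """One predictor-corrector sweep from a starting point on the branch."""
    p_lo, p_hi = p_range
    # polish the starting point
    for _ in range(30):
        F, F_X, _ = _residual(X0, p0, params, aux, vary)
        if abs(F) < 1e-13 or F_X == 0:
            break
        X0 -= F / F_X

    Xs = [float(X0)]
    ps = [float(p0)]

    F, F_X, F_p = _residual(X0, p0, params, aux, vary)
    t = np.array([-F_p, F_X])
    norm = np.hypot(*t)
    t = t / norm if norm > 0 else np.array([0.0, 1.0])
    if t[1] * direction < 0:
        t = -t

    step = ds
    while len(Xs) < max_points:
        X_prev, p_prev = Xs[-1], ps[-1]
        if len(Xs) >= 2:
            t = np.array([Xs[-1] - Xs[-2], ps[-1] - ps[-2]])
            t = t / np.hypot(*t)
        converged = False
        while step >= ds_min:
            X_pred = X_prev + step * t[0]
            p_pred = p_prev + step * t[1]
            X_new, p_new, converged = _newton_corrector(
                X_pred, p_pred, t[0], t[1], X_pred, p_pred, params, aux, vary,
                tol=_RESIDUAL_TOL * 1e-2,
            )
            # trust radius: a corrector that lands far from the predictor
            # has jumped to another branch (the folds are sharp); reject
            if converged and np.hypot(X_new - X_prev, p_new - p_prev) > 3.0 * step:
                converged = False
            if converged:
                break
            step /= 2.0
        if not converged:
            raise ContinuationError(
                f"corrector failed near ({X_prev:.6g}, {p_prev:.6g})",
                (X_prev, p_prev),
            )
        Xs.append(float(X_new))
        ps.append(float(p_new))
        step = min(step * 1.3, ds_max)
        # stop once we leave the parameter range moving outward, or X
        # leaves the physical region for the X_T case
        if (p_new > p_hi and len(Xs) > 2) or (p_new < p_lo and len(Xs) > 2):
            break
        if p_new > p_hi and direction > 0:
            break
        if vary == "X_T" and (X_new < -1e-9):
            break
    return Xs, ps


def find_saddle_nodes(
    curve: ResponseCurve,
    params: Optional[FeedbackParams] = None,
    aux: Optional[float] = None,
) -> List[SaddleNode]:
    """Locate folds of a continued curve.

    Folds are bracketed where the direction of travel of the continued
    parameter reverses between consecutive points, then refined by a
    two-variable Newton iteration on (F = 0, F_X = 0) when the kinetics
    are available; otherwise the bracket midpoint is returned.
    """
    p = curve.parameter
    if len(p) < 3:
        return []
    dp = np.diff(p)
    nodes: List[SaddleNode] = []
    for i in range(len(dp) - 1):
        if dp[i] == 0 or dp[i + 1] == 0:
            continue
        if dp[i] * dp[i + 1] < 0:
            X_f, p_f = curve.X[i + 1], p[i + 1]
            if params is not None and aux is not None:
                X_f, p_f = _refine_fold(X_f, p_f, params, aux, curve.varied_parameter)
            nodes.append(SaddleNode(float(p_f), float(X_f)))
    nodes.sort(key=lambda sn: sn.parameter)
    return nodes


def _refine_fold(X, p, params, aux, vary, tol=1e-12, max_iter=50):
    """Newton on the fold system F(X,p) = 0, F_X(X,p) = 0."""
    h = 1e-7
    for _ in range(max_iter):
        F, F_X, F_p = _residual(X, p, params, aux, vary)
        _, F_X_hx, _ = _residual(X + h, p, params, aux, vary)
        _, F_X_hp, _ = _residual(X, p + h, params, aux, vary)
        F_XX = (F_X_hx - F_X) / h
        F_Xp = (F_X_hp - F_X) / h
        det = F_X * F_Xp - F_p * F_XX
        if det == 0 or not np.isfinite(det):
            break
        dX = -(F * F_Xp - F_p * F_X) / det
        dp = -(F_X * F_X - F_XX * F) / det
        X, p = X + dX, p + dp
        if abs(F) < tol and abs(F_X) < tol:
            break
    return X, p


def slice_states(
    curve: ResponseCurve,
    p_value: float,
    params: FeedbackParams,
    fixed_value: float,
) -> List[Tuple[float, bool]]:
    """Steady states on the continued curve at one parameter value.

    Locates the crossings of the continuation polyline with the vertical
    slice ``p = p_value`` and polishes each interpolated X by Newton
    iteration on the steady-state equation at fixed parameter, so the
    returned values carry the corrector's accuracy rather than the
    polyline's.  Returns (X, stable) tuples sorted by X.
    """
    p, X = curve.parameter, curve.X
    vary = curve.varied_parameter
    aux = fixed_value
    out: List[Tuple[float, bool]] = []
    for i in range(len(p) - 1):
        if (p[i] - p_value) * (p[i + 1] - p_value) < 0 or p[i] == p_value:
            if p[i] == p_value:
                x = X[i]
            else:
                frac = (p_value - p[i]) / (p[i + 1] - p[i])
                x = X[i] + frac * (X[i + 1] - X[i])
            for _ in range(30):
                F, F_X, _ = _residual(x, p_value, params, aux, vary)
                if abs(F) < 1e-13 or F_X == 0:
                    break
                x -= F / F_X
            _, F_X, _ = _residual(x, p_value, params, aux, vary)
            out.append((float(x), bool(F_X < 0)))
    out.sort()
    # overlapping segments can cover the same state twice
    dedup: List[Tuple[float, bool]] = []
    for x, s in out:
        if not dedup or abs(x - dedup[-1][0]) > 1e-7:
            dedup.append((x, s))
    return dedup


# ---------------------------------------------------------------------------
# Exact folds from the closed-form branch parametrization

def switch_folds_exact(
    params: FeedbackParams,
    a_value: Optional[float] = None,
    X_max: float = 50.0,
    n_grid: int = 3000,
) -> List[SaddleNode]:
    """Folds of the steady-state curve versus X_T, via X_T(X) = X(f+g)/f.

    The steady-state branch is single-valued in X, so its folds are the
    interior extrema of the closed-form map X -> X_T.  Sign changes of
    dX_T/dX on a dense grid are refined by bisection.  Exact and cheap;
    used as the fast path in parameter surveys and as an oracle check on
    the continuation.
    """
    a = params.a if a_value is None else a_value

    def h_prime(X: float) -> float:
        f, g, df, dg = _fg(np.asarray(X, dtype=float), params, a)
        return float(1.0 + g / f + X * (dg * f - g * df) / f**2)

    grid = np.geomspace(1e-6, X_max, n_grid)
    vals = np.array([h_prime(x) for x in grid])
    folds: List[SaddleNode] = []
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            X_f = brentq(h_prime, grid[i], grid[i + 1], xtol=1e-13)
            f, g, _, _ = _fg(np.asarray(X_f, dtype=float), params, a)
            folds.append(SaddleNode(float(X_f * (f + g) / f), float(X_f)))
    folds.sort(key=lambda sn: sn.parameter)
    return folds


def _static_folds(params: FeedbackParams, a_bar: float) -> List[SaddleNode]:
    folds = switch_folds_exact(params, a_bar)
    if len(folds) != 2:
        raise ValueError(
            f"the static switch at a = {a_bar} is not bistable "
            f"({len(folds)} saddle nodes); X_c and event thresholds are undefined"
        )
    return folds


def midpoint_Xc(params: FeedbackParams, a_bar: float) -> float:
    """Modulation midpoint: mean of the two saddle-node X_T coordinates
    of the static switch at ``a_bar``.  Raises if that switch is not
    bistable."""
    left, right = _static_folds(params, a_bar)
    return 0.5 * (left.parameter + right.parameter)


def event_thresholds(params: FeedbackParams, a_bar: float) -> Tuple[float, float, float]:
    """(up, down, transition) crossing levels for event detection.

    ``up`` is the X coordinate of the left fold (the upper knee),
    ``down`` the X coordinate of the right fold (the lower knee), and
    ``transition`` their average — the threshold used for transition
    timing.  Always ``up > down``.
    """
    left, right = _static_folds(params, a_bar)
    up, down = left.X, right.X
    return up, down, 0.5 * (up + down)


def bistable_region_2d(
    params: FeedbackParams,
    a_grid: Sequence[float],
    X_T_max: float = 50.0,
) -> List[Tuple[float, float, float]]:
    """Boundary of the bistable region in the (a, X_T) plane.

    For each ``a`` slice the saddle-node X_T coordinates are collected;
    slices without folds contribute no boundary points.  Returns a list
    of (a, X_T_left_fold, X_T_right_fold) triples.
    """
    boundary = []
    for a in a_grid:
        folds = switch_folds_exact(params, a, X_max=X_T_max)
        if len(folds) == 2:
            boundary.append((float(a), folds[0].parameter, folds[1].parameter))
    return boundary
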