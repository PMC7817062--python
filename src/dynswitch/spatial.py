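"""1-D reaction–diffusion model: bistable traveling fronts and pinning.

Active (X) and inactive (Y) protein diffuse and interconvert through the
same Hill kinetics as the well-mixed model:

    dX/dt = D_X X_xx + (f(X) Y - g(X) X) / eps
    dY/dt = D_Y Y_xx - (f(X) Y - g(X) X) / eps

integrated with forward differences in time and centered differences in
space, under zero-flux boundaries.  The basal rate ``a`` may vary in
space (and time), which makes the local front velocity vary: a front
traveling into a region where ``a`` drops below the stall value comes to
a halt (pinning) and can be released by redistributing ``a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .continuation import steady_states_bruteforce
from .params import FeedbackParams

__all__ = [
    "SpatialField",
    "simulate_pde",
    "step_initial_field",
    "front_position",
    "front_velocity",
    "FrontFit",
    "velocity_scan",
    "stall_point",
    "pinning_experiment",
]


@dataclass
class SpatialField:
    """Snapshot of the 1-D fields: grid, X/Y profiles, a profile, time."""

    x: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    a: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("X", "Y", "a"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"profile {name} length does not match grid")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def X_T(self) -> np.ndarray:
        """Total protein, pointwise X + Y."""
        return self.X + self.Y

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "X": self.X, "Y": self.Y, "a": self.a})


def _laplacian_neumann(u: np.ndarray, dx: float) -> np.ndarray:
    """Second difference with mirrored (zero-flux) boundary nodes."""
    lap = np.empty_like(u)
    lap[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
    lap[0] = 2.0 * (u[1] - u[0])
    lap[-1] = 2.0 * (u[-2] - u[-1])
    return lap / dx**2


def _branch_states(params: FeedbackParams, a: float, X_T: float) -> Tuple[float, float]:
    """(low, high) stable X at the given a and X_T; raises if monostable."""
    roots = steady_states_bruteforce(params, a, X_T)
    stable = [x for x, s in roots if s]
    if len(stable) < 2:
        raise ValueError(
            f"kinetics at a={a}, X_T={X_T} are not bistable; no front exists"
        )
    return stable[0], stable[-1]


def step_initial_field(
    params: FeedbackParams,
    a: float,
    X_T: float = 2.0,
    L: float = 100.0,
    dx: float = 0.2,
    interface: Optional[float] = None,
) -> SpatialField:
    """Step initial condition: high-activity branch left of the
    interface, low-activity branch right of it, uniform total protein."""
    low, high = _branch_states(params, a, X_T)
    x = np.arange(0.0, L + dx / 2, dx)
    if interface is None:
        interface = L / 2
    X = np.where(x < interface, high, low)
    return SpatialField(x=x, X=X, Y=X_T - X, a=np.full_like(x, a), t=0.0)


def simulate_pde(
    params: FeedbackParams,
    a_profile: Union[float, np.ndarray, Callable[[np.ndarray, float], np.ndarray]],
    initial: SpatialField,
    t_end: float,
    D_X: float = 5.0,
    D_Y: float = 5.0,
    dt: Optional[float] = None,
    n_saves: int = 101,
    safety: float = 0.4,
) -> List[SpatialField]:
    """Explicit finite-difference integration of the two-field model.

    ``a_profile`` may be a scalar, a static array on the grid, or a
    callable ``a(x, t)`` (evaluated every step, enabling the pinning/
    release protocol).  The step must satisfy the diffusive stability
    bound dt <= dx^2 / (2 max(D_X, D_Y)); the default applies a safety
    factor to that bound, and a user-supplied dt violating it is
    refused with the admissible value reported.
    """
    dx = initial.dx
    D = max(D_X, D_Y)
    dt_max = dx * dx / (2.0 * D) if D > 0 else np.inf
    if dt is None:
        dt = safety * dt_max
    elif dt > dt_max:
        raise ValueError(
            f"dt={dt} violates the explicit stability bound; use dt <= {dt_max:.3e}"
        )
    callable_a = callable(a_profile)
    if not callable_a:
        a_static = (
            np.full_like(initial.x, float(a_profile))
            if np.isscalar(a_profile)
            else np.asarray(a_profile, dtype=float)
        )

    nsteps = max(1, int(round(t_end / dt)))
    save_at = np.unique(np.linspace(0, nsteps, n_saves).astype(int))
    X = initial.X.astype(float).copy()
    Y = initial.Y.astype(float).copy()
    x = initial.x
    inv_eps = 1.0 / params.epsilon
    Kn = params.K**params.n
    Km = params.K_prime**params.m

    snapshots: List[SpatialField] = []
    a_now = a_profile(x, 0.0) if callable_a else a_static
    if 0 in save_at:
        snapshots.append(SpatialField(x, X.copy(), Y.copy(), np.array(a_now, dtype=float, copy=True), 0.0))
    save_set = set(int(s) for s in save_at)
    for i in range(nsteps):
        t = i * dt
        if callable_a:
            a_now = a_profile(x, t)
        Xc = np.maximum(X, 0.0)
        Xn = Xc**params.n
        f = a_now + params.b * Xn / (Kn + Xn)
        g = params.a_prime + params.b_prime * Km / (Km + Xc**params.m)
        reaction = (f * Y - g * X) * inv_eps
        X = X + dt * (D_X * _laplacian_neumann(X, dx) + reaction)
        Y = Y + dt * (D_Y * _laplacian_neumann(Y, dx) - reaction)
        if (i + 1) in save_set:
            a_snap = a_profile(x, (i + 1) * dt) if callable_a else a_static
            snapshots.append(
                SpatialField(x, X.copy(), Y.copy(), np.array(a_snap, dtype=float, copy=True), (i + 1) * dt)
            )
    return snapshots


def front_position(field: SpatialField, level: float) -> float:
    """Linearly interpolated position where X crosses ``level``.

    Requires a monotone front (exactly one crossing); zero or multiple
    crossings raise, since the field then has no well-defined front.
    """
    s = field.X - level
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    exact = np.nonzero(s == 0)[0]
    n_crossings = len(idx) + len(exact)
    if n_crossings == 0:
        raise ValueError("field does not cross the level: no front")
    if n_crossings > 1:
        raise ValueError(f"{n_crossings} crossings: front position ambiguous")
    if len(exact):
        return float(field.x[exact[0]])
    i = idx[0]
    frac = -s[i] / (s[i + 1] - s[i])
    return float(field.x[i] + frac * (field.x[i + 1] - field.x[i]))


class FrontFit(NamedTuple):
    velocity: float
    r_squared: float
    positions: np.ndarray
    times: np.ndarray


def front_velocity(
    fields: Sequence[SpatialField],
    level: float,
    transient_fraction: float = 0.1,
    r2_warn: float = 0.99,
    boundary_margin: float = 2.0,
) -> FrontFit:
    """Front speed: slope of the least-squares line through (t, position).

    The first ``transient_fraction`` of the time window is discarded so
    the step initial condition can relax into the traveling profile, and
    snapshots where the front has left the domain (or sits within
    ``boundary_margin`` of it) are excluded from the fit.  Positive
    speed means the active state advances.  A poor linear fit (R^2
    below ``r2_warn``) raises a warning but still returns the slope.
    """
    times = np.array([f.t for f in fields])
    t_min = times[0] + transient_fraction * (times[-1] - times[0])
    kept = []
    for f in fields:
        if f.t < t_min:
            continue
        try:
            pos = front_position(f, level)
        except ValueError:
            continue  # front left the domain or not yet formed
        if boundary_margin > 0 and not (
            f.x[0] + boundary_margin <= pos <= f.x[-1] - boundary_margin
        ):
            continue
        kept.append((f.t, pos))
    if len(kept) < 10:
        raise ValueError("need at least 10 front positions after the transient")
    t = np.array([k[0] for k in kept])
    pos = np.array([k[1] for k in kept])
    A = np.vstack([t, np.ones_like(t)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, pos, rcond=None)
    ss_tot = float(np.sum((pos - pos.mean()) ** 2))
    ss_res = float(res[0]) if len(res) else float(np.sum((pos - A @ [slope, intercept]) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < r2_warn:
        warnings.warn(f"front position fit is poor (R^2 = {r2:.4f})", stacklevel=2)
    return FrontFit(float(slope), r2, pos, t)


def _front_level(params: FeedbackParams, a: float, X_T: float) -> float:
    low, high = _branch_states(params, a, X_T)
    return 0.5 * (low + high)


def velocity_scan(
    params: FeedbackParams,
    a_values: Sequence[float],
    X_T: float = 2.0,
    D_X: float = 5.0,
    D_Y: float = 5.0,
    L: float = 100.0,
    dx: float = 0.2,
    t_end: float = 16.0,
    n_saves: int = 60,
):
    """Front velocity versus the basal rate a, at fixed total protein.

    Each run starts from a step profile in the middle of the domain and
    fits the front position linearly in time.  Returns a DataFrame with
    columns (a, velocity, r_squared).
    """
    import pandas as pd

    rows = []
    for a in a_values:
        initial = step_initial_field(params, a, X_T, L=L, dx=dx)
        fields = simulate_pde(params, a, initial, t_end, D_X, D_Y, n_saves=n_saves)
        level = _front_level(params, a, X_T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = front_velocity(fields, level)
        rows.append({"a": float(a), "velocity": fit.velocity, "r_squared": fit.r_squared})
    return pd.DataFrame(rows)


def stall_point(
    params: FeedbackParams,
    a_values: Sequence[float],
    **scan_kwargs,
) -> float:
    """The basal rate at which the front velocity crosses zero,
    interpolated linearly between the bracketing scan points."""
    df = velocity_scan(params, a_values, **scan_kwargs)
    v = df["velocity"].to_numpy()
    a = df["a"].to_numpy()
    sign_change = np.nonzero(v[:-1] * v[1:] < 0)[0]
    if len(sign_change) == 0:
        raise ValueError("no zero crossing of the front velocity in the scanned range")
    i = sign_change[0]
    return float(a[i] - v[i] * (a[i + 1] - a[i]) / (v[i + 1] - v[i]))


def pinning_experiment(
    params: FeedbackParams,
    high_a: float = 0.27,
    low_a: float = 0.13,
    steepness: float = 0.2,
    flip_time: float = 25.0,
    blend_time: float = 2.0,
    X_T: float = 2.0,
    L: float = 60.0,
    dx: float = 0.2,
    t_end: float = 50.0,
    profile_center: Optional[float] = None,
    interface: Optional[float] = None,
    n_saves: int = 201,
):
    """Front pinning by a spatial a-gradient, and release by flipping it.

    The basal rate follows a smooth hyperbolic-tangent profile, high on
    the left and low on the right; the front launched at the left
    advances, stalls where the profile crosses the stall value, and is
    released when the profile is smoothly flipped (mirrored) at
    ``flip_time``.  Returns ``(fields, positions, pinned_position)``
    where ``positions`` is a DataFrame of front position versus time and
    ``pinned_position`` the front location just before the flip.
    """
    import pandas as pd

    if profile_center is None:
        profile_center = L / 2
    if interface is None:
        interface = L / 6

    mid = 0.5 * (high_a + low_a)
    amp = 0.5 * (high_a - low_a)

    def a_profile(x: np.ndarray, t: float) -> np.ndarray:
        down = mid - amp * np.tanh(steepness * (x - profile_center))
        if t <= flip_time:
            return down
        upp = mid + amp * np.tanh(steepness * (x - profile_center))
        w = min(1.0, (t - flip_time) / blend_time)
        s = w * w * (3.0 - 2.0 * w)  # smoothstep blend
        return (1.0 - s) * down + s * upp

    initial = step_initial_field(params, high_a, X_T, L=L, dx=dx, interface=interface)
    fields = simulate_pde(params, a_profile, initial, t_end, n_saves=n_saves)
    level = 0.5 * (
        _front_level(params, high_a, X_T) + _front_level(params, low_a, X_T)
    )
    rows = []
    pinned = None
    for f in fields:
        try:
            pos = front_position(f, level)
        except ValueError:
            pos = np.nan
        rows.append({"t": f.t, "position": pos})
        if f.t <= flip_time and np.isfinite(pos):
            pinned = pos
    return fields, pd.DataFrame(rows), pinned
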