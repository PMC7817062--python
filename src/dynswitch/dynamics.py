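"""Deterministic simulation and oscillation analysis.

``simulate`` integrates the transition, oscillator and three-equation
model variants, with or without an instantaneous/delayed modulation of
the basal activation rate.  Runs without delay default to scipy's
adaptive stiff-aware integrator (LSODA, rtol 1e-8 / atol 1e-10, the
epsilon^{-1} terms make the fast variable moderately stiff); delayed
runs and large parameter sweeps use a compiled fixed-step RK4 with a
cubic-Hermite-interpolated history buffer.

Period detection follows the two-threshold convention: up/down crossing
levels are the vertical (X) coordinates of the static switch's saddle
nodes, repeated same-direction crossings are collapsed to force
alternation, and a period is the spacing between consecutive retained
up-crossings — so only excursions that travel around both branches of
the switch count as cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .continuation import event_thresholds, midpoint_Xc, switch_folds_exact
from .kinetics import modulated_a, rhs_oscillator, rhs_transition
from .params import FeedbackParams, SwitchModulation, SystemState

__all__ = [
    "Trajectory",
    "OscillationStats",
    "simulate",
    "detect_period",
    "detect_amplitude",
    "oscillatory_region",
    "random_survey",
    "SURVEY_RANGES",
]

_MODEL_CODES = {"transition": 0, "oscillator": 1, "oscillator_full": 2}


@dataclass
class Trajectory:
    """Time-stamped states of a simulated system.

    ``data`` maps variable names to arrays aligned with ``times``;
    ``metadata`` records the model id, parameters and seed so any run
    can be reproduced exactly.
    """

    times: np.ndarray
    data: Dict[str, np.ndarray]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in self.data.items():
            if len(arr) != len(self.times):
                raise ValueError(f"column {name!r} length mismatch")

    def __getattr__(self, name: str) -> np.ndarray:
        data = object.__getattribute__(self, "data")
        if name in data:
            return data[name]
        raise AttributeError(name)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, **self.data})


@dataclass
class OscillationStats:
    """Cycle-level statistics of a trajectory.

    Empty period/amplitude lists mean the trajectory was classified as
    non-oscillatory; ``cv`` is sd/mean (sample sd, n-1 denominator).
    """

    periods: np.ndarray
    amplitudes: Optional[np.ndarray] = None

    @property
    def oscillatory(self) -> bool:
        return len(self.periods) > 0

    @staticmethod
    def _summary(values: np.ndarray) -> Tuple[float, float, float]:
        if len(values) == 0:
            return math.nan, math.nan, math.nan
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        cv = sd / mean if mean > 0 else math.nan
        return mean, sd, cv

    @property
    def period_mean(self) -> float:
        return self._summary(self.periods)[0]

    @property
    def period_sd(self) -> float:
        return self._summary(self.periods)[1]

    @property
    def period_cv(self) -> float:
        return self._summary(self.periods)[2]

    @property
    def amplitude_mean(self) -> float:
        if self.amplitudes is None:
            return math.nan
        return self._summary(self.amplitudes)[0]


def _resolve_mod(params: FeedbackParams, mod: Optional[SwitchModulation]):
    """(a_bar, da, kappa, Xc, tau) for the kernels; static a when no mod."""
    if mod is None:
        return params.a, 0.0, 1.0, 0.0, 0.0
    return mod.a_bar, mod.delta_a, mod.kappa, mod.X_c, mod.tau


def simulate(
    model: str,
    params: FeedbackParams,
    mod: Optional[SwitchModulation] = None,
    k_X: float = 0.2,
    initial: Optional[SystemState] = None,
    t_end: float = 20.0,
    delta: Optional[float] = None,
    method: str = "auto",
    dt: float = 1e-3,
    store_every: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate one deterministic model variant.

    ``model`` is one of ``transition``, ``oscillator``,
    ``oscillator_full`` or ``three_equation`` (the latter requires
    ``delta``).  ``method`` is ``auto`` (adaptive solver unless a delay
    is present), ``rk4`` (compiled fixed step) or ``scipy``.  Delay runs
    assume a constant history equal to the initial state.
    """
    if initial is None:
        initial = SystemState(X=0.0, X_T=0.0)
    if model == "three_equation":
        if delta is None:
            raise ValueError("three_equation model requires delta")
        if mod is None:
            raise ValueError("three_equation model requires a modulation")
        return _simulate_three_eq(params, mod, k_X, initial, t_end, delta, dt, store_every)
    if model not in _MODEL_CODES:
        raise ValueError(f"unknown model {model!r}")
    tau = 0.0 if mod is None else mod.tau
    if method == "auto":
        method = "rk4" if tau > 0 else "scipy"
    if method == "scipy" and tau > 0:
        raise ValueError("delayed modulation requires the fixed-step integrator")

    if method == "rk4":
        nsteps = max(1, int(round(t_end / dt)))
        if store_every is None:
            store_every = max(1, nsteps // 20_000)
        a_bar, da, kappa, Xc, tau = _resolve_mod(params, mod)
        t, X, XT, a = _kernels.ode_rk4(
            _MODEL_CODES[model],
            params.b, params.K, params.n, params.a_prime, params.b_prime,
            params.K_prime, params.m, params.epsilon,
            a_bar, da, kappa, Xc, tau,
            k_X, initial.X, initial.X_T,
            dt, nsteps, store_every,
        )
        data = {"X": X, "X_T": XT, "a": a}
    else:
        def rhs(t, y):
            if model == "transition":
                return rhs_transition(y, params, mod, k_X)
            return rhs_oscillator(y, params, mod, k_X, full_model=(model == "oscillator_full"))

        sol = solve_ivp(
            rhs, (0.0, t_end), [initial.X, initial.X_T],
            method="LSODA", rtol=rtol, atol=atol, dense_output=False,
            max_step=min(t_end / 10, 1.0),
        )
        if not sol.success:
            raise RuntimeError(f"integration of {model} failed: {sol.message}")
        a_arr = (
            np.full_like(sol.t, params.a)
            if mod is None
            else modulated_a(sol.y[1], mod)
        )
        data = {"X": sol.y[0], "X_T": sol.y[1], "a": a_arr}
        t = sol.t
    return Trajectory(
        times=t,
        data=data,
        metadata={
            "model": model,
            "params": params,
            "mod": mod,
            "k_X": k_X,
            "method": method,
        },
    )


def _simulate_three_eq(params, mod, k_X, initial, t_end, delta, dt, store_every):
    # fast relaxation of a makes the equation stiff: honor RK4 stability
    dt = min(dt, 2.5 * delta)
    nsteps = max(1, int(round(t_end / dt)))
    if store_every is None:
        store_every = max(1, nsteps // 20_000)
    a0 = initial.a_slow
    if a0 is None:
        a0 = float(modulated_a(initial.X_T, mod))
    t, X, XT, a = _kernels.three_eq_rk4(
        params.b, params.K, params.n, params.a_prime, params.b_prime,
        params.K_prime, params.m, params.epsilon,
        mod.a_bar, mod.delta_a, mod.kappa, mod.X_c,
        k_X, delta,
        initial.X, initial.X_T, a0,
        dt, nsteps, store_every,
    )
    return Trajectory(
        times=t,
        data={"X": X, "X_T": XT, "a": a},
        metadata={"model": "three_equation", "params": params, "mod": mod,
                  "k_X": k_X, "delta": delta},
    )


# ---------------------------------------------------------------------------
# Event detection

def _crossings(t: np.ndarray, x: np.ndarray, level: float, direction: int) -> np.ndarray:
    """Linearly interpolated crossing times of x through level."""
    s = x - level
    if direction > 0:
        idx = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0]
    else:
        idx = np.nonzero((s[:-1] >= 0) & (s[1:] < 0))[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = -s[idx] / (s[idx + 1] - s[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_period(traj: Trajectory, up: float, down: float) -> OscillationStats:
    """Periods of full two-branch excursions of X.

    Up-crossings of the ``up`` level and down-crossings of the ``down``
    level are merged in time; repeated same-direction events are dropped
    so the retained sequence alternates.  Periods are the differences
    between consecutive retained up-crossings.  Fewer than two retained
    up-crossings is a non-oscillatory verdict, not an error.
    """
    x = np.asarray(traj.X, dtype=float)
    if not np.all(np.isfinite(x)):
        return OscillationStats(periods=np.empty(0))
    t_up = _crossings(traj.times, x, up, +1)
    t_down = _crossings(traj.times, x, down, -1)
    events = [(t, +1) for t in t_up] + [(t, -1) for t in t_down]
    events.sort()
    retained_up: List[float] = []
    last_dir = 0
    for t, d in events:
        if d == last_dir:
            continue  # repeated same-direction crossing
        last_dir = d
        if d == +1:
            retained_up.append(t)
    if len(retained_up) < 2:
        return OscillationStats(periods=np.empty(0))
    return OscillationStats(periods=np.diff(np.array(retained_up)))


def detect_amplitude(traj: Trajectory, cutoff_factor: float = 5.0) -> OscillationStats:
    """Cycle amplitudes of X: each maximum minus the following minimum.

    The series is smoothed with a zero-phase low-pass Butterworth filter
    whose cutoff sits at ``cutoff_factor`` times the dominant frequency
    (from the FFT peak of the detrended signal), then local extrema are
    paired.  No extrema (or no dominant frequency) is a non-oscillatory
    verdict.
    """
    from scipy.signal import argrelextrema, butter, sosfiltfilt

    t = traj.times
    x = np.asarray(traj.X, dtype=float)
    if len(x) < 16 or np.ptp(x) == 0:
        return OscillationStats(periods=np.empty(0), amplitudes=np.empty(0))
    dt = float(np.median(np.diff(t)))
    # resample to a uniform grid for filtering if needed
    if not np.allclose(np.diff(t), dt, rtol=1e-3):
        tu = np.arange(t[0], t[-1], dt)
        x = np.interp(tu, t, x)
    detrended = x - np.mean(x)
    freqs = np.fft.rfftfreq(len(detrended), dt)
    power = np.abs(np.fft.rfft(detrended)) ** 2
    if len(power) < 3:
        return OscillationStats(periods=np.empty(0), amplitudes=np.empty(0))
    f0 = freqs[1:][np.argmax(power[1:])]
    if f0 <= 0:
        return OscillationStats(periods=np.empty(0), amplitudes=np.empty(0))
    nyq = 0.5 / dt
    fc = min(cutoff_factor * f0, 0.9 * nyq)
    sos = butter(4, fc / nyq, output="sos")
    smooth = sosfiltfilt(sos, x)
    maxima = argrelextrema(smooth, np.greater, order=3)[0]
    minima = argrelextrema(smooth, np.less, order=3)[0]
    amplitudes = []
    for i_max in maxima:
        following = minima[minima > i_max]
        if len(following):
            amplitudes.append(smooth[i_max] - smooth[following[0]])
    if not amplitudes:
        return OscillationStats(periods=np.empty(0), amplitudes=np.empty(0))
    return OscillationStats(periods=np.empty(0), amplitudes=np.array(amplitudes))


# ---------------------------------------------------------------------------
# Oscillatory-region mapping

def _rk4_dt_for(params: FeedbackParams, X_T_cap: float = 5.0, dt_max: float = 4e-3) -> float:
    """Step bound from the fastest local rate.

    Evaluates the analytic X-derivative of the scalar kinetics over the
    reachable state region (worst-case basal rate 2a, X_T at its cap)
    and keeps RK4 comfortably inside its real-axis stability interval.
    """
    from .continuation import _fg

    X = np.linspace(0.0, X_T_cap, 400)
    f, g, df, dg = _fg(X, params, 2.0 * params.a)
    F_X = df * (X_T_cap - X) - f - dg * X - g
    lam = float(np.max(np.abs(F_X))) / params.epsilon + 2.0 * X_T_cap
    return min(dt_max, 1.2 / lam)


def _run_and_classify(params, mod, k_X, t_end, up, down, min_period, dt=None):
    if dt is None:
        dt = _rk4_dt_for(params)
    for attempt in range(2):
        traj = simulate("oscillator", params, mod, k_X, t_end=t_end, method="rk4", dt=dt)
        if np.all(np.isfinite(traj.X)):
            break
        dt /= 5.0  # stability-bound estimate too optimistic: retry stiffer
    # discard the initial transient before counting cycles
    n0 = np.searchsorted(traj.times, 0.25 * t_end)
    sub = Trajectory(traj.times[n0:], {"X": traj.X[n0:]}, traj.metadata)
    stats = detect_period(sub, up, down)
    period = stats.period_mean if stats.oscillatory else 0.0
    if not np.isfinite(period) or period <= min_period:
        period = 0.0
    return period


def oscillatory_region(
    params: FeedbackParams,
    k_X_grid: Sequence[float],
    delta_a_grid: Sequence[float],
    kappa: float = 5.0,
    tau: float = 0.0,
    a_bar: float = 0.3,
    t_end: float = 200.0,
    min_period: float = 0.01,
):
    """Map the oscillation period over a (k_X, Δa) grid.

    Returns ``(period_map, boundary)``: the period per grid cell (0 when
    non-oscillatory by the two-threshold detector) and the smoothed
    zero-to-positive transition points along k_X for each Δa row, as a
    list of (Δa, k_X_low, k_X_high) for rows that oscillate anywhere.
    """
    up, down, _ = event_thresholds(params, a_bar)
    Xc = midpoint_Xc(params, a_bar)
    period_map = np.zeros((len(delta_a_grid), len(k_X_grid)))
    for i, da in enumerate(delta_a_grid):
        mod = SwitchModulation(a_bar=a_bar, delta_a=da, kappa=kappa, X_c=Xc, tau=tau)
        for j, kx in enumerate(k_X_grid):
            period_map[i, j] = _run_and_classify(
                params, mod, kx, t_end, up, down, min_period
            )
    boundary = []
    k_X_grid = np.asarray(k_X_grid, dtype=float)
    for i, da in enumerate(delta_a_grid):
        osc = period_map[i] > 0
        if osc.any():
            boundary.append(
                (float(da), float(k_X_grid[osc].min()), float(k_X_grid[osc].max()))
            )
    return period_map, boundary


# ---------------------------------------------------------------------------
# Random parameter survey

#: Sampling intervals for the random survey.  Uniform unless noted;
#: epsilon is sampled log-uniformly on [0.01, 1].  The intervals bracket
#: the standard constants.
SURVEY_RANGES: Dict[str, Tuple[float, float]] = {
    "a": (0.05, 0.6),
    "a_prime": (0.01, 0.5),
    "b": (0.5, 2.0),
    "b_prime": (0.5, 2.0),
    "K": (0.5, 2.0),
    "K_prime": (0.5, 2.0),
    "n": (2.0, 8.0),
    "m": (2.0, 8.0),
    "k_X": (0.5, 3.0),
    "epsilon": (0.01, 1.0),
}


def random_survey(
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    n_sets: int = 500,
    i_multipliers: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    kappas: Sequence[float] = (1.0, 5.0, 10.0),
    taus: Sequence[float] = (0.0, 0.1, 0.2),
    seed: int = 0,
    t_end: float = 200.0,
    min_period: float = 0.01,
    return_details: bool = False,
):
    """Fraction of random parameter sets that oscillate, per condition.

    Each set draws the Hill-kinetics constants, epsilon (log-uniform)
    and k_X independently from ``ranges``.  A set is first checked for
    static bistability at its sampled ``a``; non-bistable sets count as
    non-oscillatory under every condition.  Bistable sets are simulated
    for ``t_end`` with Δa = i*a for each multiplier, each kappa and each
    delay, and count as oscillatory when the detected mean period
    exceeds ``min_period``.  Returns a DataFrame with one row per
    (i, kappa, tau) and the oscillating fraction.
    """
    import pandas as pd

    ranges = dict(SURVEY_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    conditions = [(i, k, tau) for i in i_multipliers for k in kappas for tau in taus]
    counts = {c: 0 for c in conditions}
    records = []
    n_bistable = 0
    for iset in range(n_sets):
        draw = {}
        for name, (lo, hi) in ranges.items():
            if name == "epsilon":
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[name] = float(rng.uniform(lo, hi))
        k_X = draw.pop("k_X")
        params = FeedbackParams(**draw)
        folds = switch_folds_exact(params, params.a)
        bistable = len(folds) == 2
        if bistable:
            n_bistable += 1
            up, down = folds[0].X, folds[1].X
            Xc = 0.5 * (folds[0].parameter + folds[1].parameter)
            dt = _rk4_dt_for(params, X_T_cap=max(5.0, 2 * folds[1].parameter))
        for (i, kappa, tau) in conditions:
            osc = False
            if bistable:
                mod = SwitchModulation(
                    a_bar=params.a, delta_a=i * params.a, kappa=kappa, X_c=Xc, tau=tau
                )
                period = _run_and_classify(
                    params, mod, k_X, t_end, up, down, min_period, dt=dt
                )
                osc = period > 0
            if osc:
                counts[(i, kappa, tau)] += 1
            if return_details:
                records.append(
                    {"set": iset, "i": i, "kappa": kappa, "tau": tau,
                     "bistable": bistable, "oscillates": osc}
                )
    summary = pd.DataFrame(
        [
            {"i": i, "kappa": k, "tau": tau,
             "n_oscillating": counts[(i, k, tau)],
             "fraction": counts[(i, k, tau)] / n_sets}
            for (i, k, tau) in conditions
        ]
    )
    summary.attrs["n_sets"] = n_sets
    summary.attrs["n_bistable"] = n_bistable
    summary.attrs["seed"] = seed
    if return_details:
        return summary, pd.DataFrame(records)
    return summary
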