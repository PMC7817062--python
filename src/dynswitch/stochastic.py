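"""Stochastic variants: Langevin equation and Gillespie simulation.

The Langevin model adds white noise of magnitude ``sigma`` to the fast
variable only (X_T evolves deterministically), integrated with
Euler–Maruyama and X clipped at zero.  The discrete model counts
molecules of active (n_X) and inactive (n_Y) protein and draws reaction
events with the Gillespie direct method; a system size ``Omega``
converts concentrations to counts, and the noise shrinks as Omega
grows.

Transition-timing experiments measure the first crossing of X above the
transition threshold (the average of the two saddle-node X coordinates
of the static switch) across replicates, and report mean, standard
deviation and coefficient of variation per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import _kernels
from .continuation import event_thresholds, midpoint_Xc
from .dynamics import Trajectory, detect_period
from .params import FeedbackParams, SwitchModulation, SystemState

__all__ = [
    "LangevinConfig",
    "SSAConfig",
    "simulate_langevin",
    "simulate_ssa",
    "transition_time",
    "cv_statistics",
    "CVStats",
    "run_timing_experiment",
]

_MODEL_CODES = {"transition": 0, "oscillator": 1, "oscillator_full": 2}


@dataclass(frozen=True)
class LangevinConfig:
    """Noise magnitude, step size, duration and seed of a Langevin run."""

    sigma: float = 0.6
    dt: float = 1e-3
    t_end: float = 10.0
    seed: int = 0
    store_every: int = 10

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class SSAConfig:
    """System size, duration and seed of a Gillespie run.

    ``include_degradation`` switches between the transition model
    (production only) and the oscillator (production plus degradation of
    both forms, the active form acting catalytically so the mean-field
    limit is dX_T/dt = k_X - X_T X).
    """

    omega: int = 20
    t_end: float = 10.0
    seed: int = 0
    include_degradation: bool = False
    dt_out: float = 1e-2

    def __post_init__(self) -> None:
        if int(self.omega) != self.omega or self.omega < 1:
            raise ValueError("omega must be a positive integer")


def _mod_scalars(params: FeedbackParams, mod: Optional[SwitchModulation]):
    if mod is None:
        return params.a, 0.0, 1.0, 0.0
    return mod.a_bar, mod.delta_a, mod.kappa, mod.X_c


def simulate_langevin(
    model: str,
    params: FeedbackParams,
    mod: Optional[SwitchModulation] = None,
    k_X: float = 1.0,
    config: LangevinConfig = LangevinConfig(),
    initial: Optional[SystemState] = None,
) -> Trajectory:
    """Euler–Maruyama run of the transition or oscillator model."""
    if model not in _MODEL_CODES:
        raise ValueError(f"unknown model {model!r}")
    if mod is not None and mod.tau > 0:
        raise ValueError("the Langevin variants support instantaneous modulation only")
    if initial is None:
        initial = SystemState(X=0.0, X_T=0.0)
    a_bar, da, kappa, Xc = _mod_scalars(params, mod)
    nsteps = max(1, int(round(config.t_end / config.dt)))
    t, X, XT = _kernels.langevin_em(
        _MODEL_CODES[model],
        params.b, params.K, params.n, params.a_prime, params.b_prime,
        params.K_prime, params.m, params.epsilon,
        a_bar, da, kappa, Xc,
        k_X, config.sigma,
        initial.X, initial.X_T,
        config.dt, nsteps, config.store_every, config.seed,
    )
    return Trajectory(
        times=t,
        data={"X": X, "X_T": XT},
        metadata={"model": f"langevin_{model}", "params": params, "mod": mod,
                  "k_X": k_X, "sigma": config.sigma, "seed": config.seed},
    )


def simulate_ssa(
    model: str,
    params: FeedbackParams,
    mod: Optional[SwitchModulation] = None,
    k_X: float = 1.0,
    config: SSAConfig = SSAConfig(),
    initial_counts: Optional[tuple] = None,
) -> Trajectory:
    """Gillespie direct-method run with integer molecule counts.

    ``model`` selects degradation: the transition model omits the two
    degradation reactions.  Default initial condition is n_X = 0,
    n_Y = 0.  The trajectory carries counts ``n_X``/``n_Y`` and the
    corresponding concentrations ``X``/``X_T`` (counts over Omega).
    """
    if model not in ("transition", "oscillator"):
        raise ValueError(f"unknown model {model!r}")
    include_deg = model == "oscillator" or config.include_degradation
    if mod is not None and mod.tau > 0:
        raise ValueError("the discrete model supports instantaneous modulation only")
    if initial_counts is None:
        initial_counts = (0, 0)
    nX0, nY0 = int(initial_counts[0]), int(initial_counts[1])
    a_bar, da, kappa, Xc = _mod_scalars(params, mod)
    t, nX, nY = _kernels.ssa_direct(
        include_deg,
        params.b, params.K, params.n, params.a_prime, params.b_prime,
        params.K_prime, params.m, params.epsilon,
        a_bar, da, kappa, Xc,
        k_X, float(config.omega),
        nX0, nY0,
        config.t_end, config.dt_out, config.seed,
    )
    omega = float(config.omega)
    return Trajectory(
        times=t,
        data={
            "n_X": nX,
            "n_Y": nY,
            "X": nX / omega,
            "X_T": (nX + nY) / omega,
        },
        metadata={"model": f"ssa_{model}", "params": params, "mod": mod,
                  "k_X": k_X, "omega": config.omega, "seed": config.seed},
    )


def transition_time(traj: Trajectory, threshold: float) -> Optional[float]:
    """First time X crosses above ``threshold``; None if it never does."""
    x = np.asarray(traj.X, dtype=float)
    above = x >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(t1)
    return float(t0 + (threshold - x0) / (x1 - x0) * (t1 - t0))


class CVStats(NamedTuple):
    mean: float
    sd: float
    cv: float


def cv_statistics(samples: Sequence[float]) -> CVStats:
    """Sample mean, sd (n-1 denominator) and coefficient of variation.

    Requires at least two samples; a nonpositive mean makes the CV
    undefined (returned as nan).
    """
    arr = np.asarray(samples, dtype=float)
    if len(arr) < 2:
        raise ValueError("cv_statistics requires at least 2 samples")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    cv = sd / mean if mean > 0 else math.nan
    return CVStats(mean, sd, cv)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Per-replicate 31-bit streams from one master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array([int(s) % (2**31 - 1) for s in ss.generate_state(n)])


def run_timing_experiment(
    variant: str,
    params: FeedbackParams,
    a_bar: float = 0.3,
    delta_a_values: Optional[Sequence[float]] = None,
    kappa_values: Optional[Sequence[float]] = None,
    kappa: float = 5.0,
    delta_a: float = 0.3,
    k_X: float = 1.0,
    sigma: float = 0.6,
    omega: int = 20,
    replicates: int = 200,
    seed: int = 0,
    experiment: str = "transition",
    t_end: Optional[float] = None,
    dt: float = 1e-3,
):
    """Transition-time (or oscillation-period) statistics per condition.

    One of ``delta_a_values`` or ``kappa_values`` defines the swept
    condition; the other modulation constant is held at ``delta_a`` /
    ``kappa``.  ``variant`` is ``langevin`` or ``ssa``.  For
    ``experiment='transition'`` each replicate runs the transition model
    until well past the static activation threshold and records the
    first crossing of the transition threshold; replicates that never
    cross are excluded and counted.  For ``experiment='period'`` the
    oscillator variant is run for a long time and all detected periods
    are pooled across replicates.

    Returns a DataFrame with one row per condition: mean, sd, CV and
    the number of excluded replicates.
    """
    import pandas as pd

    if variant not in ("langevin", "ssa"):
        raise ValueError("variant must be 'langevin' or 'ssa'")
    if (delta_a_values is None) == (kappa_values is None):
        raise ValueError("specify exactly one of delta_a_values / kappa_values")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")

    up, down, trans = event_thresholds(params, a_bar)
    Xc = midpoint_Xc(params, a_bar)
    if t_end is None:
        if experiment == "transition":
            # run until X_T is well past the right fold of every modulated
            # switch shape (the fold at a_bar - |da| sits furthest right)
            t_end = 2.5 * Xc / k_X
        else:
            t_end = 2000.0 if variant == "langevin" else 4000.0

    sweep = (
        [("delta_a", v) for v in delta_a_values]
        if delta_a_values is not None
        else [("kappa", v) for v in kappa_values]
    )
    seeds = _spawn_seeds(seed, replicates * len(sweep)).reshape(len(sweep), replicates)
    rows = []
    all_samples = {}
    for ci, (name, value) in enumerate(sweep):
        da = value if name == "delta_a" else delta_a
        kap = value if name == "kappa" else kappa
        mod = SwitchModulation(a_bar=a_bar, delta_a=da, kappa=kap, X_c=Xc)
        samples = []
        n_excluded = 0
        for r in range(replicates):
            s = int(seeds[ci, r])
            if experiment == "transition":
                if variant == "langevin":
                    traj = simulate_langevin(
                        "transition", params, mod, k_X,
                        LangevinConfig(sigma=sigma, dt=dt, t_end=t_end, seed=s),
                    )
                else:
                    traj = simulate_ssa(
                        "transition", params, mod, k_X,
                        SSAConfig(omega=omega, t_end=t_end, seed=s),
                    )
                    traj = Trajectory(
                        traj.times, {"X": traj.X}, traj.metadata
                    )
                tc = transition_time(traj, trans)
                if tc is None:
                    n_excluded += 1
                else:
                    samples.append(tc)
            else:
                if variant == "langevin":
                    traj = simulate_langevin(
                        "oscillator", params, mod, k_X,
                        LangevinConfig(sigma=sigma, dt=dt, t_end=t_end, seed=s),
                    )
                else:
                    traj = simulate_ssa(
                        "oscillator", params, mod, k_X,
                        SSAConfig(omega=omega, t_end=t_end, seed=s),
                    )
                stats = detect_period(traj, up, down)
                samples.extend(stats.periods.tolist())
        if len(samples) >= 2:
            stats = cv_statistics(samples)
        else:
            stats = CVStats(math.nan, math.nan, math.nan)
        rows.append(
            {name: value, "mean": stats.mean, "sd": stats.sd, "cv": stats.cv,
             "n_samples": len(samples), "n_excluded": n_excluded}
        )
        all_samples[value] = np.array(samples)
    df = pd.DataFrame(rows)
    df.attrs["variant"] = variant
    df.attrs["experiment"] = experiment
    df.attrs["seed"] = seed
    df.attrs["threshold"] = trans
    df.attrs["samples"] = all_samples
    return df
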