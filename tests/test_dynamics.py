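"""Deterministic simulation, event detection and oscillation analysis."""

import numpy as np
import pytest

from dynswitch import (
    SwitchModulation,
    SystemState,
    detect_amplitude,
    detect_period,
    simulate,
)
from dynswitch.dynamics import Trajectory, random_survey


def _tail(traj, t_from):
    n0 = np.searchsorted(traj.times, t_from)
    return Trajectory(traj.times[n0:], {"X": traj.X[n0:]}, traj.metadata)


class TestSimulate:
    def test_transition_jumps_at_the_fold(self, params, static_folds, thresholds):
        # X stays near the lower branch until X_T passes the right fold
        k_X = 0.2
        fold_XT = static_folds[1].parameter
        traj = simulate("transition", params, None, k_X, t_end=fold_XT / k_X + 4)
        up, down, trans = thresholds
        before = traj.X[traj.times < 0.9 * fold_XT / k_X]
        assert np.max(before) < down
        assert np.max(traj.X) > up

    def test_sustained_oscillation_at_intermediate_production(self, params, thresholds):
        traj = simulate("oscillator", params, None, 1.7, t_end=120, method="rk4")
        stats = detect_period(_tail(traj, 40), thresholds[0], thresholds[1])
        assert stats.oscillatory
        assert stats.period_mean > 0.5

    def test_period_constant_across_cycles(self, params, thresholds):
        traj = simulate("oscillator", params, None, 1.7, t_end=200, method="rk4")
        stats = detect_period(_tail(traj, 50), thresholds[0], thresholds[1])
        assert stats.period_sd / stats.period_mean < 1e-4

    def test_rk4_and_adaptive_integrator_agree_on_period(self, params, thresholds):
        up, down, _ = thresholds
        p_rk4 = detect_period(
            _tail(simulate("oscillator", params, None, 1.7, t_end=120, method="rk4"), 40),
            up, down,
        ).period_mean
        p_sci = detect_period(
            _tail(simulate("oscillator", params, None, 1.7, t_end=120, method="scipy"), 40),
            up, down,
        ).period_mean
        assert p_rk4 == pytest.approx(p_sci, rel=1e-4)

    def test_full_model_period_deviation_shrinks_with_epsilon(self, params, thresholds):
        # the dropped -X^2 term perturbs the period at O(eps)
        import dataclasses

        up, down, _ = thresholds
        rel_diffs = []
        for eps in (0.05, 0.005):
            p = dataclasses.replace(params, epsilon=eps)
            periods = {}
            for model in ("oscillator", "oscillator_full"):
                traj = simulate(model, p, None, 1.7, t_end=60, method="rk4",
                                dt=2e-4 if eps == 0.005 else 1e-3)
                periods[model] = detect_period(_tail(traj, 20), up, down).period_mean
            rel_diffs.append(
                abs(periods["oscillator"] - periods["oscillator_full"])
                / periods["oscillator"]
            )
        assert rel_diffs[1] < rel_diffs[0]

    def test_unknown_model_rejected(self, params):
        with pytest.raises(ValueError):
            simulate("nonsense", params)


class TestDelayAndThreeEquation:
    def test_zero_delay_matches_instantaneous_run(self, params, X_c):
        # tau -> 0 must reduce the delay machinery to the instantaneous law
        inst = SwitchModulation(0.3, 0.2, 5.0, X_c, tau=0.0)
        tiny = SwitchModulation(0.3, 0.2, 5.0, X_c, tau=1e-9)
        t1 = simulate("oscillator", params, inst, 1.7, t_end=30, method="rk4")
        t2 = simulate("oscillator", params, tiny, 1.7, t_end=30, method="rk4")
        # the delay path evaluates stage values from the interpolated
        # history, so agreement is at the discretization level O(dt^2)
        assert np.max(np.abs(t1.X - t2.X)) < 5e-3

    def test_delay_changes_the_trajectory(self, params, X_c):
        mod0 = SwitchModulation(0.3, 0.2, 5.0, X_c, tau=0.0)
        mod2 = SwitchModulation(0.3, 0.2, 5.0, X_c, tau=0.2)
        t0 = simulate("oscillator", params, mod0, 1.7, t_end=40, method="rk4")
        t2 = simulate("oscillator", params, mod2, 1.7, t_end=40, method="rk4")
        assert np.max(np.abs(t0.X - t2.X)) > 1e-2

    def test_fast_relaxation_approaches_two_equation_cycle(self, params, X_c, thresholds):
        up, down, _ = thresholds
        mod = SwitchModulation(0.3, 0.2, 5.0, X_c)
        p2 = detect_period(
            _tail(simulate("oscillator", params, mod, 1.7, t_end=100, method="rk4"), 30),
            up, down,
        ).period_mean
        p3 = detect_period(
            _tail(simulate("three_equation", params, mod, 1.7, t_end=100, delta=0.01), 30),
            up, down,
        ).period_mean
        assert p3 == pytest.approx(p2, rel=0.02)

    def test_slow_relaxation_freezes_a(self, params, X_c):
        # delta = 10: a barely moves over a cycle, the modulation averages out
        mod = SwitchModulation(0.3, 0.2, 5.0, X_c)
        traj = simulate("three_equation", params, mod, 1.7, t_end=100, delta=10.0)
        n0 = np.searchsorted(traj.times, 60)
        assert np.ptp(traj.a[n0:]) < 0.02

    def test_three_equation_requires_delta_and_mod(self, params, X_c):
        with pytest.raises(ValueError):
            simulate("three_equation", params, SwitchModulation(0.3, 0.2, 5.0, X_c), 1.7)
        with pytest.raises(ValueError):
            simulate("three_equation", params, None, 1.7, delta=0.1)


class TestDetectPeriod:
    def _square_wave(self):
        # X alternates 0 -> 2 with up-crossings at t = 1, 3, 5
        t = np.linspace(0, 6, 1201)
        X = ((t % 2) >= 1).astype(float) * 2.0
        return Trajectory(t, {"X": X})

    def test_square_wave_periods(self):
        stats = detect_period(self._square_wave(), up=1.5, down=0.5)
        assert stats.oscillatory
        assert np.allclose(stats.periods, 2.0, atol=0.01)

    def test_monotone_trajectory_is_non_oscillatory(self):
        t = np.linspace(0, 10, 300)
        stats = detect_period(Trajectory(t, {"X": 0.1 * t}), up=1.5, down=0.5)
        assert not stats.oscillatory

    def test_repeated_same_direction_crossings_are_deduplicated(self):
        # small wiggle around the up threshold only: no full excursion
        t = np.linspace(0, 20, 4001)
        X = 1.5 + 0.2 * np.sin(2 * np.pi * t)  # crosses up=1.5 repeatedly
        stats = detect_period(Trajectory(t, {"X": X}), up=1.5, down=0.5)
        assert not stats.oscillatory

    def test_nan_trajectory_is_non_oscillatory(self):
        t = np.linspace(0, 5, 100)
        X = np.full_like(t, np.nan)
        assert not detect_period(Trajectory(t, {"X": X}), 1.0, 0.5).oscillatory


class TestDetectAmplitude:
    def test_sinusoid_amplitude(self):
        t = np.linspace(0, 50, 5000)
        traj = Trajectory(t, {"X": 1.0 + np.sin(2 * np.pi * t / 5)})
        stats = detect_amplitude(traj)
        assert len(stats.amplitudes) >= 5
        assert stats.amplitude_mean == pytest.approx(2.0, rel=0.05)

    def test_constant_signal_has_no_amplitude(self):
        t = np.linspace(0, 50, 500)
        stats = detect_amplitude(Trajectory(t, {"X": np.full_like(t, 1.0)}))
        assert len(stats.amplitudes) == 0

    def test_noisy_sinusoid_envelope_recovered(self, rng):
        t = np.linspace(0, 50, 5000)
        X = 1.0 + np.sin(2 * np.pi * t / 5) + 0.05 * rng.standard_normal(len(t))
        stats = detect_amplitude(Trajectory(t, {"X": X}))
        assert stats.amplitude_mean == pytest.approx(2.0, rel=0.05)


class TestTrajectoryContainer:
    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0, 1.0]), {"X": np.zeros(3)})

    def test_rejects_misaligned_columns(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), {"X": np.zeros(3)})

    def test_state_bound_preserved(self, params):
        # 0 <= X <= X_T along deterministic trajectories
        traj = simulate("transition", params, None, 0.5, t_end=8, method="scipy")
        assert np.all(traj.X >= -1e-6)
        assert np.all(traj.X <= traj.X_T + 1e-6)


class TestRandomSurveyGating:
    def test_non_bistable_sets_never_oscillate(self):
        # narrow ranges drawn around a shallow, monostable response
        ranges = {
            "a": (0.55, 0.6), "a_prime": (0.4, 0.5), "b": (0.5, 0.6),
            "b_prime": (0.5, 0.6), "K": (1.8, 2.0), "K_prime": (0.5, 0.6),
            "n": (2.0, 2.2), "m": (2.0, 2.2), "k_X": (0.5, 3.0),
            "epsilon": (0.05, 0.5),
        }
        summary, details = random_survey(
            ranges=ranges, n_sets=12, i_multipliers=(0.0, 1.0),
            kappas=(5.0,), taus=(0.0,), seed=3, t_end=50, return_details=True,
        )
        non_bistable = details[~details["bistable"]]
        assert len(non_bistable) > 0
        assert not non_bistable["oscillates"].any()

    def test_dynamic_switch_does_not_reduce_oscillation_count(self):
        summary = random_survey(
            n_sets=25, i_multipliers=(0.0, 1.0), kappas=(5.0,), taus=(0.1,),
            seed=11, t_end=100,
        )
        f0 = summary.query("i == 0.0")["fraction"].iloc[0]
        f1 = summary.query("i == 1.0")["fraction"].iloc[0]
        assert f1 >= f0
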