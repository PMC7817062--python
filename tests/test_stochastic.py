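"""Langevin and discrete stochastic variants."""

import numpy as np
import pytest

from dynswitch import (
    LangevinConfig,
    SSAConfig,
    SwitchModulation,
    cv_statistics,
    run_timing_experiment,
    simulate,
    simulate_langevin,
    simulate_ssa,
    transition_time,
)
from dynswitch.dynamics import Trajectory
from dynswitch.params import FeedbackParams


class TestLangevin:
    def test_noise_free_limit_matches_ode(self, params):
        cfg = LangevinConfig(sigma=0.0, dt=1e-4, t_end=4.0, seed=0, store_every=100)
        noisy = simulate_langevin("transition", params, None, 1.0, cfg)
        ode = simulate("transition", params, None, 1.0, t_end=4.0, method="scipy")
        interp = np.interp(noisy.times, ode.times, ode.X)
        assert np.max(np.abs(noisy.X - interp)) < 1e-3

    def test_reproducible_with_same_seed(self, params):
        cfg = LangevinConfig(sigma=0.6, dt=1e-3, t_end=2.0, seed=17)
        t1 = simulate_langevin("transition", params, None, 1.0, cfg)
        t2 = simulate_langevin("transition", params, None, 1.0, cfg)
        assert np.array_equal(t1.X, t2.X)

    def test_concentration_clipped_at_zero(self, params):
        cfg = LangevinConfig(sigma=1.5, dt=1e-3, t_end=3.0, seed=5)
        traj = simulate_langevin("transition", params, None, 0.5, cfg)
        assert np.all(traj.X >= 0)

    def test_delay_rejected(self, params, X_c):
        mod = SwitchModulation(0.3, 0.2, 5.0, X_c, tau=0.1)
        with pytest.raises(ValueError):
            simulate_langevin("transition", params, mod, 1.0, LangevinConfig())


class TestTransitionTime:
    def test_constructed_jump(self):
        t = np.linspace(0, 10, 1001)
        X = np.where(t < 4.2, 0.1, 2.0)
        traj = Trajectory(t, {"X": X})
        tc = transition_time(traj, threshold=1.0)
        assert tc == pytest.approx(4.2, abs=0.02)

    def test_flat_trajectory_has_no_transition(self):
        t = np.linspace(0, 10, 101)
        assert transition_time(Trajectory(t, {"X": np.full_like(t, 0.1)}), 1.0) is None

    def test_deterministic_transition_near_static_fold(self, params, static_folds, thresholds):
        # with a static switch and no noise, the jump happens just after
        # X_T passes the right fold; the lag is a few multiples of eps
        k_X = 1.0
        traj = simulate("transition", params, None, k_X, t_end=4.0, method="scipy")
        tc = transition_time(traj, thresholds[2])
        t_fold = static_folds[1].parameter / k_X
        assert tc is not None
        assert tc > t_fold
        assert tc - t_fold < 0.3


class TestCVStatistics:
    def test_constant_samples(self):
        assert cv_statistics([2, 2, 2]).cv == 0.0

    def test_two_samples_closed_form(self):
        stats = cv_statistics([1.0, 3.0])
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(np.sqrt(2.0))
        assert stats.cv == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cv_statistics([1.0])

    def test_nonpositive_mean_flagged(self):
        assert np.isnan(cv_statistics([-1.0, 1.0]).cv)


class TestSSA:
    def test_counts_are_consistent(self, params):
        traj = simulate_ssa(
            "transition", params, None, 1.0, SSAConfig(omega=20, t_end=4.0, seed=2)
        )
        assert np.all(traj.n_X >= 0) and np.all(traj.n_Y >= 0)
        assert np.issubdtype(traj.n_X.dtype, np.integer)
        assert np.all(traj.n_X <= traj.n_X + traj.n_Y)

    def test_pure_production_is_poisson(self, params):
        # with a = 0 and no molecules, only the production channel fires:
        # n_Y(t) ~ Poisson(k_X * Omega * t)
        p = FeedbackParams(a=0.0)
        omega, k_X, t_end = 20, 1.0, 5.0
        finals = []
        for seed in range(40):
            traj = simulate_ssa(
                "transition", p, None, k_X, SSAConfig(omega=omega, t_end=t_end, seed=seed)
            )
            assert np.all(traj.n_X == 0)
            finals.append(traj.n_Y[-1])
        lam = k_X * omega * t_end
        assert np.mean(finals) == pytest.approx(lam, rel=0.15)
        assert np.var(finals) == pytest.approx(lam, rel=0.5)

    def test_ensemble_mean_error_decreases_with_system_size(self, params):
        ode = simulate("transition", params, None, 1.0, t_end=4.0, method="scipy")
        grid = np.arange(0.0, 4.0, 0.01)
        ode_X = np.interp(grid, ode.times, ode.X)
        errors = []
        for omega in (10, 50, 200):
            acc = np.zeros_like(grid)
            reps = 20
            for s in range(reps):
                traj = simulate_ssa(
                    "transition", params, None, 1.0,
                    SSAConfig(omega=omega, t_end=4.0, seed=1000 + s),
                )
                acc += np.interp(grid, traj.times, traj.X)
            errors.append(np.max(np.abs(acc / reps - ode_X)))
        assert errors[0] > errors[1] > errors[2]

    def test_reproducible_with_same_seed(self, params):
        cfg = SSAConfig(omega=20, t_end=3.0, seed=9)
        t1 = simulate_ssa("transition", params, None, 1.0, cfg)
        t2 = simulate_ssa("transition", params, None, 1.0, cfg)
        assert np.array_equal(t1.n_X, t2.n_X)


class TestTimingExperiments:
    def test_dynamic_switch_tightens_transition_times(self, params):
        df = run_timing_experiment(
            "langevin", params, delta_a_values=[0.0, 0.3], replicates=100, seed=4
        )
        cv0 = df.loc[df["delta_a"] == 0.0, "cv"].iloc[0]
        cv3 = df.loc[df["delta_a"] == 0.3, "cv"].iloc[0]
        assert cv3 < cv0

    def test_sd_non_increasing_in_delta_a(self, params):
        df = run_timing_experiment(
            "langevin", params, delta_a_values=[0.0, 0.1, 0.2, 0.3],
            replicates=200, seed=8,
        )
        sd = df["sd"].to_numpy()
        # monotone trend allowing sampling error
        assert np.all(sd[1:] <= sd[:-1] * 1.15)
        assert sd[-1] < sd[0]

    def test_ssa_effect_smaller_than_langevin(self, params):
        lan = run_timing_experiment(
            "langevin", params, delta_a_values=[0.0, 0.3], replicates=100, seed=6
        )
        ssa = run_timing_experiment(
            "ssa", params, delta_a_values=[0.0, 0.3], replicates=100, omega=20, seed=6
        )
        gap_lan = lan["cv"].iloc[0] - lan["cv"].iloc[1]
        gap_ssa = ssa["cv"].iloc[0] - ssa["cv"].iloc[1]
        assert gap_ssa < gap_lan

    def test_period_experiment_reports_cycles(self, params):
        df = run_timing_experiment(
            "langevin", params, delta_a_values=[0.3], k_X=1.7,
            replicates=2, seed=12, experiment="period", t_end=200.0,
        )
        assert df["n_samples"].iloc[0] > 20
        assert df["cv"].iloc[0] > 0

    def test_invalid_sweep_specification(self, params):
        with pytest.raises(ValueError):
            run_timing_experiment("langevin", params, replicates=10, seed=0)
        with pytest.raises(ValueError):
            run_timing_experiment(
                "langevin", params, delta_a_values=[0.0], kappa_values=[5.0],
                replicates=10, seed=0,
            )
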