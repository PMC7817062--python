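"""Response-curve continuation against the brute-force root oracle."""

import numpy as np
import pytest

from dynswitch import (
    FeedbackParams,
    bistable_region_2d,
    event_thresholds,
    midpoint_Xc,
    steady_states_bruteforce,
    switch_folds_exact,
    trace_response_curve,
)
from dynswitch.continuation import _residual


class TestBruteForce:
    def test_zero_total_protein(self, params):
        assert steady_states_bruteforce(params, 0.3, 0.0) == [(0.0, True)]

    def test_low_total_single_root(self, params):
        roots = steady_states_bruteforce(params, 0.3, 0.1)
        assert len(roots) == 1
        X, stable = roots[0]
        assert stable
        # Hill terms are negligible at X ~ 0.02, so the linearized root
        # a X_T / (a + a' + b') is an independent check
        assert X == pytest.approx(0.3 * 0.1 / (0.3 + 0.1 + 1.0), rel=1e-3)

    def test_bistable_band_has_three_roots(self, params, static_folds):
        mid = 0.5 * (static_folds[0].parameter + static_folds[1].parameter)
        roots = steady_states_bruteforce(params, 0.3, mid)
        assert len(roots) == 3
        assert [s for _, s in roots] == [True, False, True]


class TestContinuation:
    def test_points_satisfy_steady_state_equation(self, params):
        curve = trace_response_curve(params, "X_T", 0.3, p_range=(0.0, 5.0))
        F, _, _ = _residual(curve.X, curve.parameter, params, 0.3, "X_T")
        assert np.max(np.abs(F)) < 1e-8

    def test_two_saddle_nodes_at_standard_a(self, params):
        curve = trace_response_curve(params, "X_T", 0.3, p_range=(0.0, 5.0))
        assert len(curve.saddle_nodes) == 2
        exact = switch_folds_exact(params, 0.3)
        for sn, ref in zip(curve.saddle_nodes, exact):
            assert sn.parameter == pytest.approx(ref.parameter, abs=1e-8)
            assert sn.X == pytest.approx(ref.X, abs=1e-8)

    def test_saddle_node_residuals(self, params):
        curve = trace_response_curve(params, "X_T", 0.3, p_range=(0.0, 5.0))
        for sn in curve.saddle_nodes:
            F, F_X, _ = _residual(sn.X, sn.parameter, params, 0.3, "X_T")
            assert abs(F) < 1e-8 and abs(F_X) < 1e-8

    def test_monotone_curve_at_high_a(self, params):
        curve = trace_response_curve(params, "X_T", 0.8, p_range=(0.0, 5.0))
        assert curve.saddle_nodes == []
        assert np.all(np.diff(curve.parameter) > 0)
        assert np.all(curve.stable)

    def test_stability_flips_exactly_at_folds(self, params):
        curve = trace_response_curve(params, "X_T", 0.3, p_range=(0.0, 5.0))
        flips = np.nonzero(np.diff(curve.stable.astype(int)))[0]
        assert len(flips) == 2

    def test_irreversible_switch_fold_at_negative_a(self, params):
        # at high fixed X_T the deactivation fold sits at a < 0
        curve = trace_response_curve(params, "a", fixed_value=3.0, p_range=(-2.0, 1.0))
        assert len(curve.saddle_nodes) == 2
        assert curve.saddle_nodes[0].parameter < 0.0
        assert curve.saddle_nodes[1].parameter > 0.0

    def test_agreement_with_bruteforce_on_random_slices(self, params, rng):
        # root counts and values match the oracle on random slices
        from dynswitch.continuation import slice_states

        for _ in range(15):
            a = rng.uniform(0.05, 0.6)
            curve = trace_response_curve(params, "X_T", a, p_range=(0.0, 6.0))
            for _ in range(4):
                X_T = rng.uniform(0.1, 5.5)
                expected = steady_states_bruteforce(params, a, X_T)
                found = slice_states(curve, X_T, params, a)
                assert len(found) == len(expected)
                for (x, stable), (ref, ref_stable) in zip(found, expected):
                    assert x == pytest.approx(ref, abs=1e-6)
                    assert stable == ref_stable

    def test_fold_count_zero_or_two(self, params):
        # a = 0 is excluded: there the activation threshold diverges and
        # only the upper fold exists in any finite window
        for a in np.linspace(0.05, 1.0, 20):
            p = FeedbackParams(a=a)
            folds = switch_folds_exact(p, a)
            assert len(folds) in (0, 2)


class TestConventions:
    def test_midpoint_is_mean_of_fold_coordinates(self, params, static_folds):
        expected = 0.5 * (static_folds[0].parameter + static_folds[1].parameter)
        assert midpoint_Xc(params, 0.3) == pytest.approx(expected, abs=1e-10)

    def test_event_thresholds_match_fold_verticals(self, params, static_folds):
        up, down, trans = event_thresholds(params, 0.3)
        assert up == pytest.approx(static_folds[0].X, abs=1e-10)
        assert down == pytest.approx(static_folds[1].X, abs=1e-10)
        assert trans == pytest.approx(0.5 * (up + down))
        assert up > down  # the left fold sits on the upper knee

    def test_monotone_switch_raises(self, params):
        with pytest.raises(ValueError, match="not bistable"):
            midpoint_Xc(params, 0.9)
        with pytest.raises(ValueError, match="not bistable"):
            event_thresholds(params, 0.9)


class TestBistableRegion:
    def test_boundary_matches_bruteforce_root_counts(self, params):
        a_grid = np.linspace(0.05, 0.7, 14)
        boundary = {a: (lo, hi) for a, lo, hi in bistable_region_2d(params, a_grid)}
        for a in a_grid:
            a = float(a)
            if a in boundary:
                lo, hi = boundary[a]
                inside = steady_states_bruteforce(params, a, 0.5 * (lo + hi))
                below = steady_states_bruteforce(params, a, 0.9 * lo)
                above = steady_states_bruteforce(params, a, 1.1 * hi)
                assert len(inside) == 3
                assert len(below) == 1 and len(above) == 1
            else:
                # slices with no folds contribute no boundary points
                for X_T in (0.5, 2.0, 4.0):
                    assert len(steady_states_bruteforce(params, a, X_T)) == 1

    def test_standard_a_slice_reproduces_folds(self, params, static_folds):
        boundary = bistable_region_2d(params, [0.3])
        assert len(boundary) == 1
        _, lo, hi = boundary[0]
        assert lo == pytest.approx(static_folds[0].parameter, abs=1e-8)
        assert hi == pytest.approx(static_folds[1].parameter, abs=1e-8)
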