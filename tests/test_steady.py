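"""Fixed-point analysis: bisection vs brute force, pressure invariance,
and phase-space classification."""

import numpy as np
import pytest

from seedshell import (
    ModelParameters,
    SystemState,
    hill,
    predict_pressure_invariance,
    simulate,
    solve_fixed_points,
    stream_map,
)
from seedshell.integrate import IntegrationConfig

FIG_PARAMS = ModelParameters(alpha=1.0, gamma=5.0, eta=5.0, rho=8.0)


def brute_force_sign_changes(params, n=2000):
    """Independent oracle: count sign changes of g(x) = 1 + alpha*H(x) - x
    on a dense grid over (0, 1 + alpha]."""
    x = np.geomspace(1e-6, 1.0 + params.alpha, n)
    g = 1.0 + params.alpha * hill(x, params.rho, params.eta) - x
    s = np.sign(g)
    # a saturated Hill response can make g vanish exactly at a grid point
    # (a root at floating-point precision); count those alongside strict
    # sign changes
    return int(np.sum(s[:-1] * s[1:] < 0)) + int(np.sum(g == 0.0))


class TestFixedPoints:
    def test_roots_satisfy_equation(self):
        fp = solve_fixed_points(FIG_PARAMS)
        for x in fp.roots:
            resid = 1.0 + FIG_PARAMS.alpha * hill(x, FIG_PARAMS.rho, FIG_PARAMS.eta) - x
            assert abs(resid) < 1e-10
            assert x <= fp.max_attainable_stress

    def test_step_limit_root_at_saturation(self):
        """With a near-step Hill response below 1 + alpha, the growing
        branch arrests at x* = 1 + alpha."""
        params = ModelParameters(alpha=3.0, gamma=1.0, eta=50.0, rho=1.0)
        fp = solve_fixed_points(params)
        assert fp.exists
        assert max(fp.roots) == pytest.approx(4.0, abs=1e-6)

    def test_high_threshold_leaves_only_trivial_root(self):
        """At the phase-portrait reference parameters the only balance is
        the trivial one just above x = 1; growth beyond it cannot arrest."""
        fp = solve_fixed_points(FIG_PARAMS)
        assert not fp.exists
        assert len(fp.roots) == 1
        assert fp.roots[0] == pytest.approx(1.0, abs=1e-3)
        assert not any(x > 1.1 for x in fp.roots)

    def test_bisection_agrees_with_brute_force_scan(self):
        """Root counts from bisection match a 2000-point sign scan for 100
        random parameter sets."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            params = ModelParameters(
                alpha=float(np.exp(rng.uniform(np.log(0.5), np.log(20)))),
                gamma=1.0,
                eta=float(np.exp(rng.uniform(0, np.log(30)))),
                rho=float(np.exp(rng.uniform(np.log(0.5), np.log(10)))),
            )
            fp = solve_fixed_points(params)
            assert len(fp.roots) == brute_force_sign_changes(params)


class TestPressureInvariance:
    @pytest.mark.parametrize("p_pair", [(0.5, 1.5), (0.1, 10.0)])
    def test_invariance_claim(self, p_pair):
        assert predict_pressure_invariance(FIG_PARAMS, *p_pair)

    def test_matched_initial_stress_gives_identical_rigidity(self):
        """Doubling pressure while halving the initial radius leaves the
        rigidity series identical and scales the radius series exactly."""
        params = ModelParameters(alpha=3.0, gamma=5.0, eta=10.0, rho=1.5)
        config = IntegrationConfig(t_end=10.0, dt=0.005)
        a = simulate(params, 1.0, SystemState(r=1.2, k=1.0), config)
        b = simulate(params, 2.0, SystemState(r=0.6, k=1.0), config)
        np.testing.assert_array_equal(a.k, b.k)
        np.testing.assert_allclose(a.r, 2.0 * b.r, rtol=1e-12)
        assert a.outcome == b.outcome

    def test_no_stiffening_trivial_invariance(self):
        params = ModelParameters(alpha=0.0, gamma=1.0, eta=1.0, rho=1.0)
        assert predict_pressure_invariance(params, 0.5, 1.5)


class TestStreamMap:
    def test_reference_parameters_show_all_three_regimes(self):
        smap = stream_map(FIG_PARAMS, p=1.0)
        counts = smap.class_counts()
        assert counts.get("no_growth", 0) > 0
        assert counts.get("converged", 0) > 0
        assert counts.get("diverged", 0) > 0

    def test_no_return_region_never_grows(self):
        """Starts below the strain threshold whose rigidity target exceeds
        their stress can never grow; starts below threshold but with a
        decaying rigidity may still take off later."""
        smap = stream_map(FIG_PARAMS, p=1.0, n_grid=8)
        rr, kk = np.meshgrid(smap.r_grid, smap.k_grid, indexing="ij")
        x = 1.0 * rr
        below = x / kk <= 1.0
        target = 1.0 + FIG_PARAMS.alpha * hill(x, FIG_PARAMS.rho, FIG_PARAMS.eta)
        no_return = below & (target >= x)
        assert no_return.any()
        assert np.all(smap.classes[no_return] == "no_growth")

    def test_strong_fast_stiffening_converges_growing_starts(self):
        params = ModelParameters(alpha=10.0, gamma=10.0, eta=10.0, rho=1.05)
        smap = stream_map(params, p=1.0, r_range=(1.02, 1.3), k_range=(0.9, 1.0), n_grid=4)
        growing = smap.classes != "no_growth"
        assert growing.any()
        assert np.all(smap.classes[growing] == "converged")

    def test_soft_landing_final_stress_lies_on_root(self):
        """With fast stiffening the rigidity tracks its nullcline and the
        trajectory lands on the fixed point: the final stress matches a
        root of x = 1 + alpha*H(x)."""
        params = ModelParameters(alpha=4.0, gamma=50.0, eta=10.0, rho=3.0)
        roots = solve_fixed_points(params).roots
        traj = simulate(params, 1.0, SystemState(r=1.1, k=1.0),
                        IntegrationConfig(t_end=50.0, dt=0.005))
        assert traj.outcome == "converged"
        final_stress = 1.0 * traj.r[-1]
        assert min(abs(final_stress - x) for x in roots) < 1e-4

    def test_overshoot_arrest_freezes_below_root(self):
        """An arrest where the rigidity overtakes the stress from below
        freezes the radius strictly below the root; the steady stress is
        bounded by the largest root rather than equal to it."""
        params = ModelParameters(alpha=3.0, gamma=5.0, eta=10.0, rho=1.5)
        roots = solve_fixed_points(params).roots
        traj = simulate(params, 1.0, SystemState(r=1.1, k=1.0),
                        IntegrationConfig(t_end=50.0, dt=0.005))
        assert traj.outcome == "converged"
        assert 1.0 * traj.r[-1] <= max(roots) + 1e-9

    def test_frames_round_trip_grid_size(self):
        smap = stream_map(FIG_PARAMS, p=1.0, n_grid=5)
        assert len(smap.to_frame()) == 25
        assert len(smap.nullcline_frame()) == 5
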