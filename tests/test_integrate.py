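"""Integrator tests against the analytic oracles and its own contracts."""

import numpy as np
import pytest

from seedshell import (
    IntegrationConfig,
    ModelParameters,
    SystemState,
    blow_up_time,
    closed_form_k_relaxation,
    closed_form_no_stiffening,
    hill,
    simulate,
    simulate_batch,
    simulate_days,
)
from seedshell.pressure import ConstantPressure, PressureDrop

NO_STIFFENING = ModelParameters(alpha=0.0, gamma=1.0, eta=1.0, rho=1.0)


class TestClosedForms:
    def test_initial_condition(self):
        assert closed_form_no_stiffening(2.0, 1.0, 0.0) == pytest.approx(2.0)
        assert closed_form_k_relaxation(2.0, 5.0, 0.0, 0.0) == pytest.approx(2.0)

    def test_growth_only_value(self):
        assert closed_form_no_stiffening(2.0, 1.0, 0.5) == pytest.approx(5.69344, abs=1e-4)

    def test_blow_up_domain(self):
        t_star = blow_up_time(2.0, 1.0)
        assert t_star == pytest.approx(np.log(2.0))
        with pytest.raises(ValueError):
            closed_form_no_stiffening(2.0, 1.0, t_star)
        with pytest.raises(ValueError):
            blow_up_time(0.5, 1.0)

    def test_relaxation_fixed_point(self):
        assert closed_form_k_relaxation(1.5, 3.0, 0.5, 7.0) == pytest.approx(1.5)

    def test_relaxation_value(self):
        assert closed_form_k_relaxation(2.0, 5.0, 0.0, 0.2) == pytest.approx(
            1.0 + np.exp(-1.0), rel=1e-12
        )


class TestSimulateOracles:
    def test_growth_matches_closed_form_to_blow_up(self):
        """With stiffening off and k0 = 1, RK4 tracks the exact blow-up
        solution to 1e-6 relative up to 90% of the blow-up time."""
        t_star = blow_up_time(2.0, 1.0)
        config = IntegrationConfig(t_end=0.9 * t_star, dt=1e-3, r_cap=1e6)
        traj = simulate(NO_STIFFENING, 1.0, SystemState(r=2.0, k=1.0), config)
        exact = closed_form_no_stiffening(2.0, 1.0, traj.times)
        np.testing.assert_allclose(traj.r, exact, rtol=1e-6)

    def test_divergence_detected_near_blow_up(self):
        config = IntegrationConfig(t_end=2.0, dt=1e-3)
        traj = simulate(NO_STIFFENING, 1.0, SystemState(r=2.0, k=1.0), config)
        assert traj.outcome == "diverged"
        assert traj.times[traj.event_index] == pytest.approx(np.log(2.0), abs=0.05)

    def test_rigidity_matches_exponential_relaxation(self):
        """With the radius below the growth threshold the stress is frozen
        and k relaxes exponentially to 1 + alpha*H at rate gamma."""
        params = ModelParameters(alpha=1.0, gamma=5.0, eta=2.0, rho=1.0)
        config = IntegrationConfig(t_end=2.0, dt=1e-3)
        traj = simulate(params, 1.0, SystemState(r=0.5, k=2.0), config)
        alpha_h = params.alpha * hill(0.5, params.rho, params.eta)
        exact = closed_form_k_relaxation(2.0, 5.0, alpha_h, traj.times)
        assert traj.outcome == "no_growth"
        np.testing.assert_allclose(traj.r, 0.5, rtol=0, atol=0)
        np.testing.assert_allclose(traj.k, exact, rtol=0, atol=1e-8)

    def test_no_growth_below_threshold(self):
        traj = simulate(NO_STIFFENING, 1.0, SystemState(r=0.5, k=1.0))
        assert traj.outcome == "no_growth"
        assert traj.final_relative_radius == 1.0

    def test_halving_dt_leaves_converged_radius(self):
        params = ModelParameters(alpha=3.0, gamma=5.0, eta=10.0, rho=1.5)
        init = SystemState(r=1.1, k=1.0)
        fine = simulate(params, 1.0, init, IntegrationConfig(t_end=20.0, dt=0.0025))
        coarse = simulate(params, 1.0, init, IntegrationConfig(t_end=20.0, dt=0.005))
        assert coarse.outcome == "converged"
        assert fine.final_relative_radius == pytest.approx(
            coarse.final_relative_radius, rel=1e-6
        )

    @pytest.mark.parametrize("r_cap", [50.0, 100.0, 200.0])
    def test_outcome_invariant_to_divergence_cap(self, r_cap):
        params = ModelParameters(alpha=3.0, gamma=5.0, eta=10.0, rho=1.5)
        traj = simulate(
            params, 1.0, SystemState(r=1.1, k=1.0), IntegrationConfig(r_cap=r_cap)
        )
        assert traj.outcome == "converged"


class TestTrajectoryContracts:
    def test_series_invariants(self):
        params = ModelParameters(alpha=2.0, gamma=2.0, eta=5.0, rho=1.5)
        traj = simulate(params, 1.2, SystemState(r=1.0, k=1.0))
        assert np.all(np.diff(traj.r) >= 0)
        np.testing.assert_allclose(traj.strain, traj.stress / traj.k, rtol=0, atol=0)
        assert len(traj.times) == len(traj.r) == len(traj.k)

    def test_time_varying_pressure_days(self):
        drop = PressureDrop(p_start=1.0, p_end=0.55, t_mid=4.0, width=1.0)
        params = ModelParameters(alpha=3.0, gamma=2.0, eta=8.0, rho=2.0)
        traj = simulate_days(params, drop, SystemState(r=1.3, k=1.0), tau=1.5)
        assert traj.time_unit == "days"
        # stress follows the declining pressure once growth stops
        assert traj.stress[-1] < traj.stress[np.argmax(traj.stress)]

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            ConstantPressure(0.0)


class TestBatch:
    def test_batch_of_one_equals_single(self):
        params = ModelParameters(alpha=2.0, gamma=2.0, eta=5.0, rho=1.5)
        init = SystemState(r=1.2, k=1.0)
        single = simulate(params, 1.0, init)
        (batch,) = simulate_batch([params], 1.0, [init])
        np.testing.assert_array_equal(single.r, batch.r)
        np.testing.assert_array_equal(single.k, batch.k)
        assert single.outcome == batch.outcome

    def test_batch_matches_elementwise_loop(self):
        rng = np.random.default_rng(7)
        params_list = [
            ModelParameters(
                alpha=float(rng.uniform(0.5, 10)),
                gamma=float(rng.uniform(0.5, 20)),
                eta=float(rng.uniform(1, 20)),
                rho=float(rng.uniform(0.5, 8)),
            )
            for _ in range(100)
        ]
        init_list = [
            SystemState(r=float(rng.uniform(0.5, 2.0)), k=float(rng.uniform(0.5, 2.0)))
            for _ in range(100)
        ]
        config = IntegrationConfig(t_end=5.0, dt=0.01)
        batch = simulate_batch(params_list, 1.0, init_list, config)
        for p, s, b in zip(params_list, init_list, batch):
            single = simulate(p, 1.0, s, config)
            np.testing.assert_allclose(b.r, single.r, rtol=1e-12)
            np.testing.assert_allclose(b.k, single.k, rtol=1e-12)
            assert b.outcome == single.outcome

    def test_mismatched_lengths_rejected(self):
        params = ModelParameters(alpha=1.0, gamma=1.0, eta=1.0, rho=1.0)
        with pytest.raises(ValueError):
            simulate_batch([params], 1.0, [])
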