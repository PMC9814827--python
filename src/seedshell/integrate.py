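"""Fixed-step RK4 integration of the shell model with outcome classification.

Trajectories are integrated on a fixed time grid (classic 4th-order
Runge-Kutta; the two-ODE system is non-stiff away from blow-up) and
classified by their fate:

* divergence — the radius exceeds ``r_cap`` times its initial value, or the
  state becomes non-finite (runaway growth with no stiffening arrest);
* steady state — either both the dimensionless growth rate ``|dr/dt|/r`` and
  the stiffening rate ``|dk/dt|`` fall below ``steady_tol``, or the exact
  *arrest latch* fires: for a non-increasing pressure input with infimum
  ``p_inf``, once the strain is at or below the growth threshold and the
  rigidity target at the lowest attainable stress already exceeds the
  current stress (``1 + alpha*H(p_inf*r) >= p*r``), growth can never resume
  — the radius is frozen exactly and the rigidity relaxes monotonically
  among targets that all stay above every future stress value;
* otherwise the horizon ``t_end`` is reached and the outcome is unresolved.

When the rate criterion exits early the state is frozen for the remainder of
the grid so that every trajectory shares the full time grid; when only the
arrest latch has fired the state (a frozen radius, a still-relaxing
rigidity) keeps being integrated to the horizon and the *outcome* records
the decided fate.  Outcomes:

* ``no_growth``   — the strain never exceeded the growth threshold;
* ``converged``   — the shell grew and reached (or is irrevocably bound
  for) a steady state;
* ``diverged``    — runaway growth;
* ``unresolved``  — fate undecided at the horizon.

Two analytic solutions of the decoupled limits are provided as oracles:
the no-stiffening finite-time blow-up and the frozen-stress exponential
rigidity relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import ModelParameters, SystemState
from .pressure import PressureInput

__all__ = [
    "IntegrationConfig",
    "Trajectory",
    "simulate",
    "simulate_days",
    "simulate_batch",
    "closed_form_no_stiffening",
    "closed_form_k_relaxation",
    "OUTCOME_NO_GROWTH",
    "OUTCOME_CONVERGED",
    "OUTCOME_DIVERGED",
    "OUTCOME_UNRESOLVED",
]

OUTCOME_NO_GROWTH = "no_growth"
OUTCOME_CONVERGED = "converged"
OUTCOME_DIVERGED = "diverged"
OUTCOME_UNRESOLVED = "unresolved"

_OUTCOME_BY_CODE = {
    0: OUTCOME_NO_GROWTH,
    1: OUTCOME_CONVERGED,
    2: OUTCOME_DIVERGED,
    3: OUTCOME_UNRESOLVED,
}


@dataclass(frozen=True)
class IntegrationConfig:
    """Grid and event thresholds for the fixed-step integrator.

    ``t_end`` and ``dt`` are in the time unit of the grid (dimensionless by
    default; days when used through `simulate_days`).  ``r_cap`` is the
    divergence cap as a multiple of the initial radius; biologically relevant
    final radii are below 4x, so 100x unambiguously flags runaway growth.
    ``steady_tol`` bounds the dimensionless rates for steady-state detection
    and sits far below measurement noise.
    """

    t_end: float = 20.0
    dt: float = 0.005
    r_cap: float = 100.0
    steady_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.t_end > 0):
            raise ValueError("dt and t_end must be positive")
        if not (self.r_cap > 1):
            raise ValueError("r_cap must exceed 1")
        if not (self.steady_tol > 0):
            raise ValueError("steady_tol must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class Trajectory:
    """A simulated trajectory on the full time grid.

    ``times`` are in ``time_unit``; ``r``/``k`` are the state series,
    ``stress``/``strain`` the derived series (``strain == stress/k``
    exactly).  ``event_index`` marks the step at which an early exit
    occurred (``len(times) - 1`` if the horizon was reached); beyond it a
    steady trajectory is padded with the frozen state.
    """

    times: np.ndarray
    r: np.ndarray
    k: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    outcome: str
    final_relative_radius: float
    event_index: int
    nonfinite: bool = False
    time_unit: str = "dimensionless"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "r": self.r,
                "k": self.k,
                "stress": self.stress,
                "strain": self.strain,
            }
        )

    def metadata(self) -> dict:
        return {
            "outcome": self.outcome,
            "final_relative_radius": self.final_relative_radius,
            "event_index": self.event_index,
            "nonfinite": self.nonfinite,
            "time_unit": self.time_unit,
        }


@njit(cache=False, inline="always")
def _hill_nb(x, rho, eta):
    z = (x / rho) ** eta
    if not np.isfinite(z):
        return 1.0
    return z / (1.0 + z)


@njit(cache=False, inline="always")
def _rates(r, k, p, alpha, gamma, eta, rho):
    """Dimensionless (dr/dt, dk/dt) at a state; growth rate is clamped >= 0."""
    strain = p * r / k
    g = strain - 1.0
    if g < 0.0:
        g = 0.0
    fr = g * r
    fk = gamma * (1.0 - k + alpha * _hill_nb(p * r, rho, eta))
    return fr, fk


@njit(cache=False)
def _rk4_path(
    r0,
    k0,
    alpha,
    gamma,
    eta,
    rho,
    c,
    p_half,
    p_inf,
    dt,
    n_steps,
    r_cap,
    steady_tol,
    r_out,
    k_out,
):
    """Integrate one trajectory, filling ``r_out``/``k_out`` (len n_steps+1).

    ``c`` converts grid time to dimensionless time (``c = 1/tau`` on a day
    grid); ``p_inf`` is the infimum of the (non-increasing) pressure input,
    used by the exact arrest latch.  Returns (outcome_code, event_index,
    nonfinite).
    """
    r = r0
    k = k0
    r_out[0] = r
    k_out[0] = k
    grew = False
    fate = -1
    for j in range(n_steps):
        p1 = p_half[2 * j]
        p2 = p_half[2 * j + 1]
        p3 = p_half[2 * j + 2]

        fr1, fk1 = _rates(r, k, p1, alpha, gamma, eta, rho)
        if p1 * r / k > 1.0:
            grew = True
        elif fate == -1 and 1.0 + alpha * _hill_nb(p_inf * r, rho, eta) >= p1 * r:
            # arrest latch: growth can never resume; fate decided, but keep
            # integrating so the rigidity series stays honest
            fate = 1 if grew else 0
        # steady-state check on dimensionless rates at the current state
        if fr1 / r < steady_tol and abs(fk1) < steady_tol:
            for jj in range(j, n_steps):
                r_out[jj + 1] = r
                k_out[jj + 1] = k
            if grew:
                return 1, j, False
            return 0, j, False

        kr1 = c * fr1
        kk1 = c * fk1
        fr2, fk2 = _rates(r + 0.5 * dt * kr1, k + 0.5 * dt * kk1, p2, alpha, gamma, eta, rho)
        kr2 = c * fr2
        kk2 = c * fk2
        fr3, fk3 = _rates(r + 0.5 * dt * kr2, k + 0.5 * dt * kk2, p2, alpha, gamma, eta, rho)
        kr3 = c * fr3
        kk3 = c * fk3
        fr4, fk4 = _rates(r + dt * kr3, k + dt * kk3, p3, alpha, gamma, eta, rho)
        kr4 = c * fr4
        kk4 = c * fk4

        r = r + dt / 6.0 * (kr1 + 2.0 * kr2 + 2.0 * kr3 + kr4)
        k = k + dt / 6.0 * (kk1 + 2.0 * kk2 + 2.0 * kk3 + kk4)
        r_out[j + 1] = r
        k_out[j + 1] = k

        if not (np.isfinite(r) and np.isfinite(k) and k > 0.0):
            for jj in range(j + 1, n_steps):
                r_out[jj + 1] = r
                k_out[jj + 1] = k
            return 2, j + 1, True
        if r > r_cap:
            for jj in range(j + 1, n_steps):
                r_out[jj + 1] = r
                k_out[jj + 1] = k
            return 2, j + 1, False

    if fate != -1:
        return fate, n_steps, False
    if grew:
        return 3, n_steps, False
    return 0, n_steps, False


@njit(cache=False)
def _rk4_finals_batch(
    r0s,
    k0s,
    alphas,
    gammas,
    etas,
    rhos,
    cs,
    p_half,
    p_inf,
    dt,
    n_steps,
    check_idx,
    r_cap_mult,
    steady_tol,
    dt_fate,
    t_fate,
    r_checks,
    outcomes,
    final_r,
    final_k,
    in_horizon,
):
    """Integrate a batch of parameter sets on a shared grid, recording the
    radius at the checkpoint grid indices ``check_idx`` (sorted ascending).

    Per-set early exit with the same event semantics as `_rk4_path` (arrest
    latch, rate criterion, divergence); on an early exit the remaining
    checkpoints are padded with the frozen radius.  A set still growing at
    the horizon enters a fate-resolution extension: dimensionless-time RK4
    at the limiting pressure ``p_inf`` with step ``dt_fate`` for at most
    ``t_fate`` units, ended by the same events.  The extension decides the
    *outcome* only; ``final_r`` and the checkpoints keep their
    within-horizon values.
    """
    n = r0s.shape[0]
    n_checks = check_idx.shape[0]
    for i in range(n):
        r = r0s[i]
        k = k0s[i]
        alpha = alphas[i]
        gamma = gammas[i]
        eta = etas[i]
        rho = rhos[i]
        c = cs[i]
        r_cap = r_cap_mult * r
        grew = False
        code = -1
        ptr = 0
        if n_checks > 0 and check_idx[0] == 0:
            r_checks[i, 0] = r
            ptr = 1
        for j in range(n_steps):
            p1 = p_half[2 * j]
            p2 = p_half[2 * j + 1]
            p3 = p_half[2 * j + 2]

            fr1, fk1 = _rates(r, k, p1, alpha, gamma, eta, rho)
            if p1 * r / k > 1.0:
                grew = True
            elif 1.0 + alpha * _hill_nb(p_inf * r, rho, eta) >= p1 * r:
                code = 1 if grew else 0
                break
            if fr1 / r < steady_tol and abs(fk1) < steady_tol:
                code = 1 if grew else 0
                break

            kr1 = c * fr1
            kk1 = c * fk1
            fr2, fk2 = _rates(
                r + 0.5 * dt * kr1, k + 0.5 * dt * kk1, p2, alpha, gamma, eta, rho
            )
            kr2 = c * fr2
            kk2 = c * fk2
            fr3, fk3 = _rates(
                r + 0.5 * dt * kr2, k + 0.5 * dt * kk2, p2, alpha, gamma, eta, rho
            )
            kr3 = c * fr3
            kk3 = c * fk3
            fr4, fk4 = _rates(r + dt * kr3, k + dt * kk3, p3, alpha, gamma, eta, rho)
            kr4 = c * fr4
            kk4 = c * fk4

            r = r + dt / 6.0 * (kr1 + 2.0 * kr2 + 2.0 * kr3 + kr4)
            k = k + dt / 6.0 * (kk1 + 2.0 * kk2 + 2.0 * kk3 + kk4)

            while ptr < n_checks and check_idx[ptr] == j + 1:
                r_checks[i, ptr] = r
                ptr += 1

            if not (np.isfinite(r) and np.isfinite(k) and k > 0.0):
                code = 2
                break
            if r > r_cap:
                code = 2
                break
        # pad remaining checkpoints with the (frozen or last) state
        while ptr < n_checks:
            r_checks[i, ptr] = r
            ptr += 1
        final_r[i] = r
        final_k[i] = k
        in_horizon[i] = code != -1
        if code == -1:
            # fate resolution past the horizon at the limiting pressure
            r_x = r
            k_x = k
            n_ext = int(t_fate / dt_fate)
            for _ in range(n_ext):
                fr1, fk1 = _rates(r_x, k_x, p_inf, alpha, gamma, eta, rho)
                if p_inf * r_x / k_x > 1.0:
                    grew = True
                elif 1.0 + alpha * _hill_nb(p_inf * r_x, rho, eta) >= p_inf * r_x:
                    code = 1 if grew else 0
                    break
                if fr1 / r_x < steady_tol and abs(fk1) < steady_tol:
                    code = 1 if grew else 0
                    break
                kr1 = fr1
                kk1 = fk1
                fr2, fk2 = _rates(
                    r_x + 0.5 * dt_fate * kr1,
                    k_x + 0.5 * dt_fate * kk1,
                    p_inf,
                    alpha,
                    gamma,
                    eta,
                    rho,
                )
                fr3, fk3 = _rates(
                    r_x + 0.5 * dt_fate * fr2,
                    k_x + 0.5 * dt_fate * fk2,
                    p_inf,
                    alpha,
                    gamma,
                    eta,
                    rho,
                )
                fr4, fk4 = _rates(
                    r_x + dt_fate * fr3, k_x + dt_fate * fk3, p_inf, alpha, gamma, eta, rho
                )
                r_x = r_x + dt_fate / 6.0 * (kr1 + 2.0 * fr2 + 2.0 * fr3 + fr4)
                k_x = k_x + dt_fate / 6.0 * (kk1 + 2.0 * fk2 + 2.0 * fk3 + fk4)
                if not (np.isfinite(r_x) and np.isfinite(k_x) and k_x > 0.0):
                    code = 2
                    break
                if r_x > r_cap:
                    code = 2
                    break
        if code == -1:
            code = 3 if grew else 0
        outcomes[i] = code


def _pressure_half_grid(pressure, dt: float, n_steps: int, tau: float, grid_in_days: bool):
    """Sample a PressureInput on the half-step grid (length 2*n_steps + 1)."""
    t_half = 0.5 * dt * np.arange(2 * n_steps + 1)
    t_days = t_half if grid_in_days else tau * t_half
    p = np.asarray(pressure(t_days), dtype=float)
    if p.ndim == 0:
        p = np.full(2 * n_steps + 1, float(p))
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise ValueError("pressure input must be positive and finite on the grid")
    return np.ascontiguousarray(p)


def _pressure_infimum(pressure) -> float:
    """Infimum of a non-increasing pressure input (its value at t -> inf)."""
    return float(np.asarray(pressure(1e12), dtype=float))


def _run_path(r0, k0, params, c, p_half, p_inf, config, time_unit):
    n_steps = config.n_steps
    r_out = np.empty(n_steps + 1)
    k_out = np.empty(n_steps + 1)
    code, event_index, nonfinite = _rk4_path(
        float(r0),
        float(k0),
        params.alpha,
        params.gamma,
        params.eta,
        params.rho,
        float(c),
        p_half,
        float(p_inf),
        float(config.dt),
        n_steps,
        config.r_cap * float(r0),
        config.steady_tol,
        r_out,
        k_out,
    )
    times = config.dt * np.arange(n_steps + 1)
    p_grid = p_half[::2]
    stress = p_grid * r_out
    strain = stress / k_out
    return Trajectory(
        times=times,
        r=r_out,
        k=k_out,
        stress=stress,
        strain=strain,
        outcome=_OUTCOME_BY_CODE[int(code)],
        final_relative_radius=float(r_out[-1] / r_out[0]),
        event_index=int(event_index),
        nonfinite=bool(nonfinite),
        time_unit=time_unit,
    )


def simulate(
    params: ModelParameters,
    pressure: PressureInput | float,
    init: SystemState,
    config: IntegrationConfig = IntegrationConfig(),
    tau: float = 1.0,
) -> Trajectory:
    """Integrate the shell model in dimensionless time.

    ``pressure`` may be a `PressureInput` (a function of time in days — it
    is evaluated at ``tau * t``) or a plain positive number for constant
    pressure.  ``tau`` is the time scale in days per dimensionless unit.
    """
    pressure = _as_pressure(pressure)
    p_half = _pressure_half_grid(pressure, config.dt, config.n_steps, tau, grid_in_days=False)
    p_inf = _pressure_infimum(pressure)
    return _run_path(init.r, init.k, params, 1.0, p_half, p_inf, config, "dimensionless")


def simulate_days(
    params: ModelParameters,
    pressure: PressureInput | float,
    init: SystemState,
    tau: float,
    config: IntegrationConfig = IntegrationConfig(t_end=10.0, dt=0.005),
) -> Trajectory:
    """Integrate on a grid in days with time scale ``tau`` (days per
    dimensionless unit); ``config.t_end``/``config.dt`` are in days."""
    if not (tau > 0):
        raise ValueError("tau must be positive")
    pressure = _as_pressure(pressure)
    p_half = _pressure_half_grid(pressure, config.dt, config.n_steps, tau, grid_in_days=True)
    p_inf = _pressure_infimum(pressure)
    return _run_path(init.r, init.k, params, 1.0 / tau, p_half, p_inf, config, "days")


def simulate_batch(
    params_list,
    pressure: PressureInput | float,
    init_list,
    config: IntegrationConfig = IntegrationConfig(),
    tau: float = 1.0,
):
    """Element-wise `simulate` over aligned parameter and initial-state lists.

    Results are identical to calling `simulate` on each element (the same
    compiled kernel runs in both paths).
    """
    if len(params_list) != len(init_list):
        raise ValueError(
            f"params_list and init_list lengths differ: {len(params_list)} vs {len(init_list)}"
        )
    return [
        simulate(p, pressure, s, config, tau=tau) for p, s in zip(params_list, init_list)
    ]


def _as_pressure(pressure):
    if isinstance(pressure, PressureInput):
        return pressure
    from .pressure import ConstantPressure

    return ConstantPressure(float(pressure))


# ---------------------------------------------------------------------------
# analytic oracles for the decoupled limits
# ---------------------------------------------------------------------------

def blow_up_time(r0: float, p: float) -> float:
    """Finite blow-up time of the growth-only system ``dr/dt = (p*r - 1)*r``
    (rigidity fixed at 1), valid for ``p*r0 > 1``."""
    x0 = p * r0
    if not (x0 > 1.0):
        raise ValueError("blow-up requires p*r0 > 1")
    return float(np.log(x0 / (x0 - 1.0)))


def closed_form_no_stiffening(r0: float, p: float, t):
    """Exact solution ``r(t) = 1 / (p + (1/r0 - p) e^t)`` of the
    growth-only ODE ``dr/dt = (p*r - 1)*r`` with ``k == 1``.

    Defined up to the blow-up time ``t* = ln(p*r0 / (p*r0 - 1))``; a ``t``
    at or beyond ``t*`` raises a domain error.
    """
    t = np.asarray(t, dtype=float)
    t_star = blow_up_time(r0, p)
    if np.any(t >= t_star):
        raise ValueError(f"t must be below the blow-up time {t_star:.6g}")
    out = 1.0 / (p + (1.0 / r0 - p) * np.exp(t))
    return float(out) if out.ndim == 0 else out


def closed_form_k_relaxation(k0: float, gamma: float, alpha_h: float, t):
    """Exact rigidity relaxation at frozen stress: ``k(t) = k_inf +
    (k0 - k_inf) e^(-gamma t)`` with ``k_inf = 1 + alpha_h`` where
    ``alpha_h`` is the (constant) product alpha * H(stress)."""
    if not (gamma > 0):
        raise ValueError("gamma must be positive")
    t = np.asarray(t, dtype=float)
    k_inf = 1.0 + alpha_h
    out = k_inf + (k0 - k_inf) * np.exp(-gamma * t)
    return float(out) if out.ndim == 0 else out
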