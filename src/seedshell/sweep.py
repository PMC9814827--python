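"""Parameter-space exploration, fitting, and in-silico experiments.

The fitting procedure is rejection-style: sample parameter sets from broad
log-uniform ranges, simulate each at the reference pressure over a 10-day
horizon, keep only sets that converge to a steady state with a final
relative radius inside the biologically relevant band (3.5 +/- 0.5 by
default), score the survivors against per-day mean relative-radius data by
RMSE, and retain the best ``top_k`` (100) sets.  Marginal histograms of the
retained sets summarize which parameter values the data constrain.

Because the model is dimensionless while the data live on a day axis, the
time scale ``tau`` (days per dimensionless time unit) is itself a sampled
parameter, as is the initial stress ``x0 = p(0) * r0`` (the rigidity starts
at ``k0 = 1``, its unstressed fixed point).

On the retained sets this module also runs the downstream experiments:

* `sensitivity_scan` — perturb each stiffening parameter {alpha, rho, eta}
  by -20%..+20% and record the final relative radius;
* `pressure_swap_experiment` — rerun the retained sets under the five
  genotype pressure-drop functions and compare growth and stiffening timing;
* `constant_pressure_scan` — rerun under constant pressures scaled 0.5x-1.5x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrate import (
    IntegrationConfig,
    _pressure_half_grid,
    _pressure_infimum,
    _rk4_finals_batch,
    _as_pressure,
    simulate_days,
)
from .measure import GrowthDataset
from .model import SystemState, ModelParameters
from .pressure import PressureInput, make_genotype_drops

__all__ = [
    "SweepConfig",
    "SweepResult",
    "MarginalSummary",
    "sample_parameters",
    "run_sweep",
    "marginal_mode",
    "sensitivity_scan",
    "influence",
    "pressure_swap_experiment",
    "constant_pressure_scan",
]

PARAM_COLUMNS = ("alpha", "gamma", "eta", "rho", "x0", "tau")

_OUTCOME_LABELS = np.array(["no_growth", "converged", "diverged", "unresolved"])


@dataclass(frozen=True)
class SweepConfig:
    """Sampling ranges, filter band, and integration grid for a sweep.

    Ranges for alpha, gamma, eta, rho, tau are log-uniform; the initial
    stress ``x0`` is uniform.  ``band`` is the inclusive filter on the final
    relative radius of converged simulations; ``top_k`` the number of
    best-scoring sets retained.  Integration runs on a day grid of step
    ``dt_days`` over ``horizon_days``, scoring at integer days
    ``0..horizon_days``.
    """

    n_sets: int
    seed: int = 1
    alpha_range: tuple[float, float] = (0.5, 20.0)
    gamma_range: tuple[float, float] = (0.1, 50.0)
    eta_range: tuple[float, float] = (1.0, 30.0)
    rho_range: tuple[float, float] = (0.5, 10.0)
    x0_range: tuple[float, float] = (1.01, 1.5)
    tau_range: tuple[float, float] = (0.5, 5.0)
    band: tuple[float, float] = (3.0, 4.0)
    top_k: int = 100
    horizon_days: float = 10.0
    dt_days: float = 0.005
    r_cap: float = 100.0
    steady_tol: float = 1e-6
    # fate-resolution extension past the horizon (dimensionless time)
    fate_dt: float = 0.02
    fate_horizon: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_sets < 0:
            raise ValueError("n_sets must be >= 0")
        for name in ("alpha_range", "gamma_range", "eta_range", "rho_range",
                     "x0_range", "tau_range", "band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def integration(self) -> IntegrationConfig:
        return IntegrationConfig(
            t_end=self.horizon_days,
            dt=self.dt_days,
            r_cap=self.r_cap,
            steady_tol=self.steady_tol,
        )


def sample_parameters(config: SweepConfig) -> pd.DataFrame:
    """Draw ``n_sets`` parameter sets, reproducibly from ``config.seed``.

    Columns: alpha, gamma, eta, rho (log-uniform), x0 (uniform),
    tau (log-uniform).  The draw order is fixed so the table is a pure
    function of (seed, n_sets, ranges).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sets

    def log_uniform(lo, hi):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    data = {
        "alpha": log_uniform(*config.alpha_range),
        "gamma": log_uniform(*config.gamma_range),
        "eta": log_uniform(*config.eta_range),
        "rho": log_uniform(*config.rho_range),
        "x0": rng.uniform(*config.x0_range, size=n),
        "tau": log_uniform(*config.tau_range),
    }
    return pd.DataFrame(data)


def _integrate_sets(
    sets: pd.DataFrame,
    pressure,
    config: SweepConfig,
    check_days=None,
):
    """Batch-integrate parameter sets on the shared day grid.

    Returns (relative-radius curves at ``check_days``, outcome labels,
    final relative radius).  ``r0 = x0 / p(0)`` and ``k0 = 1``.
    """
    pressure = _as_pressure(pressure)
    n_steps = config.integration.n_steps
    dt = config.dt_days
    if check_days is None:
        check_days = np.arange(int(round(config.horizon_days)) + 1)
    check_days = np.asarray(check_days)
    check_idx = np.round(check_days / dt).astype(np.int64)
    if np.any(check_idx > n_steps):
        raise ValueError("check day beyond the integration horizon")

    p_half = _pressure_half_grid(pressure, dt, n_steps, tau=1.0, grid_in_days=True)
    p_inf = _pressure_infimum(pressure)
    p0 = p_half[0]

    n = len(sets)
    r0 = np.ascontiguousarray(sets["x0"].to_numpy() / p0)
    k0 = np.ones(n)
    cs = np.ascontiguousarray(1.0 / sets["tau"].to_numpy())
    r_checks = np.empty((n, len(check_idx)))
    outcomes = np.empty(n, dtype=np.int8)
    final_r = np.empty(n)
    final_k = np.empty(n)
    in_horizon = np.empty(n, dtype=np.bool_)
    _rk4_finals_batch(
        r0,
        k0,
        np.ascontiguousarray(sets["alpha"].to_numpy()),
        np.ascontiguousarray(sets["gamma"].to_numpy()),
        np.ascontiguousarray(sets["eta"].to_numpy()),
        np.ascontiguousarray(sets["rho"].to_numpy()),
        cs,
        p_half,
        p_inf,
        dt,
        n_steps,
        np.ascontiguousarray(check_idx),
        config.r_cap,
        config.steady_tol,
        config.fate_dt,
        config.fate_horizon,
        r_checks,
        outcomes,
        final_r,
        final_k,
        in_horizon,
    )
    rel_curves = r_checks / r0[:, None]
    final_rel = final_r / r0
    return rel_curves, _OUTCOME_LABELS[outcomes], final_rel, in_horizon


def _target_means(dataset, genotype=None, days=None) -> np.ndarray:
    if isinstance(dataset, GrowthDataset):
        if genotype is None:
            genos = dataset.genotypes()
            if len(genos) != 1:
                raise ValueError(f"dataset has genotypes {genos}; specify one")
            genotype = genos[0]
        return dataset.daily_mean_relative_radius(genotype, days=days).to_numpy()
    arr = np.asarray(dataset, dtype=float)
    if days is not None and len(arr) != len(days):
        raise ValueError("target length does not match scoring days")
    return arr


@dataclass
class SweepResult:
    """Outcome of a sweep: all sampled sets, survivors, and the top-K.

    ``table`` holds one row per sampled set with its outcome, final relative
    radius, and fit score (NaN for sets that did not pass the convergence
    band).  ``top`` is the best-``top_k`` subset sorted by (score, index).
    ``survivor_curves`` holds the per-day relative-radius curves of the
    band-passing sets, enabling rescoring against a different dataset
    without re-simulating.
    """

    config: SweepConfig
    table: pd.DataFrame
    top: pd.DataFrame
    days: np.ndarray
    target: np.ndarray
    survivor_index: np.ndarray
    survivor_curves: np.ndarray
    insufficient_survivors: bool

    @property
    def n_converged(self) -> int:
        return int((self.table["outcome"] == "converged").sum())

    @property
    def n_in_band(self) -> int:
        return len(self.survivor_index)

    def best(self) -> pd.Series:
        if len(self.top) == 0:
            raise ValueError("no surviving simulations to report")
        return self.top.iloc[0]

    def best_curve(self) -> np.ndarray:
        """Per-day relative-radius curve of the best-scoring simulation."""
        pos = int(np.nonzero(self.survivor_index == self.best().name)[0][0])
        return self.survivor_curves[pos]

    def marginals(self, bin_width: float = 0.25) -> dict[str, "MarginalSummary"]:
        return {p: marginal_mode(self, p, bin_width=bin_width) for p in ("alpha", "gamma", "eta", "rho")}

    def rescore(self, dataset, genotype=None) -> "SweepResult":
        """Re-rank the surviving sets against a different target curve,
        reusing the stored simulated curves (no re-simulation)."""
        target = _target_means(dataset, genotype, days=self.days)
        return _assemble_result(
            self.config,
            self.table.drop(columns=["score"]),
            self.days,
            target,
            self.survivor_index,
            self.survivor_curves,
        )


def _assemble_result(config, base_table, days, target, survivor_index, survivor_curves):
    scores = np.sqrt(np.mean((survivor_curves - target[None, :]) ** 2, axis=1))
    table = base_table.copy()
    table["score"] = np.nan
    table.loc[survivor_index, "score"] = scores
    order = np.lexsort((survivor_index, scores))
    ranked = survivor_index[order]
    top = table.loc[ranked[: config.top_k]].copy()
    return SweepResult(
        config=config,
        table=table,
        top=top,
        days=days,
        target=target,
        survivor_index=survivor_index,
        survivor_curves=survivor_curves,
        insufficient_survivors=len(survivor_index) < config.top_k,
    )


def run_sweep(
    config: SweepConfig,
    pressure,
    dataset,
    genotype: str | None = None,
) -> SweepResult:
    """Sample, simulate, filter, score, and select.

    ``pressure`` is the reference input (a `PressureInput` or a constant);
    ``dataset`` a `GrowthDataset` (or an array of per-day mean relative
    radii at integer days ``0..horizon``).  Sets must converge with a final
    relative radius inside ``config.band`` to be scored; survivors are
    ranked by RMSE against the per-day means and the best ``top_k`` kept.
    If fewer than ``top_k`` survive, all survivors are returned and the
    result is flagged.
    """
    days = np.arange(int(round(config.horizon_days)) + 1)
    target = _target_means(dataset, genotype, days=days)
    sets = sample_parameters(config)
    if len(sets) == 0:
        empty = sets.assign(
            outcome=pd.Series(dtype=object),
            final_rel_radius=pd.Series(dtype=float),
        )
        return _assemble_result(
            config, empty, days, target, np.array([], dtype=int), np.empty((0, len(days)))
        )

    rel_curves, outcomes, final_rel, in_horizon = _integrate_sets(
        sets, pressure, config, check_days=days
    )
    table = sets.copy()
    table["outcome"] = outcomes
    table["final_rel_radius"] = final_rel

    lo, hi = config.band
    in_band = (outcomes == "converged") & (final_rel >= lo) & (final_rel <= hi)
    survivor_index = np.nonzero(in_band)[0]
    return _assemble_result(
        config, table, days, target, survivor_index, rel_curves[survivor_index]
    )


@dataclass(frozen=True)
class MarginalSummary:
    """Histogram summary of one parameter over the top-K sets."""

    param: str
    mode_bin_center: float
    median: float
    bin_width: float
    n: int


def marginal_mode(result: SweepResult, param: str, bin_width: float = 0.25) -> MarginalSummary:
    """Histogram mode of a parameter over the top-K sets.

    Fixed-width bins (default 0.25) on the parameter's natural scale,
    anchored at 0; ties resolve to the lowest bin; the bin center is
    reported, along with the median.
    """
    if param not in PARAM_COLUMNS:
        raise ValueError(f"unknown parameter {param!r}; choose from {PARAM_COLUMNS}")
    values = result.top[param].to_numpy()
    if len(values) == 0:
        raise ValueError("top-K selection is empty")
    edges = np.arange(0.0, values.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    mode_bin = int(np.argmax(counts))  # argmax takes the lowest bin on ties
    center = edges[mode_bin] + bin_width / 2.0
    return MarginalSummary(
        param=param,
        mode_bin_center=float(center),
        median=float(np.median(values)),
        bin_width=bin_width,
        n=len(values),
    )


def sensitivity_scan(
    top_sets: pd.DataFrame,
    pressures: dict[str, PressureInput] | None = None,
    config: SweepConfig | None = None,
    param_names: tuple[str, ...] = ("alpha", "rho", "eta"),
    deltas=None,
) -> pd.DataFrame:
    """Perturb each stiffening parameter by -20%..+20% and re-simulate.

    For every retained set, parameter, relative perturbation, and pressure
    input, the single parameter is scaled by ``1 + delta`` and the final
    relative radius recorded.  Returns a tidy table with columns
    ``pressure, param, delta, set_index, outcome, final_rel_radius``.
    """
    if len(top_sets) == 0:
        raise ValueError("top_sets must be non-empty")
    if pressures is None:
        drops = make_genotype_drops()
        pressures = {"Col-0": drops["Col-0"], "iku2": drops["iku2"]}
    if config is None:
        config = SweepConfig(n_sets=0)
    if deltas is None:
        deltas = np.linspace(-0.2, 0.2, 9)

    frames = []
    for label, pressure in pressures.items():
        for param in param_names:
            for delta in deltas:
                perturbed = top_sets[list(PARAM_COLUMNS)].copy()
                perturbed[param] = perturbed[param] * (1.0 + delta)
                _, outcomes, final_rel, _ih = _integrate_sets(perturbed, pressure, config)
                frames.append(
                    pd.DataFrame(
                        {
                            "pressure": label,
                            "param": param,
                            "delta": delta,
                            "set_index": top_sets.index.to_numpy(),
                            "outcome": outcomes,
                            "final_rel_radius": final_rel,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def influence(scan: pd.DataFrame) -> pd.DataFrame:
    """Influence of each parameter: the range (max - min) of the median
    final relative radius across the perturbation grid, per pressure input."""
    med = scan.groupby(["pressure", "param", "delta"])["final_rel_radius"].median()
    rng = med.groupby(level=["pressure", "param"]).agg(lambda s: s.max() - s.min())
    return rng.rename("influence").reset_index()


@dataclass
class PressureSwapResult:
    """Growth and stiffening of retained sets under each drop function."""

    times: np.ndarray  # days
    labels: tuple[str, ...]
    wt_weight: dict[str, float]
    r_mean: dict[str, np.ndarray]
    r_sd: dict[str, np.ndarray]
    k_mean: dict[str, np.ndarray]
    final_rel: dict[str, np.ndarray]  # per set
    t_half_stiffening: dict[str, np.ndarray]  # per set, days

    def final_radius_by_drop(self) -> pd.Series:
        """Mean final relative radius per drop, ordered by WT weight."""
        order = sorted(self.labels, key=lambda l: self.wt_weight[l])
        return pd.Series({l: float(np.mean(self.final_rel[l])) for l in order}, name="final_rel_radius")

    def half_time_by_drop(self) -> pd.Series:
        order = sorted(self.labels, key=lambda l: self.wt_weight[l])
        return pd.Series(
            {l: float(np.mean(self.t_half_stiffening[l])) for l in order}, name="t_half_days"
        )


#: WT mixture weight of each drop label (0 = pure iku2 drop, 1 = pure Col-0).
DROP_WT_WEIGHT = {"iku2": 0.0, "25-75": 0.25, "50-50": 0.5, "75-25": 0.75, "Col-0": 1.0}


def pressure_swap_experiment(
    top_sets: pd.DataFrame,
    drops: dict[str, PressureInput] | None = None,
    config: SweepConfig | None = None,
) -> PressureSwapResult:
    """Rerun retained sets under each pressure-drop function.

    For each drop and each set, integrates the full trajectory on the day
    grid and records the relative radius (mean and sd across sets), the mean
    rigidity, the per-set final relative radius, and the per-set time at
    which the rigidity first reaches halfway between its initial and final
    values (the stiffening half-time).
    """
    if len(top_sets) == 0:
        raise ValueError("top_sets must be non-empty")
    if drops is None:
        drops = make_genotype_drops()
    if config is None:
        config = SweepConfig(n_sets=0)
    int_config = config.integration

    times = config.dt_days * np.arange(int_config.n_steps + 1)
    r_mean, r_sd, k_mean, final_rel, t_half = {}, {}, {}, {}, {}
    for label, drop in drops.items():
        p0 = float(np.asarray(drop(0.0)))
        r_curves = np.empty((len(top_sets), len(times)))
        k_curves = np.empty((len(top_sets), len(times)))
        for i, (_, row) in enumerate(top_sets.iterrows()):
            params = ModelParameters(
                alpha=row["alpha"], gamma=row["gamma"], eta=row["eta"], rho=row["rho"]
            )
            init = SystemState(r=row["x0"] / p0, k=1.0)
            traj = simulate_days(params, drop, init, tau=row["tau"], config=int_config)
            r_curves[i] = traj.r / traj.r[0]
            k_curves[i] = traj.k
        r_mean[label] = r_curves.mean(axis=0)
        r_sd[label] = r_curves.std(axis=0)
        k_mean[label] = k_curves.mean(axis=0)
        final_rel[label] = r_curves[:, -1]
        k0 = k_curves[:, 0]
        k_end = k_curves[:, -1]
        half_level = 0.5 * (k0 + k_end)
        reached = k_curves >= half_level[:, None]
        idx = np.argmax(reached, axis=1)
        t_half[label] = np.where(reached.any(axis=1), times[idx], np.inf)

    labels = tuple(drops.keys())
    weights = {l: DROP_WT_WEIGHT.get(l, np.nan) for l in labels}
    return PressureSwapResult(
        times=times,
        labels=labels,
        wt_weight=weights,
        r_mean=r_mean,
        r_sd=r_sd,
        k_mean=k_mean,
        final_rel=final_rel,
        t_half_stiffening=t_half,
    )


def constant_pressure_scan(
    top_sets: pd.DataFrame,
    factors=None,
    base_pressure: float = 1.0,
    config: SweepConfig | None = None,
) -> pd.DataFrame:
    """Osmotic scan: rerun retained sets at constant pressures scaled by
    ``factors`` of the baseline, keeping the fitted initial radius.

    Returns a tidy table with one row per (factor, set): outcome, final
    relative radius, and initial relative growth rate (relative radius gain
    from day 0 to day 1).
    """
    if len(top_sets) == 0:
        raise ValueError("top_sets must be non-empty")
    if factors is None:
        factors = np.linspace(0.5, 1.5, 11)
    if config is None:
        config = SweepConfig(n_sets=0)

    days = np.arange(int(round(config.horizon_days)) + 1)
    rows = []
    for factor in np.asarray(factors, dtype=float):
        sets = top_sets[list(PARAM_COLUMNS)].copy()
        # keep r0 = x0 / base_pressure fixed; pressure is scaled, so the
        # effective initial stress becomes factor * x0
        sets["x0"] = sets["x0"] * factor
        curves, outcomes, final_rel, _ih = _integrate_sets(
            sets, base_pressure * factor, config, check_days=days
        )
        # _integrate_sets sets r0 = x0_col / p(0) = (factor*x0)/(factor*p) = x0/p: unchanged
        rows.append(
            pd.DataFrame(
                {
                    "factor": factor,
                    "set_index": top_sets.index.to_numpy(),
                    "outcome": outcomes,
                    "final_rel_radius": final_rel,
                    "initial_growth_rate": curves[:, 1] - curves[:, 0],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
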