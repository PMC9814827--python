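"""Named experiment runners, config handling, CSV I/O, and run manifests.

Each runner chains the library modules into one of the package's in-silico
experiments and writes tidy CSV outputs plus a JSON manifest (command, config
echo, seeds, package version, output digests) so every run is reproducible
from its manifest.

Experiments
-----------
``wt-fit``
    Fit the model at constant pressure to (synthetic) wild-type growth data:
    sweep, filter, score, select; writes the all-sets table, the top-K table,
    and a best-fit summary.
``iku2-fit``
    Same pipeline against the iku2 preset using the iku2 pressure drop.
``pressure-drops``
    Rerun the iku2-fitted top sets under the five drop functions; writes
    per-drop growth/stiffening summaries.
``sensitivity``
    The -20%..+20% perturbation scan of {alpha, rho, eta} under the Col-0
    and iku2 drops.
``osmotic-scan``
    Constant-pressure factors 0.5x-1.5x on the WT-fitted top sets.
``streammap``
    Phase-space classification grid at a reference parameter set.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrate import IntegrationConfig, Trajectory, simulate
from .model import ModelParameters, SystemState
from .pressure import (
    ConstantPressure,
    PressureDrop,
    PressureInput,
    PressureMixture,
    ScaledPressure,
    make_genotype_drops,
    DEFAULT_WT_DROP,
    DEFAULT_IKU2_DROP,
)
from .steady import stream_map
from .sweep import (
    SweepConfig,
    run_sweep,
    sensitivity_scan,
    influence,
    pressure_swap_experiment,
    constant_pressure_scan,
)
from .synth import (
    WT_GROWTH,
    IKU2_GROWTH,
    generate_growth_dataset,
    generate_pressure_dataset,
    PressureGeneratorConfig,
)
from dataclasses import replace

__all__ = [
    "ConfigError",
    "load_config",
    "pressure_from_config",
    "write_trajectory",
    "run_simulate",
    "run_experiment",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = (
    "wt-fit",
    "iku2-fit",
    "pressure-drops",
    "osmotic-scan",
    "sensitivity",
    "streammap",
)


class ConfigError(ValueError):
    """Malformed configuration; carries the offending key path."""

    def __init__(self, key_path: str, message: str):
        self.key_path = key_path
        super().__init__(f"config error at '{key_path}': {message}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("<root>", "top level must be a mapping")
    return cfg


def _get(cfg: dict, key: str, path: str, required: bool = True, default=None):
    if key not in cfg:
        if required:
            raise ConfigError(f"{path}.{key}" if path else key, "missing required key")
        return default
    return cfg[key]


def pressure_from_config(cfg: dict, path: str = "pressure") -> PressureInput:
    """Build a PressureInput from a nested config mapping.

    Kinds: ``constant`` (p0), ``drop`` (p_start, p_end, t_mid, width),
    ``mixture`` (first, second, w), ``scaled`` (base, factor).
    """
    if not isinstance(cfg, dict):
        raise ConfigError(path, "must be a mapping with a 'kind' key")
    kind = _get(cfg, "kind", path)
    if kind == "constant":
        return ConstantPressure(float(_get(cfg, "p0", path)))
    if kind == "drop":
        return PressureDrop(
            p_start=float(_get(cfg, "p_start", path)),
            p_end=float(_get(cfg, "p_end", path)),
            t_mid=float(_get(cfg, "t_mid", path)),
            width=float(_get(cfg, "width", path)),
        )
    if kind == "mixture":
        return PressureMixture(
            first=pressure_from_config(_get(cfg, "first", path), f"{path}.first"),
            second=pressure_from_config(_get(cfg, "second", path), f"{path}.second"),
            w=float(_get(cfg, "w", path)),
        )
    if kind == "scaled":
        return ScaledPressure(
            base=pressure_from_config(_get(cfg, "base", path), f"{path}.base"),
            factor=float(_get(cfg, "factor", path)),
        )
    raise ConfigError(f"{path}.kind", f"unknown pressure kind {kind!r}")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict, seeds: dict, outputs: list[Path]):
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {p.name: _digest(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory CSV: columns t, r, k, stress, strain (metadata sidecar
    is the caller's manifest)."""
    traj.to_frame().to_csv(path, index=False)


def run_simulate(config: dict, out_dir) -> Path:
    """Run one simulation from a config mapping; write trajectory CSV +
    manifest.  Returns the trajectory path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pcfg = _get(config, "params", "")
    params = ModelParameters(
        alpha=float(_get(pcfg, "alpha", "params")),
        gamma=float(_get(pcfg, "gamma", "params")),
        eta=float(_get(pcfg, "eta", "params")),
        rho=float(_get(pcfg, "rho", "params")),
    )
    icfg = _get(config, "init", "")
    init = SystemState(
        r=float(_get(icfg, "r", "init")), k=float(_get(icfg, "k", "init"))
    )
    pressure = pressure_from_config(_get(config, "pressure", ""))
    intcfg = config.get("integration", {})
    integration = IntegrationConfig(
        t_end=float(intcfg.get("t_end", 20.0)),
        dt=float(intcfg.get("dt", 0.005)),
        r_cap=float(intcfg.get("r_cap", 100.0)),
        steady_tol=float(intcfg.get("steady_tol", 1e-6)),
    )
    traj = simulate(params, pressure, init, integration, tau=float(config.get("tau", 1.0)))
    out = out_dir / "trajectory.csv"
    write_trajectory(traj, out)
    meta = out_dir / "trajectory_meta.json"
    meta.write_text(json.dumps(traj.metadata(), indent=2))
    write_manifest(out_dir, "simulate", config, {}, [out, meta])
    return out


def _sweep_config(config: dict, seed: int, default_n: int) -> SweepConfig:
    scfg = config.get("sweep", {})
    kwargs = {k: v for k, v in scfg.items() if k not in ("n_sets", "seed")}
    for key in ("alpha_range", "gamma_range", "eta_range", "rho_range", "x0_range",
                "tau_range", "band"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SweepConfig(n_sets=int(scfg.get("n_sets", default_n)), seed=seed, **kwargs)


def run_experiment(name: str, config: dict | None, out_dir, seed: int = 1) -> dict[str, Path]:
    """Run a named experiment; write result CSVs + manifest into ``out_dir``.

    Returns a dict of output paths by role.  Unknown names raise a
    ``ValueError`` listing the valid experiments.
    """
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}; valid names: {EXPERIMENT_NAMES}")
    config = config or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_seed = int(config.get("generator_seed", 42))
    outputs: dict[str, Path] = {}

    def _fit(preset, pressure, default_n=20000):
        dataset = generate_growth_dataset(replace(preset, seed=gen_seed))
        sweep_cfg = _sweep_config(config, seed, default_n)
        result = run_sweep(sweep_cfg, pressure, dataset, genotype=preset.genotype)
        return dataset, result

    if name in ("wt-fit", "iku2-fit"):
        if name == "wt-fit":
            dataset, result = _fit(WT_GROWTH, ConstantPressure(1.0))
        else:
            dataset, result = _fit(IKU2_GROWTH, DEFAULT_IKU2_DROP)
        outputs["all_sets"] = out_dir / "all_sets.csv"
        result.table.to_csv(outputs["all_sets"], index=False)
        outputs["top"] = out_dir / "top_sets.csv"
        result.top.to_csv(outputs["top"], index=True, index_label="set_index")
        best = result.best()
        summary = {
            "n_sets": result.config.n_sets,
            "n_converged": result.n_converged,
            "n_in_band": result.n_in_band,
            "best_score": float(best["score"]),
            "best_final_rel_radius": float(result.best_curve()[-1]),
            "rho_mode": result.marginals()["rho"].mode_bin_center,
        }
        outputs["summary"] = out_dir / "summary.json"
        outputs["summary"].write_text(json.dumps(summary, indent=2))

    elif name == "pressure-drops":
        _, result = _fit(IKU2_GROWTH, DEFAULT_IKU2_DROP)
        swap = pressure_swap_experiment(result.top)
        frames = []
        stride = max(1, len(swap.times) // 200)
        for label in swap.labels:
            frames.append(
                pd.DataFrame(
                    {
                        "drop": label,
                        "t_days": swap.times[::stride],
                        "rel_radius_mean": swap.r_mean[label][::stride],
                        "rel_radius_sd": swap.r_sd[label][::stride],
                        "k_mean": swap.k_mean[label][::stride],
                    }
                )
            )
        outputs["curves"] = out_dir / "drop_curves.csv"
        pd.concat(frames, ignore_index=True).to_csv(outputs["curves"], index=False)
        outputs["summary"] = out_dir / "drop_summary.csv"
        pd.DataFrame(
            {
                "final_rel_radius": swap.final_radius_by_drop(),
                "t_half_stiffening": swap.half_time_by_drop(),
            }
        ).to_csv(outputs["summary"], index_label="drop")

    elif name == "sensitivity":
        _, result = _fit(IKU2_GROWTH, DEFAULT_IKU2_DROP)
        scan = sensitivity_scan(result.top)
        outputs["scan"] = out_dir / "sensitivity_scan.csv"
        scan.to_csv(outputs["scan"], index=False)
        outputs["influence"] = out_dir / "influence.csv"
        influence(scan).to_csv(outputs["influence"], index=False)

    elif name == "osmotic-scan":
        _, result = _fit(WT_GROWTH, ConstantPressure(1.0))
        scan = constant_pressure_scan(result.top)
        outputs["scan"] = out_dir / "osmotic_scan.csv"
        scan.to_csv(outputs["scan"], index=False)
        outputs["summary"] = out_dir / "osmotic_summary.csv"
        scan.groupby("factor")[["final_rel_radius", "initial_growth_rate"]].mean().to_csv(
            outputs["summary"]
        )

    elif name == "streammap":
        mcfg = config.get("streammap", {})
        params = ModelParameters(
            alpha=float(mcfg.get("alpha", 1.0)),
            gamma=float(mcfg.get("gamma", 5.0)),
            eta=float(mcfg.get("eta", 5.0)),
            rho=float(mcfg.get("rho", 8.0)),
        )
        smap = stream_map(
            params,
            p=float(mcfg.get("p", 1.0)),
            n_grid=int(mcfg.get("n_grid", 15)),
        )
        outputs["grid"] = out_dir / "streammap.csv"
        smap.to_frame().to_csv(outputs["grid"], index=False)
        outputs["nullcline"] = out_dir / "nullcline.csv"
        smap.nullcline_frame().to_csv(outputs["nullcline"], index=False)

    write_manifest(
        out_dir,
        f"experiment {name}",
        config,
        {"seed": seed, "generator_seed": gen_seed},
        list(outputs.values()),
    )
    outputs["manifest"] = out_dir / "manifest.json"
    return outputs


def run_synth(kind: str, out_dir, seed: int = 42) -> Path:
    """Write a synthetic measurement table (``growth`` or ``pressure``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "growth":
        wt = generate_growth_dataset(replace(WT_GROWTH, seed=seed))
        iku2 = generate_growth_dataset(replace(IKU2_GROWTH, seed=seed + 1))
        table = pd.concat([wt.table, iku2.table], ignore_index=True)
        out = out_dir / "growth_measurements.csv"
    elif kind == "pressure":
        table = generate_pressure_dataset(PressureGeneratorConfig(seed=seed))
        out = out_dir / "pressure_measurements.csv"
    else:
        raise ValueError(f"unknown synth kind {kind!r}; choose 'growth' or 'pressure'")
    table.to_csv(out, index=False)
    return out
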