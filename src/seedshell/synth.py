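"""Synthetic measurement generators with the structure of the study data.

Two generators stand in for the experimental tables so the whole pipeline is
testable without any download:

* per-seed growth tables — S-shaped relative-radius curves sampled at integer
  days post-anthesis (DPA) 0..10 with multiplicative per-seed noise.  The
  wild-type preset is calibrated so the noiseless curve rises ~3.5-fold,
  first reaches 98% of its 10-DPA value at day 7, and has its day-over-day
  growth-rate peak in days 1-3.  The *iku2* preset grows similarly early but
  arrests earlier and smaller.
* stage-binned endosperm pressure tables — normalized pressures per embryo
  stage, declining more steeply in the wild type than in *iku2*.

These emulate population-level curve shape, per-day sample sizes, and
genotype ordering; they do not emulate between-experiment batch effects,
measurement censoring, or the true per-seed dispersion (shown only
graphically in the study data).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np
import pandas as pd

from .measure import GrowthDataset
from .pressure import STAGE_ORDER

__all__ = [
    "GrowthGeneratorConfig",
    "PressureGeneratorConfig",
    "growth_curve",
    "generate_growth_dataset",
    "generate_pressure_dataset",
    "WT_GROWTH",
    "IKU2_GROWTH",
    "DEFAULT_PRESSURE",
]

# Per-day sample sizes of the growth measurements (days 0..10).
_N_PER_DAY_WT = (428, 485, 529, 483, 510, 511, 505, 493, 501, 446, 447)
_N_PER_DAY_IKU2 = (275, 280, 355, 324, 360, 369, 353, 322, 304, 237, 336)

# Per-stage sample sizes of the pooled pressure measurements.
_N_PER_STAGE_WT = (31, 109, 84, 100)
_N_PER_STAGE_IKU2 = (51, 89, 76, 106)


@dataclass(frozen=True)
class GrowthGeneratorConfig:
    """Logistic growth-curve generator for one genotype.

    The noiseless relative radius is ``1 + amplitude * (sig(d) - sig(0)) /
    (1 - sig(0))`` with ``sig`` the logistic of midpoint ``t_mid`` (days) and
    scale ``s`` (days), so the plateau is ``1 + amplitude`` and day 0 is
    exactly 1.  Per-seed values get multiplicative Gaussian noise of
    coefficient of variation ``noise_cv`` (truncated at -0.5).
    """

    genotype: str
    amplitude: float
    t_mid: float
    s: float
    noise_cv: float = 0.08
    n_per_day: tuple[int, ...] = _N_PER_DAY_WT
    seed: int = 42
    day0_radius_um: float = 150.0

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.s > 0):
            raise ValueError("amplitude and s must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(n < 0 for n in self.n_per_day):
            raise ValueError("n_per_day must be non-negative")


#: Wild-type preset: amplitude anchored to the ~3.5-fold radius increase;
#: t_mid and s calibrated so the noiseless curve plateaus (98% of the 10-DPA
#: value) at day 7 with the growth-rate peak in days 1-3.
WT_GROWTH = GrowthGeneratorConfig(
    genotype="Col-0", amplitude=2.5, t_mid=2.4, s=1.2, n_per_day=_N_PER_DAY_WT
)

#: iku2 preset: similar early growth, earlier and smaller arrest.
IKU2_GROWTH = GrowthGeneratorConfig(
    genotype="iku2", amplitude=2.1, t_mid=2.2, s=1.0, n_per_day=_N_PER_DAY_IKU2
)


def growth_curve(d, config: GrowthGeneratorConfig):
    """Noiseless relative radius at day ``d`` (scalar or array)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("day must be >= 0")
    sig = lambda t: 1.0 / (1.0 + np.exp(-(t - config.t_mid) / config.s))
    s0 = sig(0.0)
    out = 1.0 + config.amplitude * (sig(d) - s0) / (1.0 - s0)
    return float(out) if out.ndim == 0 else out


def generate_growth_dataset(config: GrowthGeneratorConfig) -> GrowthDataset:
    """Per-seed growth table for one genotype, reproducible from the seed.

    Each seed at day ``d`` gets ``relative_radius = curve(d) * (1 + eps)``
    with ``eps ~ N(0, noise_cv)`` truncated at -0.5, plus an ``area_um2``
    column via the nominal day-0 radius.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for d, n in enumerate(config.n_per_day):
        base = growth_curve(d, config)
        eps = rng.normal(0.0, config.noise_cv, size=n) if config.noise_cv > 0 else np.zeros(n)
        eps = np.maximum(eps, -0.5)
        rel = base * (1.0 + eps)
        radius = rel * config.day0_radius_um
        for i in range(n):
            rows.append(
                {
                    "genotype": config.genotype,
                    "dpa": d,
                    "seed_id": f"{config.genotype}-d{d}-{i:04d}",
                    "area_um2": pi * radius[i] ** 2,
                    "relative_radius": rel[i],
                }
            )
    return GrowthDataset(pd.DataFrame(rows))


@dataclass(frozen=True)
class PressureGeneratorConfig:
    """Stage-binned normalized pressure generator for both genotypes.

    Per (genotype, stage), ``n`` draws from ``N(mean, noise_sd)`` truncated
    positive.  The wild-type stage means must be non-increasing and decline
    more in total than the iku2 means (the measured genotype ordering).
    """

    wt_means: tuple[float, ...] = (1.00, 0.90, 0.70, 0.55)
    iku2_means: tuple[float, ...] = (1.00, 0.95, 0.88, 0.85)
    n_wt: tuple[int, ...] = _N_PER_STAGE_WT
    n_iku2: tuple[int, ...] = _N_PER_STAGE_IKU2
    noise_sd: float = 0.08
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.wt_means) != len(STAGE_ORDER) or len(self.iku2_means) != len(STAGE_ORDER):
            raise ValueError(f"stage means must have {len(STAGE_ORDER)} entries")
        if np.any(np.diff(self.wt_means) > 0):
            raise ValueError("WT stage means must be non-increasing")
        wt_decline = self.wt_means[0] - self.wt_means[-1]
        iku2_decline = self.iku2_means[0] - self.iku2_means[-1]
        if not (wt_decline > iku2_decline):
            raise ValueError("WT total pressure decline must exceed iku2's")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_PRESSURE = PressureGeneratorConfig()


def generate_pressure_dataset(config: PressureGeneratorConfig = DEFAULT_PRESSURE) -> pd.DataFrame:
    """Tidy per-seed pressure table: genotype, stage, pressure, experiment_id."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for genotype, means, ns in (
        ("Col-0", config.wt_means, config.n_wt),
        ("iku2", config.iku2_means, config.n_iku2),
    ):
        for stage, mean, n in zip(STAGE_ORDER, means, ns):
            draws = (
                rng.normal(mean, config.noise_sd, size=n)
                if config.noise_sd > 0
                else np.full(n, mean)
            )
            draws = np.abs(draws)  # truncate positive (reflection keeps mean ~unbiased at these CVs)
            draws[draws == 0] = mean
            for i, val in enumerate(draws):
                rows.append(
                    {
                        "genotype": genotype,
                        "stage": stage,
                        "pressure": float(val),
                        "experiment_id": f"synth-{genotype}-{stage}-{i:03d}",
                    }
                )
    return pd.DataFrame(rows)
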