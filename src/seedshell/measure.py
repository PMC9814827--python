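"""Measurement-level computations on raw seed data.

Covers the arithmetic that turns raw microscopy and nanoindentation
readouts into the quantities the model consumes:

* turgor pressure from the slope of a force-displacement curve,
  ``P = slope * c_M / pi`` (inverse of the thin-shell relation
  ``F = pi * P * delta / c_M``);
* radius of curvature from fitted ellipse axes, ``RC = major^2 / minor``;
* mean curvature as the arithmetic mean of the two principal curvatures;
* seed radius from projected area via the circle idealization
  ``Area = pi * radius^2``;
* day-over-day relative growth rate of the area.

Also provides the tidy growth-table container with per-day summaries used
by the sweep/fit layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "pressure_from_indentation",
    "slope_through_origin",
    "curvature_radius",
    "mean_curvature",
    "relative_growth_rate",
    "radius_from_area",
    "GrowthDataset",
]


def pressure_from_indentation(slope: float, c_m: float) -> float:
    """Turgor pressure from an indentation force-displacement slope.

    For a pressurized thin shell indented by a flat probe, force scales as
    ``F = pi * P * delta / c_M`` with ``delta`` the displacement and ``c_M``
    the mean curvature of the load-bearing wall; hence
    ``P = slope * c_M / pi``.
    """
    if not (slope > 0):
        raise ValueError(f"slope must be > 0, got {slope}")
    if not (c_m > 0):
        raise ValueError(f"c_M must be > 0, got {c_m}")
    return slope * c_m / pi


def slope_through_origin(displacement, force) -> float:
    """Ordinary least-squares slope of force vs displacement through the
    origin (the loading model is linear with zero intercept)."""
    d = np.asarray(displacement, dtype=float)
    f = np.asarray(force, dtype=float)
    if d.shape != f.shape or d.size == 0:
        raise ValueError("displacement and force must be equal-length, non-empty")
    denom = float(np.dot(d, d))
    if denom <= 0:
        raise ValueError("displacement values must not all be zero")
    return float(np.dot(d, f) / denom)


def curvature_radius(major: float, minor: float) -> float:
    """Radius of curvature at the apex of a fitted ellipse,
    ``RC = major^2 / minor`` (equals the radius for a circle)."""
    if not (major > 0 and minor > 0):
        raise ValueError("ellipse axes must be positive")
    return major * major / minor


def mean_curvature(rc_long: float, rc_trans: float) -> float:
    """Mean curvature from two orthogonal curvature radii:
    ``c_M = (1/RC_long + 1/RC_trans) / 2`` (arithmetic mean of the
    principal curvatures; symmetric in its arguments)."""
    if not (rc_long > 0 and rc_trans > 0):
        raise ValueError("curvature radii must be positive")
    return 0.5 * (1.0 / rc_long + 1.0 / rc_trans)


def relative_growth_rate(area_n: float, area_prev: float) -> float:
    """Day-over-day relative growth rate
    ``(Area(day n) - Area(day n-1)) / Area(day n-1)``."""
    if not (area_prev > 0):
        raise ValueError("previous area must be positive")
    if not (area_n > 0):
        raise ValueError("area must be positive")
    return (area_n - area_prev) / area_prev


def radius_from_area(area):
    """Radius of the circle with the given area, ``sqrt(area / pi)``."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    out = np.sqrt(area / pi)
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthDataset:
    """Tidy per-seed growth table with per-day summaries.

    ``table`` has columns ``genotype, dpa, seed_id`` and at least one of
    ``area_um2`` / ``relative_radius``.  When only areas are present, the
    relative radius is derived per genotype by normalizing each seed's
    radius by the genotype's day-0 mean radius.
    """

    table: pd.DataFrame

    REQUIRED = ("genotype", "dpa", "seed_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"growth table missing columns: {missing}")
        if "relative_radius" not in self.table.columns:
            if "area_um2" not in self.table.columns:
                raise ValueError("growth table needs area_um2 or relative_radius")
            self.table = self.table.copy()
            rel = np.empty(len(self.table))
            for genotype, grp in self.table.groupby("genotype"):
                radius = radius_from_area(grp["area_um2"].to_numpy())
                day0 = grp["dpa"] == 0
                if not day0.any():
                    raise ValueError(f"genotype {genotype!r} has no day-0 rows")
                r0 = float(np.mean(radius[day0.to_numpy()]))
                rel[grp.index.to_numpy()] = radius / r0
            self.table["relative_radius"] = rel

    @classmethod
    def from_csv(cls, path) -> "GrowthDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique().tolist())

    def daily_mean_relative_radius(self, genotype: str, days=None) -> pd.Series:
        """Mean relative radius per integer DPA for one genotype."""
        sub = self.table[self.table["genotype"] == genotype]
        if len(sub) == 0:
            raise ValueError(f"no rows for genotype {genotype!r}")
        means = sub.groupby("dpa")["relative_radius"].mean()
        if days is not None:
            missing = sorted(set(days) - set(means.index))
            if missing:
                raise ValueError(f"genotype {genotype!r} missing days {missing}")
            means = means.loc[list(days)]
        return means

    def daily_growth_rates(self, genotype: str) -> pd.Series:
        """Relative growth rate of the mean area between consecutive days."""
        sub = self.table[self.table["genotype"] == genotype]
        if "area_um2" in sub.columns:
            means = sub.groupby("dpa")["area_um2"].mean()
        else:
            means = sub.groupby("dpa")["relative_radius"].mean() ** 2
        days = means.index.to_numpy()
        vals = means.to_numpy()
        rates = {
            int(days[i]): relative_growth_rate(vals[i], vals[i - 1])
            for i in range(1, len(days))
        }
        return pd.Series(rates, name="relative_growth_rate")
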