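"""Time-dependent endosperm pressure inputs.

Pressure is the external control variable of the shell model.  This module
provides the pressure functions used in the in-silico experiments:

* constant pressure;
* a parametric "drop" — a descending logistic in developmental time (days),
  emulating the measured decline of endosperm turgor during seed growth;
* linear mixtures of two inputs (used to interpolate between the wild-type
  and *iku2* fitted drops);
* multiplicative scaling (osmotic treatments).

A drop can also be fitted by least squares to stage-binned pressure
measurements (`fit_drop`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PressureInput",
    "ConstantPressure",
    "PressureDrop",
    "PressureMixture",
    "ScaledPressure",
    "StagePressureSummary",
    "make_genotype_drops",
    "fit_drop",
    "STAGE_ORDER",
    "DEFAULT_STAGE_DAYS",
    "DEFAULT_WT_DROP",
    "DEFAULT_IKU2_DROP",
]

#: Embryo stages used to bin nanoindentation pressure measurements, in
#: developmental order, and their default day-post-anthesis midpoints.
STAGE_ORDER = ("preglobular", "globular", "triangular/heart", "torpedo")
DEFAULT_STAGE_DAYS = {
    "preglobular": 1.5,
    "globular": 3.5,
    "triangular/heart": 5.5,
    "torpedo": 8.0,
}


class PressureInput:
    """Base class: a positive pressure as a function of time in days."""

    def __call__(self, t_days):
        raise NotImplementedError

    # -- algebra -----------------------------------------------------------
    def scaled(self, factor: float) -> "ScaledPressure":
        return ScaledPressure(self, factor)

    def mixed_with(self, other: "PressureInput", w: float) -> "PressureMixture":
        return PressureMixture(self, other, w)


@dataclass(frozen=True)
class ConstantPressure(PressureInput):
    p0: float

    def __post_init__(self) -> None:
        if not (self.p0 > 0.0):
            raise ValueError(f"constant pressure must be > 0, got {self.p0}")

    def __call__(self, t_days):
        t_days = np.asarray(t_days, dtype=float)
        out = np.full_like(t_days, self.p0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PressureDrop(PressureInput):
    """Descending logistic drop in days.

    ``p(t) = p_end + (p_start - p_end) / (1 + exp((t - t_mid)/width))``

    ``p_start >= p_end > 0`` so the function is monotone non-increasing;
    ``t_mid`` is the day of half-drop and ``width`` the transition scale.
    """

    p_start: float
    p_end: float
    t_mid: float
    width: float
    degenerate: bool = False  # flag set by fit_drop on constant data

    def __post_init__(self) -> None:
        if not (self.p_end > 0.0):
            raise ValueError(f"p_end must be > 0, got {self.p_end}")
        if not (self.p_start >= self.p_end):
            raise ValueError("drop requires p_start >= p_end (non-increasing pressure)")
        if not (self.width > 0.0):
            raise ValueError(f"width must be > 0, got {self.width}")

    @property
    def depth(self) -> float:
        """Total pressure drop ``p_start - p_end``."""
        return self.p_start - self.p_end

    def __call__(self, t_days):
        t_days = np.asarray(t_days, dtype=float)
        # the logistic saturates to p_end far past t_mid; exp overflow there
        # is benign (1/(1+inf) -> 0)
        with np.errstate(over="ignore"):
            out = self.p_end + (self.p_start - self.p_end) / (
                1.0 + np.exp((t_days - self.t_mid) / self.width)
            )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PressureMixture(PressureInput):
    """Pointwise linear mixture ``w*first(t) + (1-w)*second(t)``."""

    first: PressureInput
    second: PressureInput
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"mixture weight must be in [0, 1], got {self.w}")

    def __call__(self, t_days):
        return self.w * self.first(t_days) + (1.0 - self.w) * self.second(t_days)


@dataclass(frozen=True)
class ScaledPressure(PressureInput):
    base: PressureInput
    factor: float

    def __post_init__(self) -> None:
        if not (self.factor > 0.0):
            raise ValueError(f"scale factor must be > 0, got {self.factor}")

    def __call__(self, t_days):
        return self.factor * self.base(t_days)


# Default normalized drops — calibration constants, not measured ground truth:
# the wild type shows the deeper turgor decline, the iku2 mutant a shallower one.
DEFAULT_WT_DROP = PressureDrop(p_start=1.0, p_end=0.55, t_mid=4.0, width=1.0)
DEFAULT_IKU2_DROP = PressureDrop(p_start=1.0, p_end=0.85, t_mid=4.0, width=1.0)


def make_genotype_drops(
    wt: PressureDrop = DEFAULT_WT_DROP,
    iku2: PressureDrop = DEFAULT_IKU2_DROP,
) -> dict[str, PressureInput]:
    """The five pressure inputs of the drop-swap experiment.

    Returns a dict keyed by label, ordered from shallowest to deepest drop:
    ``iku2``, ``25-75``, ``50-50``, ``75-25``, ``Col-0``.  The three
    intermediates are pointwise linear combinations ``w*WT + (1-w)*iku2``
    with WT weights 0.25, 0.5, 0.75.

    Raises ``ValueError`` if the WT drop is not strictly deeper than the
    iku2 drop (the measured genotype ordering).
    """
    if not (wt.depth > iku2.depth):
        raise ValueError(
            "wild-type drop depth must exceed iku2 drop depth "
            f"(got {wt.depth:.4g} vs {iku2.depth:.4g})"
        )
    return {
        "iku2": iku2,
        "25-75": PressureMixture(wt, iku2, 0.25),
        "50-50": PressureMixture(wt, iku2, 0.50),
        "75-25": PressureMixture(wt, iku2, 0.75),
        "Col-0": wt,
    }


@dataclass(frozen=True)
class StagePressureSummary:
    """Stage-binned normalized pressure for one genotype.

    ``stages`` are in developmental order with strictly increasing day
    midpoints; ``means`` are per-stage mean normalized pressures and ``ns``
    the per-stage sample sizes.
    """

    genotype: str
    stages: tuple[str, ...]
    days: tuple[float, ...]
    means: tuple[float, ...]
    ns: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (len(self.stages) == len(self.days) == len(self.means)):
            raise ValueError("stages, days, means must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("stage day midpoints must be strictly increasing")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("stage means must be finite")


def summarize_stage_pressure(
    table, genotype: str, stage_days: dict[str, float] | None = None
) -> StagePressureSummary:
    """Build a `StagePressureSummary` from a tidy per-seed pressure table.

    ``table`` is a DataFrame with columns genotype, stage, pressure.
    """
    stage_days = dict(DEFAULT_STAGE_DAYS if stage_days is None else stage_days)
    sub = table[table["genotype"] == genotype]
    if len(sub) == 0:
        raise ValueError(f"no rows for genotype {genotype!r}")
    stages, days, means, ns = [], [], [], []
    for stage in sorted(stage_days, key=stage_days.get):
        grp = sub[sub["stage"] == stage]
        if len(grp) == 0:
            continue
        stages.append(stage)
        days.append(stage_days[stage])
        means.append(float(grp["pressure"].mean()))
        ns.append(int(len(grp)))
    return StagePressureSummary(
        genotype=genotype,
        stages=tuple(stages),
        days=tuple(days),
        means=tuple(means),
        ns=tuple(ns),
    )


def fit_drop(
    summary: StagePressureSummary,
    n_starts: int = 20,
    seed: int = 0,
) -> PressureDrop:
    """Least-squares fit of the 4-parameter logistic drop to stage means.

    Multi-start (``n_starts`` seeded initializations) trust-region least
    squares; the start with the lowest residual wins.  Degenerate (constant)
    data yield a flagged constant-equivalent drop with
    ``p_start == p_end == mean``.
    """
    if len(summary.means) < 3:
        raise ValueError("fit_drop needs at least 3 stages with finite means")
    days = np.asarray(summary.days, dtype=float)
    means = np.asarray(summary.means, dtype=float)

    span = float(means.max() - means.min())
    if span < 1e-9:
        m = float(means.mean())
        return PressureDrop(p_start=m, p_end=m + 0.0, t_mid=float(days.mean()),
                            width=1.0, degenerate=True) if m > 0 else _raise_nonpositive(m)

    # parameters: (p_end, depth, t_mid, log_width); depth >= 0 via bounds
    def resid(theta):
        p_end, depth, t_mid, log_w = theta
        w = np.exp(log_w)
        pred = p_end + depth / (1.0 + np.exp((days - t_mid) / w))
        return pred - means

    rng = np.random.default_rng(seed)
    t_lo, t_hi = float(days.min()), float(days.max())
    best = None
    for i in range(n_starts):
        if i == 0:
            theta0 = np.array([means.min(), span, days.mean(), 0.0])
        else:
            theta0 = np.array(
                [
                    means.min() * rng.uniform(0.5, 1.5),
                    span * rng.uniform(0.5, 2.0),
                    rng.uniform(t_lo, t_hi),
                    rng.uniform(np.log(0.2), np.log(5.0)),
                ]
            )
        try:
            sol = least_squares(
                resid,
                theta0,
                bounds=([1e-6, 0.0, t_lo - 10.0, np.log(1e-2)],
                        [np.inf, np.inf, t_hi + 10.0, np.log(1e2)]),
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    p_end, depth, t_mid, log_w = best.x
    return PressureDrop(
        p_start=float(p_end + depth),
        p_end=float(p_end),
        t_mid=float(t_mid),
        width=float(np.exp(log_w)),
    )


def _raise_nonpositive(m):
    raise ValueError(f"mean pressure must be positive, got {m}")
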