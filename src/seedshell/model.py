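"""Dimensionless mechanical model of a growing pressurized shell.

The seed coat (testa) is idealized as a thin, linearly elastic spherical
shell of dimensionless radius ``r`` and effective rigidity ``k``, inflated by
the endosperm's dimensionless turgor pressure ``p``.  Two mechanosensitive
processes act on the shell and together form an incoherent feedforward loop:

* strain-based growth — the radius grows at a rate proportional to the
  elastic strain in excess of a threshold (Lockhart-type irreversible
  expansion)::

      dr/dt = (p*r/k - 1)_+ * r

* stress-based stiffening — the rigidity relaxes toward a stress-dependent
  target set by a Hill response of the wall tension::

      dk/dt = gamma * (1 - k + alpha * H_eta(p*r, rho))

Stress is proportional to ``p*r`` (Laplace tension of a thin shell) and
strain to ``p*r/k``.  Pressure therefore promotes growth directly while also
promoting the stiffening that ultimately curbs it.  All quantities are
dimensionless; the mapping to days and micrometres lives in the sweep/fit
layer (a sampled time scale) and in the measurement utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "hill",
    "positive_part",
    "rhs",
    "nullcline_k",
    "stress_strain",
]

#: Dimensionless strain threshold for irreversible growth.  The
#: nondimensionalization absorbs the Lockhart yield threshold into the unit
#: strain, so this is a constant of the model, not a parameter.
GROWTH_STRAIN_THRESHOLD = 1.0


@dataclass(frozen=True)
class ModelParameters:
    """The four dimensionless stiffening/growth parameters.

    Parameters
    ----------
    alpha : float
        Stiffening amplitude: the rigidity target saturates at ``1 + alpha``
        under high wall stress.  ``alpha >= 0`` (zero disables stiffening,
        which is useful for analytic oracles).
    gamma : float
        Ratio of the stiffening rate to the growth rate (``> 0``).
    eta : float
        Hill exponent of the stress response; steepness of
        mechanotransduction (``>= 1``).
    rho : float
        Hill half-activation stress: the ratio of the stiffening threshold
        to the growth threshold (``> 0``).
    """

    alpha: float
    gamma: float
    eta: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.alpha >= 0.0):
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not (self.gamma > 0.0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.eta >= 1.0):
            raise ValueError(f"eta must be >= 1, got {self.eta}")
        if not (self.rho > 0.0):
            raise ValueError(f"rho must be > 0, got {self.rho}")


@dataclass(frozen=True)
class SystemState:
    """State of the shell: radius ``r = R/h``, rigidity ``k``, time ``t``."""

    r: float
    k: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r > 0.0):
            raise ValueError(f"r must be > 0, got {self.r}")
        if not (self.k > 0.0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.t >= 0.0):
            raise ValueError(f"t must be >= 0, got {self.t}")


def hill(x, rho: float, eta: float):
    """Hill response ``x**eta / (x**eta + rho**eta)``.

    Monotone non-decreasing sigmoid with half-activation at ``x == rho``;
    0 at ``x == 0`` and approaching 1 as ``x -> inf``.  Accepts scalars or
    arrays for ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0):
        raise ValueError("hill: stress x must be non-negative")
    if not (rho > 0.0):
        raise ValueError("hill: rho must be positive")
    if not (eta >= 1.0):
        raise ValueError("hill: eta must be >= 1")
    # (x/rho)**eta formulation avoids overflow of x**eta for large eta.
    with np.errstate(over="ignore"):
        z = (x / rho) ** eta
        out = z / (1.0 + z)
    out = np.where(np.isfinite(z), out, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def positive_part(x):
    """Threshold-linear function ``(x)_+ = max(x, 0)`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    out = np.maximum(x, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def stress_strain(r, k, p):
    """Dimensionless wall stress ``p*r`` and strain ``p*r/k``."""
    stress = np.asarray(p, dtype=float) * np.asarray(r, dtype=float)
    strain = stress / np.asarray(k, dtype=float)
    return stress, strain


def rhs(state: SystemState, p: float, params: ModelParameters) -> tuple[float, float]:
    """Right-hand side (dr/dt, dk/dt) of the shell model.

    ``dr/dt = (p*r/k - 1)_+ * r`` is always non-negative: irreversible growth
    means the radius never shrinks.  ``dk/dt = gamma*(1 - k + alpha*H(p*r))``
    relaxes the rigidity toward the stress-set target.
    """
    if not (p > 0.0):
        raise ValueError(f"pressure must be > 0, got {p}")
    stress = p * state.r
    strain = stress / state.k
    dr = positive_part(strain - GROWTH_STRAIN_THRESHOLD) * state.r
    dk = params.gamma * (1.0 - state.k + params.alpha * hill(stress, params.rho, params.eta))
    return float(dr), float(dk)


def nullcline_k(x_grid, params: ModelParameters):
    """Rigidity nullcline ``k = 1 + alpha*H(x)`` as a function of stress.

    This is the ``dk/dt = 0`` locus — the sigmoid curve marking the arrest of
    stiffening in the state space.  ``x_grid`` is stress ``p*r``.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    return 1.0 + params.alpha * hill(x_grid, params.rho, params.eta)
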