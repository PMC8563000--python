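"""Closed-form mean-reversion (OU) machinery of band migration.

In the co-moving band coordinate, a cell of chemotactic ability ``chi``
exposed to a linearized perceived gradient ``g(z) = g0 + g1 z`` obeys

    dz = [chi (g0 + g1 z) - V_G] dt + epsilon dW

i.e. an Ornstein-Uhlenbeck process when g1 < 0 (the pushed-wave case):
the deterministic force ``F(z) = chi (g0 + g1 z) - V_G`` vanishes at the
balanced position ``z* = (V_G - chi g0) / (chi g1)``, reverts with rate
``r = chi |g1|``, and the stationary law is Gaussian with SD
``sigma = epsilon / sqrt(2 r)``.  Sign conventions are fixed by the
defining conditions F(z*) = 0, -U'(z) = F(z), and stationary variance
epsilon^2 / (2 r); the potential's additive constant is fixed by
U(z*) = 0 (an upward parabola has no finite value at infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate

__all__ = [
    "Phenotype",
    "OUDerived",
    "force",
    "balanced_position",
    "potential",
    "drift_potential",
    "reversion_rate",
    "stationary_sd",
    "mean_relaxation",
    "stationary_density",
    "ou_msd",
    "classify_wave",
    "phenotype_order",
    "derive",
]


@dataclass(frozen=True)
class Phenotype:
    """One chemotactic phenotype.

    ``chi`` (mm^2/min) converts a perceived gradient into drift velocity
    (V_D = chi g); ``epsilon`` (mm/min^0.5) is the motility noise strength,
    epsilon = sqrt(2 D) with D the run-and-tumble diffusivity.
    """

    chi: float
    epsilon: float = 0.124
    label: str = ""

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def diffusivity(self) -> float:
        return 0.5 * self.epsilon**2


@dataclass(frozen=True)
class OUDerived:
    """Derived OU quantities for one phenotype in one gradient."""

    r: float        # reversion rate, 1/min
    z_star: float   # balanced position, mm
    sigma: float    # stationary SD, mm (NaN when r == 0)


def force(z, phenotype: Phenotype, g0: float, g1: float, v_g: float):
    """Deterministic moving-frame force ``F(z) = chi (g0 + g1 z) - V_G``."""
    return phenotype.chi * (g0 + g1 * np.asarray(z, dtype=float)) - v_g


def balanced_position(phenotype: Phenotype, g0: float, g1: float,
                      v_g: float) -> float:
    """The unique root of F: ``z* = (V_G - chi g0) / (chi g1)``."""
    if phenotype.chi * g1 == 0:
        raise ValueError("chi*g1 = 0: no finite balanced position")
    return (v_g - phenotype.chi * g0) / (phenotype.chi * g1)


def reversion_rate(phenotype: Phenotype, g1: float) -> float:
    """Reversion rate ``r = chi |g1|`` of the pushed-wave well.

    Only a decreasing gradient (g1 < 0) produces mean reversion; g1 = 0 is
    diffusive (r = 0) and g1 > 0 is a pulled front (no reversion, NaN).
    """
    if g1 > 0:
        warnings.warn("g1 > 0 (pulled front): no reversion rate", stacklevel=2)
        return np.nan
    return phenotype.chi * abs(g1)


def stationary_sd(phenotype: Phenotype, g1: float) -> float:
    """Stationary SD ``sigma = epsilon / sqrt(2 chi |g1|) = sqrt(D / r)``."""
    r = reversion_rate(phenotype, g1)
    if not r > 0:
        warnings.warn("r = 0: diffusive, stationary SD undefined", stacklevel=2)
        return np.nan
    return phenotype.epsilon / np.sqrt(2.0 * r)


def derive(phenotype: Phenotype, g0: float, g1: float, v_g: float) -> OUDerived:
    return OUDerived(
        r=reversion_rate(phenotype, g1),
        z_star=balanced_position(phenotype, g0, g1, v_g),
        sigma=stationary_sd(phenotype, g1),
    )


def potential(z, phenotype: Phenotype, g0: float, g1: float, v_g: float):
    """Effective potential with ``-dU/dz = F(z)`` and ``U(z*) = 0``.

    For g1 < 0 this is the upward parabola ``U = (r/2)(z - z*)^2`` with
    curvature r = chi |g1| about the balanced position.
    """
    z = np.asarray(z, dtype=float)
    z_star = balanced_position(phenotype, g0, g1, v_g)
    return -0.5 * phenotype.chi * g1 * (z - z_star) ** 2


def drift_potential(z_grid: np.ndarray, v_d: np.ndarray) -> np.ndarray:
    """Drift-based potential variant ``U(z) = int_z^inf V_D dz'`` (mm^2/min).

    This integrates a *velocity* profile (not a force), so its units differ
    from :func:`potential`; it is the direct empirical summary of a
    measured V_D(z) curve, evaluated by cumulative trapezoid from the top
    of the grid.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    v_d = np.asarray(v_d, dtype=float)
    cum = scipy.integrate.cumulative_trapezoid(v_d, z_grid, initial=0.0)
    return cum[-1] - cum


def mean_relaxation(t, C0: float, r: float, z_star: float):
    """Ensemble-mean relaxation ``z(t) = C0 exp(-r t) + z*``.

    For a linear drift profile ``V_D(z) = -r z + V_D0`` the fixed point is
    ``z* = (V_D0 - V_G)/r``, and a subgroup started with mean offset C0
    from it converges exponentially at the reversion rate.
    """
    if r <= 0:
        raise ValueError("mean relaxation requires r > 0")
    return C0 * np.exp(-r * np.asarray(t, dtype=float)) + z_star


def stationary_density(z_grid: np.ndarray, z_star: float,
                       sigma: float) -> np.ndarray:
    """Stationary Gaussian band profile, trapezoid-normalized on the grid.

    This is the stationary solution of the Fokker-Planck equation
    equivalent to the moving-frame OU dynamics.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z_grid = np.asarray(z_grid, dtype=float)
    pdf = np.exp(-0.5 * ((z_grid - z_star) / sigma) ** 2)
    norm = np.trapezoid(pdf, z_grid)
    return pdf / norm


def ou_msd(t, r: float, sigma: float):
    """Stationary-OU moving-frame MSD ``2 sigma^2 (1 - exp(-r t))``.

    Plateaus at twice the stationary variance.
    """
    return 2.0 * sigma**2 * (1.0 - np.exp(-r * np.asarray(t, dtype=float)))


def classify_wave(g1: float, tol: float = 1e-9) -> str:
    """Front type by the gradient slope: decreasing g (g1 < 0) is pushed,
    flat is diffusive, increasing is pulled.

    ``tol`` absorbs discretization noise around an exactly flat gradient.
    """
    if not np.isfinite(g1):
        raise ValueError("g1 must be finite")
    if g1 < -tol:
        return "pushed"
    if g1 > tol:
        return "pulled"
    return "diffusive"


def phenotype_order(population: list[Phenotype], g0: float, g1: float,
                    v_g: float) -> pd.DataFrame:
    """Ordered table of (chi, z*, r, sigma) for a pushed gradient.

    Sorted by chi; in a pushed front (g1 < 0, all chi > 0) the balanced
    positions strictly increase with chi while the stationary widths
    strictly decrease, which is asserted.
    """
    if not g1 < 0:
        raise ValueError("phenotype ordering is defined for pushed fronts (g1 < 0)")
    if any(p.chi <= 0 for p in population):
        raise ValueError("all chi must be positive")
    rows = []
    for p in sorted(population, key=lambda p: p.chi):
        d = derive(p, g0, g1, v_g)
        rows.append((p.label or f"chi={p.chi:g}", p.chi, d.z_star, d.r, d.sigma))
    table = pd.DataFrame(rows, columns=["label", "chi", "z_star_mm",
                                        "r_per_min", "sigma_mm"])
    zs = table["z_star_mm"].to_numpy()
    sg = table["sigma_mm"].to_numpy()
    if len(table) > 1:
        assert np.all(np.diff(zs) > 0), "balanced positions must increase with chi"
        assert np.all(np.diff(sg) < 0), "stationary widths must decrease with chi"
    return table
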