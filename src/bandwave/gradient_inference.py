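"""Attractant-profile and perceived-gradient inference from a density profile.

In the frame co-moving with a band travelling at ``V_G``, a steadily
consumed attractant obeys the travelling-wave balance

    -V_G dS/dz = D_s d2S/dz2 - k rho(z)

with fresh medium ahead of the band (``S -> S_far`` as z -> +inf) and an
exhausted, flux-free tail behind (``S' -> 0`` as z -> -inf).  Receptors
sense the log of the MWC occupancy ratio, so the perceived gradient is

    g(z) = d/dz [ ln(1 + S/K_off) - ln(1 + S/K_on) ]

which reduces to the log-concentration gradient for K_off << S << K_on.
Around the band center g(z) is nearly linear and is summarised by its
linearization g(z) ~ g0 + g1 z; a decreasing gradient (g1 < 0) is the
pushed-wave case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .io_config import SpatialProfile

__all__ = [
    "GradientField",
    "infer_attractant_profile",
    "perceived_gradient",
    "linearize_gradient",
    "mwc_log_occupancy",
]

#: aspartate diffusivity ~800 um^2/s in mm^2/min
DEFAULT_DS = 0.048
#: MWC dissociation constants for the Tar-aspartate pair, uM
DEFAULT_KOFF = 3.5
DEFAULT_KON = 1000.0


@dataclass
class GradientField:
    """Attractant concentration and perceived gradient on a z grid."""

    z: np.ndarray                       # mm
    S: np.ndarray | None = None         # uM
    g: np.ndarray | None = None         # 1/mm
    params: dict = field(default_factory=dict)
    g0: float | None = None             # 1/mm
    g1: float | None = None             # 1/mm^2
    fit_window: tuple[float, float] | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        koff = self.params.get("koff", DEFAULT_KOFF)
        kon = self.params.get("kon", DEFAULT_KON)
        if not kon > koff > 0:
            raise ValueError("need K_on > K_off > 0")
        if self.S is not None and np.any(self.S < 0):
            raise ValueError("S must be nonnegative on the grid")


def mwc_log_occupancy(S: np.ndarray, koff: float = DEFAULT_KOFF,
                      kon: float = DEFAULT_KON) -> np.ndarray:
    """Receptor free-energy ligand term ln[(1 + S/K_off)/(1 + S/K_on)]."""
    S = np.asarray(S, dtype=float)
    return np.log1p(S / koff) - np.log1p(S / kon)


def infer_attractant_profile(
    rho: SpatialProfile | tuple[np.ndarray, np.ndarray],
    v_g: float,
    d_s: float = DEFAULT_DS,
    k: float = 3.0e-9,
    s_far: float = 200.0,
    grid: np.ndarray | None = None,
    koff: float = DEFAULT_KOFF,
    kon: float = DEFAULT_KON,
) -> GradientField:
    """Solve the travelling-wave attractant balance for S(z).

    ``rho`` is a density profile (cells/mm^3 on z bins, or an explicit
    ``(z, rho)`` pair); ``k`` is the consumption rate per unit of that
    density (uM mm^3/min per cell for a per-volume density).  The linear
    two-point problem

        D_s S'' + V_G S' = k rho,  S'(z_min) = 0,  S(z_max) = S_far

    is discretised with second-order central differences and solved as a
    sparse banded system; a cell Peclet number ``V_G h / D_s >= 2`` raises
    a refinement error, and S is clipped at 0 with a warning if consumption
    formally exhausts the attractant.
    """
    if v_g <= 0:
        raise ValueError("V_G must be positive")
    if isinstance(rho, SpatialProfile):
        z_rho, rho_vals = rho.centers, np.nan_to_num(rho.value)
    else:
        z_rho, rho_vals = (np.asarray(a, dtype=float) for a in rho)
    if np.any(rho_vals < 0):
        raise ValueError("rho must be nonnegative")
    if grid is None:
        pad = 3.0 * max(d_s / v_g, 0.5)
        grid = np.arange(z_rho.min() - pad, z_rho.max() + pad, 0.02)
    grid = np.asarray(grid, dtype=float)
    h = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), h):
        raise ValueError("grid must be uniform")
    peclet = v_g * h / d_s
    if peclet >= 2.0:
        raise ValueError(
            f"cell Peclet number {peclet:.2f} >= 2: refine the grid "
            f"(need h < {2 * d_s / v_g:.3g} mm)"
        )
    rho_g = np.interp(grid, z_rho, rho_vals, left=0.0, right=0.0)
    n = len(grid)
    main = np.full(n, -2.0 * d_s / h**2)
    upper = np.full(n - 1, d_s / h**2 + v_g / (2 * h))
    lower = np.full(n - 1, d_s / h**2 - v_g / (2 * h))
    rhs = k * rho_g
    A = scipy.sparse.lil_matrix((n, n))
    A.setdiag(main)
    A.setdiag(upper, 1)
    A.setdiag(lower, -1)
    # left BC: one-sided second-order S'(z_min) = 0
    A[0, :] = 0.0
    A[0, 0], A[0, 1], A[0, 2] = -3.0 / (2 * h), 4.0 / (2 * h), -1.0 / (2 * h)
    rhs[0] = 0.0
    # right BC: Dirichlet S = S_far
    A[-1, :] = 0.0
    A[-1, -1] = 1.0
    rhs[-1] = s_far
    S = scipy.sparse.linalg.spsolve(A.tocsr(), rhs)
    if S.min() < -1e-6 * s_far:
        warnings.warn(
            f"consumption exhausts attractant (min S = {S.min():.3g}); clipping at 0",
            stacklevel=2,
        )
    S = np.clip(S, 0.0, None)
    return GradientField(
        z=grid, S=S,
        params={"v_g": v_g, "d_s": d_s, "k": k, "s_far": s_far,
                "koff": koff, "kon": kon},
    )


def perceived_gradient(field: GradientField) -> GradientField:
    """Fill ``g = d/dz ln[(1+S/K_off)/(1+S/K_on)]`` by centered differences."""
    if field.S is None:
        raise ValueError("field has no S; run infer_attractant_profile first")
    koff = field.params.get("koff", DEFAULT_KOFF)
    kon = field.params.get("kon", DEFAULT_KON)
    L = mwc_log_occupancy(field.S, koff, kon)
    g = np.gradient(L, field.z)
    if np.all(field.S < 0.01 * koff) and np.all(np.abs(g) < 1e-12):
        warnings.warn("S far below receptor sensitivity everywhere; g ~ 0",
                      stacklevel=2)
    field.g = g
    return field


def linearize_gradient(field: GradientField,
                       window: tuple[float, float]) -> tuple[float, float]:
    """Least-squares line ``g ~ g0 + g1 z`` on the window; stores the fit.

    Returns ``(g0, g1)``; the RMS residual is stored on the field.
    """
    if field.g is None:
        raise ValueError("field has no g; run perceived_gradient first")
    lo, hi = window
    mask = (field.z >= lo) & (field.z <= hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 grid points inside the window")
    zw, gw = field.z[mask], field.g[mask]
    if np.ptp(zw) == 0:
        raise ValueError("degenerate window")
    coeffs = np.polyfit(zw, gw, 1)
    g1, g0 = float(coeffs[0]), float(coeffs[1])
    resid = gw - (g0 + g1 * zw)
    field.g0, field.g1 = g0, g1
    field.fit_window = (float(lo), float(hi))
    field.fit_residual = float(np.sqrt(np.mean(resid**2)))
    return g0, g1
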