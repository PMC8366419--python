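"""Fourier-magnitude and real-space projectors, HIO/ER updates, shrinkwrap.

All operations act pointwise on flat node arrays, so they are identical on
every shell regardless of its angular sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PolarGrid
from .polar_fourier import (
    PolarField,
    inverse_polar_fourier_transform,
    polar_fourier_transform,
)

__all__ = [
    "SupportMask",
    "ProjectorSettings",
    "DegenerateSupportError",
    "magnitude_projection",
    "real_space_projection",
    "hio_update",
    "er_update",
    "shrinkwrap_update",
]


class DegenerateSupportError(ValueError):
    """Raised when a support mask keeps no nodes."""


@dataclass
class SupportMask:
    """Boolean support over the nodes of a real-space grid."""

    grid: PolarGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != (self.grid.n_nodes,):
            raise ValueError("mask size must equal the grid node count")
        if not self.inside.any():
            raise DegenerateSupportError("support mask keeps no nodes")


@dataclass
class ProjectorSettings:
    """Constraint set for the real-space projectors.

    beta is the HIO feedback strength; bounds are optional density clips
    applied inside the support.
    """

    beta: float = 0.9
    nonnegativity: bool = True
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and self.lower_bound > self.upper_bound
        ):
            raise ValueError("lower_bound must not exceed upper_bound")

    def effective_bounds(self) -> tuple[float, float]:
        lo = -np.inf if self.lower_bound is None else self.lower_bound
        if self.nonnegativity:
            lo = max(lo, 0.0)
        hi = np.inf if self.upper_bound is None else self.upper_bound
        return lo, hi


def magnitude_projection(F: PolarField, I_mod: PolarField) -> PolarField:
    """Impose |F'|^2 = max(I_mod, 0) while keeping the phase of F.

    Where F vanishes the phase is taken as 1, so F' is real sqrt(I) there.
    Negative modified intensities (noise) are clipped to zero.
    """
    if F.grid is not I_mod.grid and F.grid.n_nodes != I_mod.grid.n_nodes:
        raise ValueError("F and I_mod must share a grid")
    amp = np.sqrt(np.clip(I_mod.values.real, 0.0, None))
    Fv = np.asarray(F.values, dtype=complex)
    mod = np.abs(Fv)
    safe = np.where(mod > 0, mod, 1.0)
    # component-wise division: numpy's complex divide can overflow on
    # subnormal magnitudes
    phase = (Fv.real / safe) + 1j * (Fv.imag / safe)
    phase = np.where(mod > 0, phase, 1.0 + 0.0j)
    return PolarField(F.grid, amp * phase)


def real_space_projection(
    rho: PolarField, mask: SupportMask, settings: ProjectorSettings
) -> PolarField:
    """Zero outside the support, clip to the configured bounds inside."""
    if rho.grid.n_nodes != mask.grid.n_nodes:
        raise ValueError("density and mask must share a grid")
    lo, hi = settings.effective_bounds()
    out = np.clip(rho.values.real, lo, hi)
    out = np.where(mask.inside, out, 0.0)
    return PolarField(rho.grid, out)


def _feasible(rho: PolarField, mask: SupportMask, settings: ProjectorSettings) -> np.ndarray:
    lo, hi = settings.effective_bounds()
    v = rho.values.real
    return mask.inside & (v >= lo) & (v <= hi)


def hio_update(
    rho_prev: PolarField,
    rho_proj: PolarField,
    mask: SupportMask,
    settings: ProjectorSettings,
) -> PolarField:
    """Hybrid input-output: accept feasible nodes, negative feedback elsewhere.

    Nodes where the candidate density satisfies support and bounds keep the
    candidate; all others get rho_prev - beta * rho_proj.
    """
    if rho_prev.grid.n_nodes != rho_proj.grid.n_nodes:
        raise ValueError("densities must share a grid")
    ok = _feasible(rho_proj, mask, settings)
    out = np.where(
        ok, rho_proj.values.real, rho_prev.values.real - settings.beta * rho_proj.values.real
    )
    return PolarField(rho_prev.grid, out)


def er_update(
    rho_proj: PolarField, mask: SupportMask, settings: ProjectorSettings
) -> PolarField:
    """Error reduction: plain projection onto the real-space constraint set."""
    return real_space_projection(rho_proj, mask, settings)


def shrinkwrap_update(
    rho: PolarField,
    sigma: float,
    threshold_frac: float,
    fourier_grid: PolarGrid,
) -> SupportMask:
    """Re-estimate the support by thresholding a Gaussian-smoothed density.

    Smoothing happens in Fourier space (multiply the structure factors by
    exp(-q^2 sigma^2 / 2)); a direct real-space convolution is ill-defined on
    the non-uniform polar grid.  The mask keeps nodes where the smoothed
    density reaches ``threshold_frac`` of its maximum.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    if not np.any(rho.values):
        raise DegenerateSupportError("cannot shrinkwrap an all-zero density")
    F = polar_fourier_transform(rho, fourier_grid)
    q = fourier_grid.shell_radii_of_nodes()
    F = PolarField(fourier_grid, F.values * np.exp(-0.5 * (q * sigma) ** 2))
    smoothed = inverse_polar_fourier_transform(F, rho.grid).values
    peak = smoothed.max()
    if peak <= 0:
        raise DegenerateSupportError("smoothed density has no positive values")
    return SupportMask(rho.grid, smoothed >= threshold_frac * peak)
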