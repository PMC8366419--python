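"""Polar Fourier transform via per-order spherical Hankel transforms.

A density sampled on the real-space polar grid is carried to Fourier space in
three steps: per-shell spherical harmonic analysis, a radial spherical Hankel
transform independently for every (l, m), and per-shell harmonic synthesis on
the Fourier grid.  The inverse runs the mirrored pipeline.

Convention: F(q) = integral rho(r) exp(+i q.r) d^3r, so

    F_lm(q) = 4*pi * i^l   * sum_n j_l(q r_n) rho_lm(r_n) r_n^2 dr
    rho_lm(r) = (-i)^l/(2*pi^2) * sum_k j_l(q_k r) F_lm(q_k) q_k^2 dq

with j_l the spherical Bessel function.  The radial sums are plain uniform
quadrature with weight r^2*dr (radii start one step away from the origin), so
both directions are single cached matrix products per order l.

Real-space shells carry fewer harmonics than the common Fourier band limit L;
missing orders are treated as zero on the way out and truncated on the way
back in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn

from .grid import PolarGrid
from .sph_harmonics import (
    ShellFunction,
    ShellHarmonics,
    forward_sht,
    forward_sht_stack,
    inverse_sht,
    inverse_sht_stack,
)

__all__ = [
    "PolarField",
    "HarmonicCoefficients",
    "hankel_matrix",
    "field_to_harmonics",
    "harmonics_to_field",
    "polar_fourier_transform",
    "inverse_polar_fourier_transform",
    "intensity_from_structure_factors",
]


@dataclass
class PolarField:
    """Scalar values at every node of a polar grid, flat and shell-major."""

    grid: PolarGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"expected {self.grid.n_nodes} node values, got shape {self.values.shape}"
            )

    def shell(self, n: int) -> np.ndarray:
        """Shell ``n`` as an (L_n, M_n) view."""
        return self.values[self.grid.shell_slice(n)].reshape(self.grid.shell_shape(n))

    def copy(self) -> "PolarField":
        return PolarField(self.grid, self.values.copy())

    @classmethod
    def zeros(cls, grid: PolarGrid, dtype=float) -> "PolarField":
        return cls(grid, np.zeros(grid.n_nodes, dtype=dtype))


@dataclass
class HarmonicCoefficients:
    """Per-shell harmonic coefficient stack aligned with a grid's radii."""

    grid: PolarGrid
    shells: list[ShellHarmonics]

    def __post_init__(self) -> None:
        if len(self.shells) != self.grid.n_shells:
            raise ValueError("one coefficient block per shell required")
        for n, sh in enumerate(self.shells):
            if sh.band_limit > self.grid.L_per_shell[n]:
                raise ValueError(f"shell {n}: band limit exceeds grid band")

    def copy(self) -> "HarmonicCoefficients":
        return HarmonicCoefficients(
            self.grid, [ShellHarmonics(s.shell_index, s.coeffs.copy()) for s in self.shells]
        )


def _uniform_band(grid: PolarGrid) -> bool:
    return len(set(grid.L_per_shell)) == 1


def field_to_harmonics(f: PolarField) -> HarmonicCoefficients:
    """Forward SHT on every shell.

    Shells sharing one band limit (Fourier grids) are transformed in a single
    batched matrix product; real-space shells go one by one.
    """
    grid = f.grid
    if _uniform_band(grid):
        L, M = grid.shell_shape(0)
        stack = f.values.reshape(grid.n_shells, L, M)
        coeffs = forward_sht_stack(stack, grid, 0)
        shells = [ShellHarmonics(n, coeffs[n]) for n in range(grid.n_shells)]
    else:
        shells = [
            forward_sht(ShellFunction(n, f.shell(n)), grid)
            for n in range(grid.n_shells)
        ]
    return HarmonicCoefficients(grid, shells)


def harmonics_to_field(h: HarmonicCoefficients, real_output: bool = False) -> PolarField:
    """Inverse SHT on every shell; optionally drop the imaginary part."""
    grid = h.grid
    dtype = float if real_output else complex
    out = PolarField.zeros(grid, dtype=dtype)
    if _uniform_band(grid) and all(
        s.band_limit == grid.L_per_shell[0] for s in h.shells
    ):
        stack = np.stack([s.coeffs for s in h.shells])
        vals = inverse_sht_stack(stack, grid, 0)
        out.values[:] = (vals.real if real_output else vals).reshape(-1)
        return out
    for n in range(grid.n_shells):
        vals = inverse_sht(h.shells[n], grid).values
        out.values[grid.shell_slice(n)] = (vals.real if real_output else vals).ravel()
    return out


def hankel_matrix(
    l: int, real_grid: PolarGrid, fourier_grid: PolarGrid, direction: str
) -> np.ndarray:
    """Radial spherical Hankel transform matrix of order ``l``.

    forward: (N, N) with H[k, n] = 4*pi * i^l * j_l(q_k r_n) * r_n^2 * dr
    inverse: (N, N) with H[n, k] = (-i)^l/(2*pi^2) * j_l(q_k r_n) * q_k^2 * dq
    Cached per (grid pair, l, direction).
    """
    if real_grid.n_shells != fourier_grid.n_shells:
        raise ValueError("real and Fourier grids must share the shell count N")
    if direction not in ("forward", "inverse"):
        raise ValueError(f"unknown direction {direction!r}")
    key = ("hankel", id(fourier_grid) if direction == "forward" else id(real_grid), l, direction)
    cache = real_grid._caches if direction == "forward" else fourier_grid._caches
    if key not in cache:
        r = real_grid.radii
        q = fourier_grid.radii
        jl = spherical_jn(l, np.outer(q, r))  # (N_q, N_r)
        if direction == "forward":
            mat = (4.0 * np.pi * (1j**l)) * jl * (r**2 * real_grid.radial_step)[None, :]
        else:
            mat = ((-1j) ** l / (2.0 * np.pi**2)) * (
                jl.T * (q**2 * fourier_grid.radial_step)[None, :]
            )
        cache[key] = mat
    return cache[key]


def _radial_stack(h: HarmonicCoefficients, L: int) -> np.ndarray:
    """(L, 2L-1, N) radial profiles of every (l, m), zero where a shell lacks l."""
    grid = h.grid
    N = grid.n_shells
    R = np.zeros((L, 2 * L - 1, N), dtype=complex)
    for n, sh in enumerate(h.shells):
        Ln = sh.band_limit
        Lc = min(Ln, L)
        src = sh.coeffs[:Lc, Ln - Lc : Ln + Lc - 1]
        R[:Lc, L - Lc : L + Lc - 1, n] = src
    return R


def polar_fourier_transform(rho: PolarField, fourier_grid: PolarGrid) -> PolarField:
    """Real-space density -> complex structure factors on the Fourier grid."""
    if rho.grid.space != "real" or fourier_grid.space != "fourier":
        raise ValueError("expected a real-space field and a Fourier-space target grid")
    real_grid = rho.grid
    L = fourier_grid.L_per_shell[0]
    R = _radial_stack(field_to_harmonics(rho), L)
    Fc = np.empty_like(R)
    for l in range(L):
        H = hankel_matrix(l, real_grid, fourier_grid, "forward")
        Fc[l] = R[l] @ H.T  # (2L-1, N_r) x (N_r, N_q) -> (2L-1, N_q)
    shells = [ShellHarmonics(k, Fc[:, :, k]) for k in range(fourier_grid.n_shells)]
    return harmonics_to_field(HarmonicCoefficients(fourier_grid, shells))


def inverse_polar_fourier_transform(
    F: PolarField, real_grid: PolarGrid, check_imag: float | None = None
) -> PolarField:
    """Structure factors -> real-space density (real part).

    ``check_imag`` asserts the discarded imaginary norm is below that fraction
    of the real norm; physically consistent inputs sit near machine precision.
    """
    if F.grid.space != "fourier" or real_grid.space != "real":
        raise ValueError("expected a Fourier-space field and a real-space target grid")
    fourier_grid = F.grid
    L = fourier_grid.L_per_shell[0]
    R = _radial_stack(field_to_harmonics(F), L)
    Rc = np.empty_like(R)
    for l in range(L):
        H = hankel_matrix(l, real_grid, fourier_grid, "inverse")
        Rc[l] = R[l] @ H.T  # (2L-1, N_q) x (N_q, N_r) -> (2L-1, N_r)
    shells = []
    for n in range(real_grid.n_shells):
        Ln = real_grid.L_per_shell[n]
        Lc = min(Ln, L)
        block = np.zeros((Ln, 2 * Ln - 1), dtype=complex)
        block[:Lc, Ln - Lc : Ln + Lc - 1] = Rc[:Lc, L - Lc : L + Lc - 1, n]
        shells.append(ShellHarmonics(n, block))
    rho_c = harmonics_to_field(HarmonicCoefficients(real_grid, shells))
    if check_imag is not None:
        re = np.linalg.norm(rho_c.values.real)
        im = np.linalg.norm(rho_c.values.imag)
        if re > 0 and im > check_imag * re:
            raise ValueError(
                f"imaginary part {im:.3e} exceeds {check_imag:.1e} of real norm {re:.3e}"
            )
    return PolarField(real_grid, rho_c.values.real.copy())


def intensity_from_structure_factors(F: PolarField) -> PolarField:
    """I = |F|^2 pointwise (real, nonnegative)."""
    return PolarField(F.grid, (F.values.real**2 + F.values.imag**2))
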