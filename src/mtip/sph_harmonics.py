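"""Per-shell spherical harmonic analysis and synthesis.

The transform of a function sampled on one shell's (theta, phi) product grid
is computed as an FFT over azimuth followed by an associated Legendre matrix
product over inclination, and the inverse as the mirrored pair.  Harmonics
are orthonormal complex Y_l^m with the Condon-Shortley phase; the normalized
Legendre functions are generated by the standard fully-normalized three-term
recurrence in l at fixed m, which stays bounded at band limits of several
hundred.

Coefficients for a shell with band limit L are stored densely as an
(L, 2L-1) complex array indexed ``[l, m + L - 1]``; entries with |m| > l are
identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PolarGrid

__all__ = [
    "ShellFunction",
    "ShellHarmonics",
    "legendre_table",
    "associated_legendre_matrix",
    "forward_sht",
    "inverse_sht",
]


@dataclass
class ShellFunction:
    """Scalar samples on one shell's (L_n, M_n) angular grid."""

    shell_index: int
    values: np.ndarray


@dataclass
class ShellHarmonics:
    """Dense (L, 2L-1) coefficient block for one shell, m centered at L-1."""

    shell_index: int
    coeffs: np.ndarray

    @property
    def band_limit(self) -> int:
        return self.coeffs.shape[0]

    def coefficient(self, l: int, m: int) -> complex:
        if abs(m) > l or l >= self.band_limit:
            raise IndexError(f"(l={l}, m={m}) outside stored band")
        return self.coeffs[l, m + self.band_limit - 1]


def _normalized_legendre(L_band: int, x: np.ndarray) -> np.ndarray:
    """P̄_l^m(x) for 0 <= m <= l < L_band, shape (L_band, L_band, len(x)).

    Normalization: Y_l^m(theta, phi) = P̄_l^m(cos theta) e^{i m phi} is an
    orthonormal basis of the sphere; the Condon-Shortley (-1)^m is folded in.
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    P = np.zeros((L_band, L_band, x.size))
    P[0, 0] = 1.0 / np.sqrt(4.0 * np.pi)
    for m in range(1, L_band):
        # sectoral seed, includes Condon-Shortley sign
        P[m, m] = -np.sqrt((2 * m + 1) / (2.0 * m)) * s * P[m - 1, m - 1]
    for m in range(L_band):
        if m + 1 < L_band:
            P[m + 1, m] = np.sqrt(2 * m + 3.0) * x * P[m, m]
        for l in range(m + 2, L_band):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            P[l, m] = a * (x * P[l - 1, m] - b * P[l - 2, m])
    return P


def legendre_table(L_band: int, x: np.ndarray) -> np.ndarray:
    """Full table P̄_l^m(x) incl. negative m, shape (L_band, 2*L_band-1, len(x)).

    The m axis is centered: index ``m + L_band - 1``.  Negative orders follow
    P̄_l^{-m} = (-1)^m P̄_l^m.
    """
    pos = _normalized_legendre(L_band, x)
    L = L_band
    full = np.zeros((L, 2 * L - 1, np.asarray(x).size))
    for m in range(L):
        full[:, L - 1 + m, :] = pos[:, m, :]
        if m:
            full[:, L - 1 - m, :] = ((-1) ** m) * pos[:, m, :]
    return full


def _shell_table(grid: PolarGrid, shell: int) -> np.ndarray:
    """Cached legendre_table at the shell's own band limit and nodes."""
    key = ("legendre", shell)
    if key not in grid._caches:
        L = grid.L_per_shell[shell]
        x = np.cos(grid.theta_nodes[shell])
        grid._caches[key] = legendre_table(L, x)
    return grid._caches[key]


def _shell_ops(grid: PolarGrid, shell: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached batched-matmul operands: analysis (2L-1, L, L_n) with weights
    folded in, and synthesis (2L-1, L_n, L).  The batch axis is m."""
    key = ("sht_ops", shell)
    if key not in grid._caches:
        table = _shell_table(grid, shell)  # (L, 2L-1, L_n)
        w = grid.theta_weights[shell]
        analysis = np.ascontiguousarray((table * w[None, None, :]).transpose(1, 0, 2))
        synthesis = np.ascontiguousarray(table.transpose(1, 2, 0))
        grid._caches[key] = (analysis, synthesis)
    return grid._caches[key]


def associated_legendre_matrix(
    m: int, L_band: int, grid: PolarGrid, shell: int, kind: str = "synthesis"
) -> np.ndarray:
    """(L_band - |m|) x L_n matrix of P̄_l^m(cos theta_i), rows l = |m|..L_band-1.

    ``kind="analysis"`` folds the Gauss-Legendre weights and the 2*pi
    normalization of the phi integral into the columns, so for any fixed m
    the pair satisfies analysis @ synthesis.T = identity (discrete Legendre
    orthogonality).  Tables are cached on the grid after first build.
    """
    if abs(m) >= L_band:
        raise ValueError(f"|m|={abs(m)} must be < L_band={L_band}")
    if L_band > grid.L_per_shell[shell]:
        raise ValueError("band limit exceeds the shell's quadrature order")
    table = _shell_table(grid, shell)
    Lg = grid.L_per_shell[shell]
    rows = table[abs(m) : L_band, Lg - 1 + m, :]
    if kind == "analysis":
        return 2.0 * np.pi * rows * grid.theta_weights[shell][None, :]
    if kind == "synthesis":
        return rows.copy()
    raise ValueError(f"unknown kind {kind!r}")


def _check_shape(f: ShellFunction, grid: PolarGrid) -> None:
    n = f.shell_index
    if f.values.shape != grid.shell_shape(n):
        raise ValueError(
            f"shell {n}: values shape {f.values.shape} != grid shape {grid.shell_shape(n)}"
        )


def forward_sht(f: ShellFunction, grid: PolarGrid) -> ShellHarmonics:
    """Analysis: f(theta_i, phi_j) -> f_lm for l < L_n, |m| <= l.

    Computed as FFT over phi (with the 2*pi/M azimuthal quadrature weight)
    followed by a weighted associated-Legendre contraction over theta.  Exact
    for functions band-limited below the shell's L_n.
    """
    _check_shape(f, grid)
    return ShellHarmonics(
        f.shell_index,
        forward_sht_stack(f.values[None, :, :], grid, f.shell_index)[0],
    )


def forward_sht_stack(values: np.ndarray, grid: PolarGrid, shell: int) -> np.ndarray:
    """Analysis of a stack of functions sharing one shell's angular grid.

    ``values``: (S, L_n, M_n) -> coefficients (S, L_n, 2*L_n - 1).
    """
    L, M = grid.shell_shape(shell)
    if values.shape[1:] != (L, M):
        raise ValueError(f"values shape {values.shape[1:]} != grid shape {(L, M)}")
    G = np.fft.fft(values, axis=2) * (2.0 * np.pi / M)
    # columns m = -(L-1) .. (L-1): negative m wrap to the top of the FFT output
    Gm = np.concatenate([G[:, :, M - (L - 1) :], G[:, :, :L]], axis=2)
    analysis, _ = _shell_ops(grid, shell)  # (2L-1, L, L_n)
    C = np.matmul(analysis, np.ascontiguousarray(Gm.transpose(2, 1, 0)))
    return np.ascontiguousarray(C.transpose(2, 1, 0))  # (S, L, 2L-1)


def inverse_sht(h: ShellHarmonics, grid: PolarGrid) -> ShellFunction:
    """Synthesis: f(theta_i, phi_j) = sum_lm f_lm Y_l^m(theta_i, phi_j)."""
    n = h.shell_index
    L = grid.L_per_shell[n]
    Lb = h.band_limit
    if Lb > L:
        raise ValueError(f"coefficient band limit {Lb} exceeds shell band {L}")
    coeffs = h.coeffs
    if Lb < L:  # zero-pad into the shell's band
        padded = np.zeros((L, 2 * L - 1), dtype=complex)
        padded[:Lb, L - Lb : L + Lb - 1] = coeffs
        coeffs = padded
    return ShellFunction(n, inverse_sht_stack(coeffs[None, :, :], grid, n)[0])


def inverse_sht_stack(coeffs: np.ndarray, grid: PolarGrid, shell: int) -> np.ndarray:
    """Synthesis of a stack of coefficient blocks on one shell's grid.

    ``coeffs``: (S, L_n, 2*L_n - 1) -> samples (S, L_n, M_n).
    """
    L, M = grid.shell_shape(shell)
    if coeffs.shape[1:] != (L, 2 * L - 1):
        raise ValueError("coefficient block does not match the shell band limit")
    _, synthesis = _shell_ops(grid, shell)  # (2L-1, L_n, L)
    H = np.matmul(synthesis, np.ascontiguousarray(coeffs.transpose(2, 1, 0)))
    H = H.transpose(2, 1, 0)  # (S, L_n, 2L-1)
    S = coeffs.shape[0]
    spec = np.zeros((S, L, M), dtype=complex)
    spec[:, :, :L] = H[:, :, L - 1 :]
    spec[:, :, M - (L - 1) :] = H[:, :, : L - 1]
    return np.fft.ifft(spec, axis=2) * M
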