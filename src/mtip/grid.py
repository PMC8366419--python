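"""Spherical-polar sampling grids with Gauss-Legendre quadrature.

Real- and Fourier-space quantities live on stacks of concentric spherical
shells at equispaced radii.  On each shell the inclination angles are the
arccosines of Gauss-Legendre nodes (so integrals over cos(theta) are a
Gauss-Legendre sum) and the azimuths are equispaced (so integrals over phi
are an FFT-exact trapezoid sum).

Real-space shells use a per-shell band limit L_n = ceil(pi*n) + 1 that grows
with the shell index, keeping the angular point density roughly uniform in
space; Fourier-space shells share a single generous band limit
L = ceil(pi*(N-1)) + 15 so the harmonic transforms there lose nothing of the
real-space representation.  Azimuth counts are always M = 2L - 1, the minimum
that resolves orders |m| <= L - 1 without aliasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarGrid",
    "gauss_legendre_rule",
    "build_real_grid",
    "build_fourier_grid",
    "default_q_max",
]


def gauss_legendre_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of the ``order``-point Gauss-Legendre rule on [-1, 1].

    The rule integrates polynomials up to degree ``2*order - 1`` exactly and
    its weights sum to 2.  Nodes are returned in ascending order.
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ValueError(f"Gauss-Legendre order must be a positive integer, got {order!r}")
    nodes, weights = np.polynomial.legendre.leggauss(int(order))
    return nodes, weights


@dataclass(eq=False)
class PolarGrid:
    """A stack of spherical shells with per-shell angular quadrature.

    Attributes
    ----------
    space : {"real", "fourier"}
        Which domain the radii live in (length vs inverse length).
    radii : (N,) ndarray
        Strictly increasing, equispaced, starting at one radial step (the
        origin is excluded to avoid degenerate shells).
    L_per_shell, M_per_shell : tuple of int
        Inclination and azimuth counts per shell.
    theta_nodes, theta_weights : tuple of ndarray
        Per-shell inclination angles in (0, pi), ascending, and the matching
        Gauss-Legendre weights (in the cos(theta) variable; each set sums
        to 2).
    phi_nodes : tuple of ndarray
        Per-shell equispaced azimuths ``2*pi*k/M_n``.
    """

    space: str
    radii: np.ndarray
    L_per_shell: tuple[int, ...]
    M_per_shell: tuple[int, ...]
    theta_nodes: tuple[np.ndarray, ...]
    theta_weights: tuple[np.ndarray, ...]
    phi_nodes: tuple[np.ndarray, ...]
    _caches: dict = field(default_factory=dict, repr=False)

    # -- structural helpers -------------------------------------------------

    @property
    def n_shells(self) -> int:
        return len(self.radii)

    @property
    def radial_step(self) -> float:
        return float(self.radii[0])

    @property
    def shell_sizes(self) -> tuple[int, ...]:
        return tuple(L * M for L, M in zip(self.L_per_shell, self.M_per_shell))

    @property
    def n_nodes(self) -> int:
        return int(sum(self.shell_sizes))

    def shell_slice(self, n: int) -> slice:
        """Flat-array slice holding shell ``n`` (0-based)."""
        start = int(sum(self.shell_sizes[:n]))
        return slice(start, start + self.shell_sizes[n])

    def shell_shape(self, n: int) -> tuple[int, int]:
        return (self.L_per_shell[n], self.M_per_shell[n])

    # -- quadrature ---------------------------------------------------------

    def solid_angle_weights(self, n: int) -> np.ndarray:
        """(L_n, M_n) weights integrating over the unit sphere (sum = 4*pi)."""
        L, M = self.shell_shape(n)
        return np.broadcast_to(
            self.theta_weights[n][:, None] * (2.0 * np.pi / M), (L, M)
        )

    def volume_weights(self) -> np.ndarray:
        """Flat per-node weights for the plain volume integral (r^2 dr dOmega)."""
        key = "volume_weights"
        if key not in self._caches:
            dr = self.radial_step
            parts = [
                (self.radii[n] ** 2 * dr) * self.solid_angle_weights(n).ravel()
                for n in range(self.n_shells)
            ]
            self._caches[key] = np.concatenate(parts)
        return self._caches[key]

    def nodes_xyz(self) -> np.ndarray:
        """(n_nodes, 3) Cartesian coordinates of every grid node, shell-major."""
        key = "nodes_xyz"
        if key not in self._caches:
            parts = []
            for n in range(self.n_shells):
                r = self.radii[n]
                th = self.theta_nodes[n][:, None]
                ph = self.phi_nodes[n][None, :]
                st = np.sin(th)
                x = r * st * np.cos(ph)
                y = r * st * np.sin(ph)
                z = r * np.cos(th) * np.ones_like(ph)
                parts.append(
                    np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
                )
            self._caches[key] = np.concatenate(parts, axis=0)
        return self._caches[key]

    def shell_radii_of_nodes(self) -> np.ndarray:
        """Flat per-node radius (constant within a shell)."""
        key = "node_radii"
        if key not in self._caches:
            self._caches[key] = np.concatenate(
                [np.full(sz, self.radii[n]) for n, sz in enumerate(self.shell_sizes)]
            )
        return self._caches[key]

    def _validate(self) -> None:
        dr = np.diff(self.radii)
        if self.radii[0] <= 0 or np.any(dr <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if not np.allclose(dr, dr[0], rtol=0, atol=1e-12 * self.radii[-1]):
            raise ValueError("radii must be equispaced")
        for n in range(self.n_shells):
            if abs(self.theta_weights[n].sum() - 2.0) > 1e-10:
                raise ValueError(f"shell {n}: Gauss-Legendre weights do not sum to 2")


def _angular_rule(L: int, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # theta ascending <=> cos(theta) descending
    x, w = gauss_legendre_rule(L)
    order = np.argsort(-x)
    theta = np.arccos(x[order])
    weights = w[order]
    phi = 2.0 * np.pi * np.arange(M) / M
    return theta, weights, phi


def build_real_grid(N: int, r_max: float) -> PolarGrid:
    """Real-space grid: N shells at r_n = n*r_max/N, band limit growing with n."""
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise ValueError(f"need at least 2 shells, got N={N!r}")
    if r_max <= 0:
        raise ValueError(f"r_max must be positive, got {r_max!r}")
    radii = np.arange(1, N + 1) * (float(r_max) / N)
    Ls = tuple(math.ceil(math.pi * n) + 1 for n in range(1, N + 1))
    Ms = tuple(2 * L - 1 for L in Ls)
    thetas, weights, phis = zip(*(_angular_rule(L, M) for L, M in zip(Ls, Ms)))
    grid = PolarGrid("real", radii, Ls, Ms, thetas, weights, phis)
    grid._validate()
    return grid


def build_fourier_grid(N: int, q_max: float) -> PolarGrid:
    """Fourier-space grid: N shells at q_k = k*q_max/N, one shared band limit."""
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise ValueError(f"need at least 2 shells, got N={N!r}")
    if q_max <= 0:
        raise ValueError(f"q_max must be positive, got {q_max!r}")
    radii = np.arange(1, N + 1) * (float(q_max) / N)
    L = math.ceil(math.pi * (N - 1)) + 15
    M = 2 * L - 1
    theta, w, phi = _angular_rule(L, M)
    Ls = (L,) * N
    Ms = (M,) * N
    grid = PolarGrid("fourier", radii, Ls, Ms, (theta,) * N, (w,) * N, (phi,) * N)
    grid._validate()
    return grid


def default_q_max(N: int, r_max: float) -> float:
    """Nyquist-like pairing of the radial grids: q_max = pi*N/(2*r_max)."""
    return math.pi * N / (2.0 * float(r_max))
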