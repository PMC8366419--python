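"""Gaussian-blob phantoms and simulated correlation data.

Phantoms are sums of isotropic 3D Gaussians.  They are strictly positive,
compactly concentrated and essentially band-limited, i.e. they have exactly
the statistical structure the reconstruction assumes, and their polar
Fourier transform has a closed form per blob (translation phase times a
Gaussian), which makes them an analytic oracle for the transform stack.

External-style correlation data are produced by running the forward model:
density -> structure factors -> intensity -> intensity harmonics -> B_l.
Optional noise is additive Hermitian Gaussian on each B_l matrix; shot noise
on detector images is a different (out-of-scope) regime, since this package
consumes correlations, not snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import CorrelationData, compute_Bl
from .grid import PolarGrid
from .polar_fourier import (
    PolarField,
    field_to_harmonics,
    intensity_from_structure_factors,
    polar_fourier_transform,
)

__all__ = [
    "PhantomSpec",
    "default_three_blob_spec",
    "make_phantom",
    "simulate_external_Bl",
    "add_noise",
]


@dataclass
class PhantomSpec:
    """Mixture of Gaussian blobs inside a ball of radius r_max.

    Each blob is (center, amplitude, width sigma); centers must stay within
    0.7 * r_max so the object sits comfortably inside the support ball.
    """

    blobs: list[tuple[np.ndarray, float, float]]
    r_max: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.blobs:
            raise ValueError("a phantom needs at least one blob")
        norm_blobs = []
        for center, amp, sigma in self.blobs:
            center = np.asarray(center, dtype=float)
            if center.shape != (3,):
                raise ValueError("blob centers must be 3-vectors")
            if np.linalg.norm(center) > 0.7 * self.r_max + 1e-12:
                raise ValueError(
                    f"blob center {center} outside 0.7*r_max = {0.7 * self.r_max}"
                )
            if amp <= 0 or sigma <= 0:
                raise ValueError("blob amplitude and width must be positive")
            norm_blobs.append((center, float(amp), float(sigma)))
        self.blobs = norm_blobs

    @classmethod
    def random(
        cls, n_blobs: int, r_max: float, seed: int,
        width_range: tuple[float, float] = (0.1, 0.18),
    ) -> "PhantomSpec":
        """Randomized spec: centers uniform in the 0.55*r_max ball."""
        rng = np.random.default_rng(seed)
        blobs = []
        for _ in range(n_blobs):
            while True:
                c = rng.uniform(-0.55 * r_max, 0.55 * r_max, size=3)
                if np.linalg.norm(c) <= 0.55 * r_max:
                    break
            amp = rng.uniform(0.6, 1.0)
            sig = rng.uniform(*width_range) * r_max
            blobs.append((c, amp, sig))
        return cls(blobs, r_max, seed=seed)


def default_three_blob_spec(r_max: float = 1.0) -> PhantomSpec:
    """The canonical three-blob test object used throughout the test suite.

    Blob widths are at least 2.4 radial steps of the N=16 grid so the object
    is well resolved, and the centers are separated by a couple of widths so
    the object is genuinely non-spherical (all even B_l orders are exercised).
    """
    return PhantomSpec(
        blobs=[
            (np.array([0.25, 0.00, 0.10]) * r_max, 1.0, 0.20 * r_max),
            (np.array([-0.20, 0.22, -0.05]) * r_max, 0.8, 0.17 * r_max),
            (np.array([0.02, -0.24, -0.18]) * r_max, 0.9, 0.15 * r_max),
        ],
        r_max=r_max,
    )


def make_phantom(spec: PhantomSpec, grid: PolarGrid) -> PolarField:
    """Evaluate the blob mixture at every node of a real-space grid."""
    if grid.space != "real":
        raise ValueError("phantoms are real-space objects")
    xyz = grid.nodes_xyz()
    rho = np.zeros(grid.n_nodes)
    for center, amp, sigma in spec.blobs:
        d2 = np.sum((xyz - center[None, :]) ** 2, axis=1)
        rho += amp * np.exp(-d2 / (2.0 * sigma**2))
    return PolarField(grid, rho)


def phantom_structure_factors(spec: PhantomSpec, fourier_grid: PolarGrid) -> PolarField:
    """Closed-form structure factors of the blob mixture (analytic oracle).

    F(q) = sum_b A_b (2 pi sigma_b^2)^{3/2} exp(-q^2 sigma_b^2 / 2) exp(i q.c_b)
    under the e^{+i q.r} forward convention.
    """
    if fourier_grid.space != "fourier":
        raise ValueError("need a Fourier grid")
    qxyz = fourier_grid.nodes_xyz()
    q2 = np.sum(qxyz**2, axis=1)
    F = np.zeros(fourier_grid.n_nodes, dtype=complex)
    for center, amp, sigma in spec.blobs:
        F += (
            amp
            * (2.0 * np.pi * sigma**2) ** 1.5
            * np.exp(-0.5 * q2 * sigma**2)
            * np.exp(1j * (qxyz @ center))
        )
    return PolarField(fourier_grid, F)


def simulate_external_Bl(
    rho: PolarField, fourier_grid: PolarGrid, even_only: bool = True
) -> CorrelationData:
    """Forward-model correlation data from a phantom density."""
    F = polar_fourier_transform(rho, fourier_grid)
    I = intensity_from_structure_factors(F)
    I_harm = field_to_harmonics(I)
    L = fourier_grid.L_per_shell[0]
    l_values = np.arange(0, L, 2) if even_only else np.arange(L)
    data = compute_Bl(I_harm, l_values)
    data.provenance = "external"
    data.even_only = even_only
    return data


def add_noise(B: CorrelationData, rel_level: float, seed: int) -> CorrelationData:
    """Additive Hermitian Gaussian noise, scaled per order to the data norm.

    Each B_l receives rel_level * ||B_l||_F / N * H with H = (G + G^H)/2 and
    G standard complex Gaussian; Hermiticity is exact by construction.
    """
    if rel_level < 0:
        raise ValueError("rel_level must be nonnegative")
    out = B.copy()
    out.provenance = f"{B.provenance}+noise"
    if rel_level == 0:
        out.provenance = B.provenance
        return out
    rng = np.random.default_rng(seed)
    N = B.q.size
    for i in range(out.Bl.shape[0]):
        G = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
        H = 0.5 * (G + G.conj().T)
        out.Bl[i] += rel_level * np.linalg.norm(B.Bl[i]) / N * H
    return out
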