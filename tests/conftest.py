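"""Shared fixtures: small grids, phantoms and independent oracles.

Oracles here deliberately avoid the package's own transform code paths:
spherical harmonics come from scipy.special.sph_harm_y and the Fourier
integral is evaluated as a direct quadrature sum over all grid nodes.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import sph_harm_y

from mtip.grid import build_fourier_grid, build_real_grid, default_q_max
from mtip.polar_fourier import PolarField
from mtip.synthetic import default_three_blob_spec, make_phantom, simulate_external_Bl


@pytest.fixture(scope="session")
def real_grid_8():
    return build_real_grid(8, 1.0)


@pytest.fixture(scope="session")
def fourier_grid_8():
    return build_fourier_grid(8, default_q_max(8, 1.0))


@pytest.fixture(scope="session")
def real_grid_16():
    return build_real_grid(16, 1.0)


@pytest.fixture(scope="session")
def fourier_grid_16():
    return build_fourier_grid(16, default_q_max(16, 1.0))


@pytest.fixture(scope="session")
def phantom_8(real_grid_8):
    return make_phantom(default_three_blob_spec(1.0), real_grid_8)


@pytest.fixture(scope="session")
def bl_data_8(phantom_8, fourier_grid_8):
    return simulate_external_Bl(phantom_8, fourier_grid_8, even_only=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# oracles


def sht_oracle(values: np.ndarray, grid, shell: int) -> np.ndarray:
    """Direct double-sum spherical harmonic analysis via scipy harmonics.

    f_lm = sum_ij w_i (2 pi / M) conj(Y_l^m(theta_i, phi_j)) f(theta_i, phi_j)
    """
    L, M = grid.shell_shape(shell)
    theta = grid.theta_nodes[shell]
    phi = grid.phi_nodes[shell]
    w = grid.theta_weights[shell]
    coeffs = np.zeros((L, 2 * L - 1), dtype=complex)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    for l in range(L):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, m, TH, PH)
            coeffs[l, m + L - 1] = np.sum(
                w[:, None] * (2 * np.pi / M) * np.conj(Y) * values
            )
    return coeffs


def random_bandlimited_shell(grid, shell: int, l_max: int, rng) -> np.ndarray:
    """Random function with content only below l_max, sampled on the shell."""
    L, M = grid.shell_shape(shell)
    theta = grid.theta_nodes[shell]
    phi = grid.phi_nodes[shell]
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    f = np.zeros((L, M), dtype=complex)
    for l in range(min(l_max, L)):
        for m in range(-l, l + 1):
            c = rng.normal() + 1j * rng.normal()
            f += c * sph_harm_y(l, m, TH, PH)
    return f


def brute_force_ft(rho: PolarField, fourier_grid) -> np.ndarray:
    """F(q) = sum_nodes rho(x) w(x) exp(+i q.x): direct 3D quadrature."""
    xyz = rho.grid.nodes_xyz()
    w = rho.grid.volume_weights()
    qxyz = fourier_grid.nodes_xyz()
    out = np.empty(fourier_grid.n_nodes, dtype=complex)
    chunk = 2048
    weighted = rho.values * w
    for start in range(0, qxyz.shape[0], chunk):
        block = qxyz[start : start + chunk]
        out[start : start + chunk] = np.exp(1j * block @ xyz.T) @ weighted
    return out
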