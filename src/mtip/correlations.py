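"""Angular cross-correlation data B_l(q,q') and the correlation projector.

For intensity harmonics I_lm(q) the fluctuation-scattering correlation data
are

    B_l(q_k, q_k') = sum_{m=-l}^{l} I_lm(q_k) * conj(I_lm(q_k')),

one Hermitian positive-semidefinite N x N matrix per order l with rank at
most 2l+1.  The correlation projector replaces computed harmonics with the
nearest set (in the Frobenius sense, per order) that reproduces the external
B_l exactly: factor B_l = F_l F_l^H with F_l of N x (2l+1) via a clipped
eigendecomposition, then rotate the factor onto the computed harmonics by
the orthogonal-Procrustes unitary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd

from .grid import PolarGrid
from .polar_fourier import HarmonicCoefficients
from .sph_harmonics import ShellHarmonics

__all__ = [
    "CorrelationData",
    "compute_Bl",
    "factor_Bl",
    "correlation_projection",
]

_HERMITIAN_TOL = 1e-10


@dataclass
class CorrelationData:
    """B_l(q, q') matrix stack over harmonic orders.

    ``Bl[i]`` is the N x N matrix for order ``l_values[i]``.  ``even_only``
    marks data restricted to even orders (the physical case for a real
    density, where Friedel symmetry voids odd-l intensity harmonics).
    """

    q: np.ndarray
    l_values: np.ndarray
    Bl: np.ndarray
    even_only: bool = True
    provenance: str = "computed"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.l_values = np.asarray(self.l_values, dtype=int)
        self.Bl = np.asarray(self.Bl, dtype=complex)
        n = self.q.size
        if self.Bl.shape != (self.l_values.size, n, n):
            raise ValueError(
                f"Bl shape {self.Bl.shape} inconsistent with {self.l_values.size} orders on {n} shells"
            )

    def matrix(self, l: int) -> np.ndarray:
        idx = np.nonzero(self.l_values == l)[0]
        if idx.size == 0:
            raise KeyError(f"order l={l} not present")
        return self.Bl[idx[0]]

    def validate(self, tol: float = _HERMITIAN_TOL) -> None:
        """Check Hermiticity and diagonal nonnegativity."""
        for l, B in zip(self.l_values, self.Bl):
            scale = max(np.abs(B).max(), 1.0)
            if np.abs(B - B.conj().T).max() > tol * scale:
                raise ValueError(f"B_{l} is not Hermitian within tolerance")
            d = np.diag(B)
            if np.abs(d.imag).max() > tol * scale or d.real.min() < -tol * scale:
                raise ValueError(f"B_{l} diagonal must be real and nonnegative")

    def copy(self) -> "CorrelationData":
        return CorrelationData(
            self.q.copy(), self.l_values.copy(), self.Bl.copy(),
            self.even_only, self.provenance,
        )


def _intensity_stack(I_harm: HarmonicCoefficients) -> np.ndarray:
    """(N, L, 2L-1) array of I_lm(q_k) from a Fourier-grid harmonic stack."""
    grid = I_harm.grid
    if grid.space != "fourier":
        raise ValueError("intensity harmonics must live on a Fourier grid")
    L = grid.L_per_shell[0]
    out = np.zeros((grid.n_shells, L, 2 * L - 1), dtype=complex)
    for k, sh in enumerate(I_harm.shells):
        if sh.band_limit != L:
            raise ValueError("all Fourier shells must share the band limit")
        out[k] = sh.coeffs
    return out


def _order_columns(stack: np.ndarray, l: int) -> np.ndarray:
    """A_l: (N, 2l+1) matrix with columns m = -l..l of I_lm(q_k)."""
    L = stack.shape[1]
    return stack[:, l, L - 1 - l : L + l]


def compute_Bl(
    I_harm: HarmonicCoefficients, l_values: np.ndarray | None = None
) -> CorrelationData:
    """Correlation matrices B_l = A_l A_l^H from intensity harmonics."""
    stack = _intensity_stack(I_harm)
    L = stack.shape[1]
    if l_values is None:
        l_values = np.arange(L)
    l_values = np.asarray(l_values, dtype=int)
    if l_values.size and l_values.max() >= L:
        raise ValueError("requested order exceeds the harmonic band limit")
    N = stack.shape[0]
    Bl = np.empty((l_values.size, N, N), dtype=complex)
    for i, l in enumerate(l_values):
        A = _order_columns(stack, l)
        Bl[i] = A @ A.conj().T
    even_only = bool(l_values.size) and bool(np.all(l_values % 2 == 0))
    return CorrelationData(I_harm.grid.radii.copy(), l_values, Bl,
                           even_only=even_only, provenance="computed")


def _factor_matrix(B: np.ndarray, l: int, clip_rel: float = 1e-12) -> np.ndarray:
    """Clipped-eigenvalue rank-(2l+1) factor of a Hermitian matrix."""
    lam, V = np.linalg.eigh(0.5 * (B + B.conj().T))
    lam = lam[::-1].copy()
    V = V[:, ::-1]
    lam[lam < max(0.0, clip_rel * max(lam[0], 0.0))] = 0.0
    k = 2 * l + 1
    lam = lam[:k]
    V = V[:, :k]
    F = V * np.sqrt(lam)[None, :]
    if F.shape[1] < k:  # N < 2l+1: pad columns so shapes stay (N, 2l+1)
        F = np.pad(F, ((0, 0), (0, k - F.shape[1])))
    return F


def factor_Bl(Bl_ext: CorrelationData, l: int, clip_rel: float = 1e-12) -> np.ndarray:
    """N x (2l+1) factor F_l with F_l F_l^H ~= B_l.

    Eigendecompose the Hermitian B_l, clip eigenvalues below
    ``max(0, clip_rel * lambda_max)`` to zero, keep the 2l+1 largest.  Exact
    when B_l is PSD with rank <= 2l+1 (always true for noiseless data built
    from the forward model).
    """
    B = Bl_ext.matrix(l)
    scale = max(np.abs(B).max(), 1.0)
    if np.abs(B - B.conj().T).max() > _HERMITIAN_TOL * scale:
        raise ValueError(f"B_{l} is not Hermitian within tolerance")
    return _factor_matrix(B, l, clip_rel)


def _procrustes_rotation(F: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Unitary R minimizing ||A - F R||_F (SVD of F^H A)."""
    U, _, Vh = svd(F.conj().T @ A)
    return U @ Vh


def _real_basis_matrix(l: int) -> np.ndarray:
    """Unitary W mapping complex coefficients a_m (m = -l..l) to real-basis
    coefficients b = W a, real whenever the underlying function is real.

    Rows: b_0 = a_0; for m > 0 the cosine term ((-1)^m a_m + a_{-m})/sqrt(2)
    and the sine term i((-1)^m a_m - a_{-m})/sqrt(2).
    """
    n = 2 * l + 1
    W = np.zeros((n, n), dtype=complex)
    c = l  # index of m=0 in -l..l ordering
    W[c, c] = 1.0
    for m in range(1, l + 1):
        sgn = (-1) ** m
        W[c + m, c + m] = sgn / np.sqrt(2)   # cosine row
        W[c + m, c - m] = 1.0 / np.sqrt(2)
        W[c - m, c + m] = 1j * sgn / np.sqrt(2)  # sine row
        W[c - m, c - m] = -1j / np.sqrt(2)
    return W


def correlation_projection(
    I_comp: HarmonicCoefficients, Bl_ext: CorrelationData
) -> HarmonicCoefficients:
    """Project computed intensity harmonics onto consistency with external B_l.

    Per order l present in the data: A_l <- F_l R_l with R_l the Procrustes
    unitary, so the output reproduces B_l exactly while staying as close as
    possible to the computed harmonics.  Orders absent from the data (odd l
    in even-only mode) are zeroed.
    """
    grid = I_comp.grid
    if grid.radii.shape != Bl_ext.q.shape or not np.allclose(
        grid.radii, Bl_ext.q, rtol=1e-10, atol=0
    ):
        raise ValueError("correlation data q grid does not match the Fourier grid")
    stack = _intensity_stack(I_comp)
    N, L = stack.shape[0], stack.shape[1]
    out = np.zeros_like(stack)
    # The external data are fixed across iterations; factor each B_l once.
    # Data consistent with a REAL intensity are real-symmetric in the real
    # spherical-harmonic basis; matching there with a real orthogonal
    # Procrustes keeps the projected harmonics realness-preserving, which the
    # complex-unitary match does not.
    factors = getattr(Bl_ext, "_factor_cache", None)
    if factors is None:
        factors = {}
        # Scale for the realness test is global: high-l matrices are tiny and
        # carry only roundoff, so a per-matrix relative test misclassifies.
        global_scale = max(float(np.abs(Bl_ext.Bl).max()), 1e-300)
        for l in Bl_ext.l_values:
            l = int(l)
            W = _real_basis_matrix(l)
            # For a real intensity, B_l = sum_m a_lm(q) a_lm(q') over REAL
            # coefficients, hence real symmetric as computed (the matrix is
            # invariant under a unitary change of the m basis).
            B = Bl_ext.matrix(l)
            real_route = np.abs(B.imag).max() <= 1e-8 * global_scale
            if real_route:
                F = _factor_matrix(B.real, l)
            else:
                F = factor_Bl(Bl_ext, l)
            factors[l] = (F, W, real_route)
        Bl_ext._factor_cache = factors
    for l in range(L):
        if l not in factors:
            continue
        A = _order_columns(stack, l)
        F, W, real_route = factors[l]
        if real_route:
            A_real = (A @ W.T).real
            R = _procrustes_rotation(F, A_real)
            out[:, l, L - 1 - l : L + l] = (F @ R) @ np.conj(W)
        else:
            R = _procrustes_rotation(F, A)
            out[:, l, L - 1 - l : L + l] = F @ R
    shells = [ShellHarmonics(k, out[k]) for k in range(N)]
    return HarmonicCoefficients(grid, shells)
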