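"""Correlation data B_l, low-rank factorization and the Procrustes projector."""

import numpy as np
import pytest
from scipy.stats import unitary_group

from mtip.correlations import (
    CorrelationData,
    compute_Bl,
    correlation_projection,
    factor_Bl,
)
from mtip.grid import build_fourier_grid
from mtip.polar_fourier import HarmonicCoefficients
from mtip.sph_harmonics import ShellHarmonics


def harmonics_from_stack(grid, stack):
    """Wrap an (N, L, 2L-1) intensity-coefficient array."""
    return HarmonicCoefficients(
        grid, [ShellHarmonics(k, stack[k]) for k in range(stack.shape[0])]
    )


def random_harmonics(grid, rng, l_max=None, real_intensity=False):
    N = grid.n_shells
    L = grid.L_per_shell[0]
    l_max = L if l_max is None else l_max
    stack = np.zeros((N, L, 2 * L - 1), dtype=complex)
    for l in range(l_max):
        for m in range(-l, l + 1):
            stack[:, l, m + L - 1] = rng.normal(size=N) + 1j * rng.normal(size=N)
    if real_intensity:
        for l in range(l_max):
            for m in range(0, l + 1):
                stack[:, l, L - 1 - m] = (-1) ** m * np.conj(stack[:, l, L - 1 + m])
            stack[:, l, L - 1] = stack[:, l, L - 1].real
    return stack


@pytest.fixture(scope="module")
def grid5():
    return build_fourier_grid(5, 5.0)


class TestComputeBl:
    def test_isotropic_rank_one(self, grid5, rng):
        stack = np.zeros((5, grid5.L_per_shell[0], 2 * grid5.L_per_shell[0] - 1), complex)
        a = rng.normal(size=5) + 1j * rng.normal(size=5)
        stack[:, 0, grid5.L_per_shell[0] - 1] = a
        B = compute_Bl(harmonics_from_stack(grid5, stack), np.arange(4))
        np.testing.assert_allclose(B.matrix(0), np.outer(a, np.conj(a)), atol=1e-14)
        for l in (1, 2, 3):
            assert np.abs(B.matrix(l)).max() == 0.0

    def test_matches_triple_loop_oracle(self, grid5, rng):
        stack = random_harmonics(grid5, rng, l_max=4)
        B = compute_Bl(harmonics_from_stack(grid5, stack), np.arange(4))
        L = grid5.L_per_shell[0]
        for l in range(4):
            oracle = np.zeros((5, 5), dtype=complex)
            for k in range(5):
                for kp in range(5):
                    for m in range(-l, l + 1):
                        oracle[k, kp] += stack[k, l, m + L - 1] * np.conj(
                            stack[kp, l, m + L - 1]
                        )
            # equality up to summation-order roundoff of the BLAS product
            np.testing.assert_allclose(
                B.matrix(l), oracle, rtol=0, atol=1e-13 * np.abs(oracle).max()
            )

    def test_invariants_hold(self, grid5, rng):
        stack = random_harmonics(grid5, rng, l_max=5)
        B = compute_Bl(harmonics_from_stack(grid5, stack), np.arange(5))
        B.validate()  # Hermitian, real nonnegative diagonal
        for i, l in enumerate(B.l_values):
            assert np.linalg.matrix_rank(B.Bl[i], tol=1e-10) <= 2 * l + 1
            assert np.diag(B.Bl[i]).real.min() >= 0


class TestFactorBl:
    def test_rank_one_factor(self, grid5, rng):
        a = rng.normal(size=5) + 1j * rng.normal(size=5)
        B = CorrelationData(grid5.radii, [0], np.outer(a, np.conj(a))[None], even_only=True)
        F = factor_Bl(B, 0)
        np.testing.assert_allclose(F @ F.conj().T, B.Bl[0], atol=1e-10)
        # F equals a up to a unit phase
        phase = F[np.argmax(np.abs(a)), 0] / a[np.argmax(np.abs(a))]
        np.testing.assert_allclose(F[:, 0], a * phase, atol=1e-10)

    def test_negative_definite_clips_to_zero(self, grid5):
        B = CorrelationData(grid5.radii, [1], (-np.eye(5, dtype=complex))[None])
        F = factor_Bl(B, 1)
        assert F.shape == (5, 3)
        assert np.abs(F).max() == 0.0

    def test_reconstructs_forward_model_data(self, grid5, rng):
        stack = random_harmonics(grid5, rng, l_max=3)
        B = compute_Bl(harmonics_from_stack(grid5, stack), np.arange(3))
        for l in range(3):
            F = factor_Bl(B, l)
            err = np.linalg.norm(F @ F.conj().T - B.matrix(l)) / np.linalg.norm(
                B.matrix(l)
            )
            assert err < 1e-10

    def test_non_hermitian_rejected(self, grid5, rng):
        M = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        B = CorrelationData(grid5.radii, [1], M[None])
        with pytest.raises(ValueError):
            factor_Bl(B, 1)


class TestCorrelationProjection:
    def test_fixed_point_when_consistent(self, grid5, rng):
        """Data generated from the harmonics themselves leave them unchanged."""
        stack = random_harmonics(grid5, rng, l_max=6, real_intensity=True)
        harm = harmonics_from_stack(grid5, stack)
        B = compute_Bl(harm, np.arange(6))
        out = correlation_projection(harm, B)
        for k in range(5):
            got = out.shells[k].coeffs[:6]
            want = stack[k, :6]
            assert np.abs(got - want).max() < 1e-8 * max(np.abs(want).max(), 1)

    def test_output_reproduces_external_Bl(self, grid5, rng):
        """Projected harmonics reproduce the external data regardless of input."""
        truth = random_harmonics(grid5, rng, l_max=6, real_intensity=True)
        B = compute_Bl(harmonics_from_stack(grid5, truth), np.arange(0, 6, 2))
        other = random_harmonics(grid5, rng, l_max=6, real_intensity=True)
        out = correlation_projection(harmonics_from_stack(grid5, other), B)
        B_out = compute_Bl(out, B.l_values)
        for i in range(B.l_values.size):
            scale = max(np.linalg.norm(B.Bl[i]), 1e-300)
            assert np.linalg.norm(B_out.Bl[i] - B.Bl[i]) / scale < 1e-8

    def test_orders_absent_from_data_are_zeroed(self, grid5, rng):
        stack = random_harmonics(grid5, rng, l_max=6, real_intensity=True)
        harm = harmonics_from_stack(grid5, stack)
        B = compute_Bl(harm, np.arange(0, 6, 2))  # even orders only
        out = correlation_projection(harm, B)
        L = grid5.L_per_shell[0]
        for k in range(5):
            for l in (1, 3, 5):
                assert np.abs(out.shells[k].coeffs[l]).max() == 0.0

    def test_idempotent_at_data_level(self, grid5, rng):
        truth = random_harmonics(grid5, rng, l_max=5, real_intensity=True)
        B = compute_Bl(harmonics_from_stack(grid5, truth), np.arange(5))
        start = random_harmonics(grid5, rng, l_max=5, real_intensity=True)
        once = correlation_projection(harmonics_from_stack(grid5, start), B)
        twice = correlation_projection(once, B)
        B1 = compute_Bl(once, B.l_values)
        B2 = compute_Bl(twice, B.l_values)
        for i in range(B.l_values.size):
            scale = max(np.linalg.norm(B1.Bl[i]), 1e-300)
            assert np.linalg.norm(B2.Bl[i] - B1.Bl[i]) / scale < 1e-8

    def test_procrustes_beats_random_unitaries(self, rng):
        """The returned rotation is optimal against 200 random unitaries."""
        grid4 = build_fourier_grid(4, 4.0)
        l = 1
        truth = random_harmonics(grid4, rng, l_max=2, real_intensity=True)
        B = compute_Bl(harmonics_from_stack(grid4, truth), [l])
        start = random_harmonics(grid4, rng, l_max=2, real_intensity=True)
        harm = harmonics_from_stack(grid4, start)
        out = correlation_projection(harm, B)
        L = grid4.L_per_shell[0]
        A = np.stack([start[k, l, L - 2 : L + 1] for k in range(4)])
        A_out = np.stack([out.shells[k].coeffs[l, L - 2 : L + 1] for k in range(4)])
        best = np.linalg.norm(A_out - A)
        F = factor_Bl(B, l)
        for _ in range(200):
            U = unitary_group.rvs(3, random_state=rng)
            assert np.linalg.norm(F @ U - A) >= best - 1e-9

    def test_unitary_invariance_of_output_data(self, grid5, rng):
        """Right-rotating the computed harmonics leaves the output B_l fixed."""
        truth = random_harmonics(grid5, rng, l_max=3, real_intensity=True)
        B = compute_Bl(harmonics_from_stack(grid5, truth), [2])
        start = random_harmonics(grid5, rng, l_max=3, real_intensity=True)
        L = grid5.L_per_shell[0]
        rotated = start.copy()
        U = unitary_group.rvs(5, random_state=rng)
        rotated[:, 2, L - 3 : L + 2] = start[:, 2, L - 3 : L + 2] @ U
        out_a = compute_Bl(
            correlation_projection(harmonics_from_stack(grid5, start), B), [2]
        )
        B._factor_cache = None  # force identical refactor for the second call
        out_b = compute_Bl(
            correlation_projection(harmonics_from_stack(grid5, rotated), B), [2]
        )
        np.testing.assert_allclose(out_a.Bl[0], out_b.Bl[0], atol=1e-8)

    def test_grid_mismatch_raises(self, grid5, rng):
        other = build_fourier_grid(5, 7.0)
        stack = random_harmonics(grid5, rng, l_max=2)
        B = compute_Bl(harmonics_from_stack(grid5, stack), [0])
        with pytest.raises(ValueError):
            correlation_projection(harmonics_from_stack(other, stack), B)
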