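"""Alignment, averaging, PRTF and the numerical validation rule."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtip.ensemble import (
    CartesianMap,
    PRTFCurve,
    align_density,
    average_and_interpolate,
    compute_prtf,
    estimate_resolution,
    so3_grid,
    validate_prtf,
)
from mtip.polar_fourier import PolarField
from mtip.synthetic import PhantomSpec, default_three_blob_spec, make_phantom


@pytest.fixture(scope="module")
def truth16(real_grid_16):
    return make_phantom(default_three_blob_spec(1.0), real_grid_16)


def rotated_phantom(grid, Rm, flip=False):
    spec = default_three_blob_spec(1.0)
    sign = -1.0 if flip else 1.0
    return make_phantom(
        PhantomSpec([(sign * (Rm @ c), a, s) for c, a, s in spec.blobs], 1.0), grid
    )


class TestSO3Grid:
    def test_size_and_unit_quaternions(self):
        rots = so3_grid(576)
        q = rots.as_quat()
        assert q.shape == (576, 4)
        np.testing.assert_allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        np.testing.assert_array_equal(so3_grid(64).as_quat(), so3_grid(64).as_quat())


class TestAlignDensity:
    def test_identity_alignment(self, truth16):
        aligned, rec = align_density(truth16, truth16)
        assert rec["correlation"] >= 0.9999
        assert not rec["flip"]
        assert np.linalg.norm(rec["shift"]) < 0.02

    def test_recovers_grid_rotation(self, real_grid_16, truth16):
        """A rotation from the search grid itself is recovered (corr ~ 1)."""
        Rm = so3_grid(576)[123].as_matrix()
        moving = rotated_phantom(real_grid_16, Rm)
        aligned, rec = align_density(moving, truth16)
        assert rec["correlation"] >= 0.99
        corr = np.corrcoef(aligned.values, truth16.values)[0, 1]
        assert corr >= 0.99

    def test_recovers_enantiomer(self, real_grid_16, truth16):
        moving = rotated_phantom(real_grid_16, np.eye(3), flip=True)
        aligned, rec = align_density(moving, truth16)
        assert rec["flip"]
        assert rec["correlation"] >= 0.99

    def test_recovers_off_grid_rotation_with_shift(self, real_grid_16, truth16):
        """Refinement handles a rotation not on the grid plus a translation."""
        Rm = Rotation.from_rotvec([0.21, -0.13, 0.32]).as_matrix()
        spec = default_three_blob_spec(1.0)
        shift = np.array([0.04, -0.03, 0.05])
        moving = make_phantom(
            PhantomSpec([(Rm @ c + shift, a, s) for c, a, s in spec.blobs], 1.0),
            real_grid_16,
        )
        aligned, rec = align_density(moving, truth16)
        assert rec["correlation"] >= 0.98

    def test_zero_variance_rejected(self, real_grid_16, truth16):
        flat = PolarField(real_grid_16, np.ones(real_grid_16.n_nodes))
        with pytest.raises(ValueError):
            align_density(flat, truth16)


class TestAverageAndInterpolate:
    def test_averaging_copies_is_identity(self, truth16):
        one = average_and_interpolate([truth16], dims=24)
        three = average_and_interpolate([truth16, truth16, truth16], dims=24)
        np.testing.assert_allclose(one.values, three.values, atol=1e-12)

    def test_gaussian_radial_profile(self, real_grid_16):
        """Interpolated map reproduces an isotropic Gaussian to 2% inside r_max/2."""
        sigma = 0.25
        r = np.linalg.norm(real_grid_16.nodes_xyz(), axis=1)
        rho = PolarField(real_grid_16, np.exp(-(r**2) / (2 * sigma**2)))
        cmap = average_and_interpolate([rho], dims=32)
        ax = (np.arange(32) - 15.5) * cmap.voxel_size
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        rv = np.sqrt(X**2 + Y**2 + Z**2)
        inner = rv <= 0.5
        expected = np.exp(-(rv[inner] ** 2) / (2 * sigma**2))
        assert np.abs(cmap.values[inner] - expected).max() / expected.max() < 0.02

    def test_mass_conservation(self, truth16):
        """Cartesian map mass matches the polar quadrature mass within 5%."""
        cmap = average_and_interpolate([truth16], dims=48)
        mass_cart = cmap.values.sum() * cmap.voxel_size**3
        mass_polar = (truth16.values * truth16.grid.volume_weights()).sum()
        assert mass_cart == pytest.approx(mass_polar, rel=0.05)

    def test_outside_ball_is_zero(self, truth16):
        cmap = average_and_interpolate([truth16], dims=24)
        ax = (np.arange(24) - 11.5) * cmap.voxel_size
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        outside = np.sqrt(X**2 + Y**2 + Z**2) > 1.0
        assert np.abs(cmap.values[outside]).max() == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_and_interpolate([])


class TestComputePrtf:
    def test_identical_replicas_give_unity(self, fourier_grid_8, rng):
        vals = rng.standard_normal(fourier_grid_8.n_nodes) + 1j * rng.standard_normal(
            fourier_grid_8.n_nodes
        )
        F = PolarField(fourier_grid_8, vals)
        prtf = compute_prtf([F.copy(), F.copy(), F.copy()])
        np.testing.assert_allclose(prtf.values, 1.0, atol=1e-12)

    def test_single_replica_is_unity(self, fourier_grid_8, rng):
        vals = rng.standard_normal(fourier_grid_8.n_nodes) + 1j * rng.standard_normal(
            fourier_grid_8.n_nodes
        )
        prtf = compute_prtf([PolarField(fourier_grid_8, vals)])
        np.testing.assert_allclose(prtf.values, 1.0, atol=1e-12)

    def test_random_phases_decohere(self, fourier_grid_8, rng):
        """64 replicas with i.i.d. phases: every shell falls well below 1."""
        amp = np.ones(fourier_grid_8.n_nodes)
        reps = [
            PolarField(
                fourier_grid_8,
                amp * np.exp(2j * np.pi * rng.uniform(size=fourier_grid_8.n_nodes)),
            )
            for _ in range(64)
        ]
        prtf = compute_prtf(reps)
        assert prtf.values.max() < 0.3

    def test_global_phase_invariance(self, fourier_grid_8, rng):
        vals = rng.standard_normal(fourier_grid_8.n_nodes) + 1j * rng.standard_normal(
            fourier_grid_8.n_nodes
        )
        F = PolarField(fourier_grid_8, vals)
        Fp = PolarField(fourier_grid_8, vals * np.exp(1j * 1.234))
        prtf = compute_prtf([F, Fp])
        np.testing.assert_allclose(prtf.values, 1.0, atol=1e-10)


class TestResolutionEstimate:
    def test_first_crossing(self):
        prtf = PRTFCurve(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0.9, 0.5, 0.3, 0.2]))
        q, crossed = estimate_resolution(prtf)
        assert crossed and q == 3.0

    def test_no_crossing_flags(self):
        prtf = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.9]))
        q, crossed = estimate_resolution(prtf)
        assert not crossed and q == 2.0

    def test_first_shell_crossing(self):
        prtf = PRTFCurve(np.array([1.0, 2.0]), np.array([0.1, 0.9]))
        q, crossed = estimate_resolution(prtf)
        assert crossed and q == 1.0


class TestValidatePrtf:
    def test_identical_curves_pass(self):
        c = PRTFCurve(np.arange(1.0, 5.0), np.array([0.9, 0.8, 0.5, 0.3]))
        report = validate_prtf(c, c)
        assert report["pass"]
        assert all(row["rel_delta"] == 0 for row in report["shells"])

    def test_twelve_percent_deviation_fails(self):
        ref = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.5]))
        cand = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.56]))
        report = validate_prtf(cand, ref)
        assert not report["pass"]
        bad = [r for r in report["shells"] if not r["ok"]]
        assert len(bad) == 1 and bad[0]["q"] == 2.0

    def test_low_reference_shells_ignored(self):
        """Deviation at a shell with reference <= 0.25 does not fail the check."""
        ref = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.20]))
        cand = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.10]))
        assert validate_prtf(cand, ref)["pass"]

    def test_shell_mismatch_rejected(self):
        a = PRTFCurve(np.array([1.0, 2.0]), np.array([0.9, 0.8]))
        b = PRTFCurve(np.array([1.0, 3.0]), np.array([0.9, 0.8]))
        with pytest.raises(ValueError):
            validate_prtf(a, b)
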