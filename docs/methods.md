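# Methods

## Model and discretization

The package reconstructs a real, nonnegative electron density ρ(r) from
fluctuation-scattering cross-correlation matrices
`B_l(q,q') = Σ_m I_lm(q) I*_lm(q')`, where `I_lm` are spherical-harmonic
coefficients of the 3D diffraction intensity.  The data are invariant under
global rotation, point inversion and translation of the object; those three
ambiguities are resolved only at the analysis stage (alignment), never
during iteration.

Fields are sampled on spherical-polar grids of N shells at equispaced radii
starting one step from the origin (`r_n = n·r_max/N`); the origin is
excluded to avoid a degenerate shell.  Per shell, inclinations sit at the
arccosines of Gauss–Legendre nodes and azimuths are equispaced.  Real-space
shells carry a band limit growing with radius, `L_n = ⌈πn⌉ + 1`,
`M_n = 2L_n − 1`, which keeps the angular sampling density roughly uniform
in space; Fourier shells share one generous band limit `L = ⌈π(N−1)⌉ + 15`,
`M = 2L − 1`, so nothing of the real-space representation is lost in
Fourier space.  The ceiling in these formulas is this package's reading of
the (irrational) printed expressions; it errs on the side of a higher band
limit.  All arithmetic is double precision — the iteration is long enough
that single-precision roundoff visibly destabilizes it.

### Spherical harmonic transform

Analysis on one shell is an FFT over azimuth (with the 2π/M quadrature
weight) followed by a weighted associated-Legendre contraction over
inclination; synthesis is the mirror image.  Harmonics are orthonormal
complex `Y_l^m` with the Condon–Shortley phase.  The normalized Legendre
functions come from the standard fully-normalized three-term recurrence in
l at fixed m, stable to band limits of several hundred.  Because the
Gauss–Legendre rule of order `L_n` integrates polynomial degree `2L_n − 1`
exactly, analysis is exact for fields band-limited below `L_n`, and
analysis∘synthesis is the identity on coefficients (verified to 1e−10 at
L = 63).  Legendre tables and the batched matrix operands are built once
per grid and cached; shells that share a band limit (all Fourier shells)
are transformed in a single batched matrix product.

### Polar Fourier transform

With the convention `F(q) = ∫ ρ(r) e^{+iq·r} d³r`, the radial link at order
l is the spherical Hankel transform

    F_lm(q_k) = 4π i^l  Σ_n j_l(q_k r_n) ρ_lm(r_n) r_n² Δr
    ρ_lm(r_n) = (−i)^l/(2π²) Σ_k j_l(q_k r_n) F_lm(q_k) q_k² Δq

implemented as one cached N×N matrix per (l, direction).  The radial rule
is a plain uniform sum with weight r²Δr: for integrands that decay inside
the domain (the only ones the transforms meet in practice) the rule is
spectrally accurate, because it coincides with the trapezoid rule when the
boundary terms vanish; for non-decaying integrands it carries an O(1/N)
boundary bias (measured as 3/(2N) on the constant function — see the grid
tests).  Real-space coefficients with `l ≥ L_n` are treated as zero going
forward; coefficients above a shell's band are truncated coming back.  The
default pairing of the grids is `q_max = πN/(2 r_max)`, a Nyquist-like
choice the user can override.

Measured accuracy: the transform of an isotropic Gaussian matches the
closed form to ~1e−15 at N=32 over the lower half band (converging
monotonically from ~6e−2 at N=8 for a σ = 0.07·r_max object), agrees with
a brute-force 3D quadrature of the Fourier sum to better than 1e−6 in
relative L2 at N=8, and the forward/inverse round trip on the three-blob
phantom is ~3e−3 relative at N=16.

## Correlation projection

Per order l, the external `B_l` is factored as `F_l F_l†` with `F_l` of
size N×(2l+1): eigendecompose, clip eigenvalues below
`max(0, 1e−12·λ_max)`, keep the 2l+1 largest.  The computed coefficient
matrix `A_l` (columns m = −l..l) is then replaced by `F_l R_l`, where `R_l`
is the Procrustes minimizer of `‖A_l − F_l R‖_F` (`R = UV†` from the SVD of
`F_l† A_l`), so the output reproduces the external data exactly while
moving least from the current iterate.  Orders absent from the data (odd l
for a real density, by Friedel symmetry) are zeroed.

One refinement matters in practice: for a real intensity the B_l are real
symmetric matrices, and the coefficient columns can be expressed in the
real spherical-harmonic basis, where consistency with a real intensity
means the coefficients themselves are real.  The projector detects
real-symmetric data (against a global, not per-matrix, scale — high orders
are numerically tiny and pure roundoff) and then performs the match with a
real orthogonal Procrustes in the real basis, which preserves the
conjugate symmetry `I_{l,−m} = (−1)^m I*_{lm}` exactly at every iteration.
Genuinely complex Hermitian data fall back to the complex unitary match.
Factors are computed once per dataset and cached.  The fit is unweighted
Frobenius across shells; no q-dependent weighting is applied.

## Iteration

One MTIP iteration is forward → correlation projection → inverse
(magnitude projection keeps the computed phases; where `|F| = 0` the phase
is taken as 1; negative modified intensities clip to 0) → real-space
update.  ER is the plain projection onto support/nonnegativity/bounds; HIO
keeps the candidate where it is feasible (inside the support *and* within
bounds — the generalized-constraint reading) and applies
`ρ_prev − β·ρ_cand` elsewhere, with β = 0.9 by default (standard HIO
practice; no printed value exists for this parameter).

A replica starts from uniform [0,1) noise inside a ball of radius
0.8·r_max and runs `outer` cycles of (HIO block, ER block, shrinkwrap),
then an ER-only refinement on the frozen support.  Defaults are
15/60/40/200 (outer/HIO/ER/refine); the tests and the acceptance script
use a reduced 5/20/20/50 schedule at N=16, which already recovers the
phantom and keeps the whole experiment in minutes on one CPU.  The logged
convergence metric is `r = Σ_l‖B_l^c − B_l^e‖_F / Σ_l‖B_l^e‖_F`.  This
residual is not strictly monotone under ER — the magnitude constraint set
is non-convex and the metric is measured before the real-space projection —
but on a converged replica the refinement holds it in a narrow band.

Shrinkwrap smooths the density by multiplying its structure factors by
`exp(−q²σ²/2)` (a real-space Gaussian convolution is ill-defined on the
non-uniform polar grid) and keeps nodes above a fraction of the smoothed
maximum.  σ starts at 3Δr, shrinks by 0.99 per call with a floor of 1.5Δr.
The threshold default is **0.02**, deliberately softer than the 0.1–0.2
customary for compact objects with sharp edges: the phantoms (and most
solution-scattering particles) are smooth, and their low-density tails are
still constrained by the correlation data — masking them off was measured
to pin the data residual roughly tenfold above its attainable level and to
visibly degrade recovery.  All of these are config-overridable.

## Ensemble analysis

**Alignment.**  The data fix the object only up to rotation, inversion and
translation, so replicas are aligned to a reference by maximizing the
real-space Pearson correlation over a deterministic 576-element
super-Fibonacci SO(3) grid crossed with the inversion flip, followed by
Nelder–Mead refinement over rotation *and* translation (translation must be
refined because nothing in the data pins it; shrinkwrap only roughly
centers the support).  Densities are evaluated at arbitrary points by
synthesizing each shell's band-limited representation on a common uniform
angular grid (exact for band-limited fields) and interpolating trilinearly
in (r, θ, φ); the radial axis is padded to the origin and φ wraps.
Recovering a known rotation+shift of the phantom yields correlation 1.000.

**Averaging.**  Aligned densities are averaged pointwise on the polar grid
and interpolated to a cubic Cartesian voxel map (zero outside r_max),
written as float32 MRC/CCP4.  Mass agrees with the polar quadrature within
5 % and an isotropic Gaussian's radial profile is reproduced to 2 % inside
r_max/2.

**PRTF.**  Per Fourier shell,
`PRTF(q_k) = Σ_nodes |Σ_i F_i| / Σ_nodes Σ_i |F_i|` over aligned replicas,
each replica first multiplied by the global phase best matching the
reference replica.  Identical replicas give exactly 1; fully decohered
phases give ~1/√(n·nodes).  The resolution estimate is the first shell
below 1/e (flagged if never crossed).  The validation rule compares two
curves shell-by-shell: shells with reference value above 0.25 must agree
within ±5 % **relative**; lower shells are ignored.  This rule is meant
for two runs of the *same* computation (its original use compares two
implementations of one algorithm): measured here, two independent
10-replica ensembles disagree by up to ~27 % in the mid-band, so the
acceptance script exercises the rule on an invariance of the estimator
(recomputing the PRTF with a different phase-reference replica) and
reports the half-ensemble dispersion as a separate number.

## Synthetic data

Phantoms are mixtures of isotropic 3D Gaussians — strictly positive,
effectively band-limited, with a closed-form transform per blob
(translation phase × Gaussian) that serves as an analytic oracle for the
transform stack.  The canonical test object has three blobs of widths
0.20/0.17/0.15·r_max (≥ 2.4 radial steps on the N=16 grid, i.e. resolved)
and amplitudes 1.0/0.8/0.9, centers within 0.3·r_max of the origin;
`PhantomSpec.random` draws seeded variants.  External-style data are the
forward model applied to the phantom (even orders by default); noise, when
requested, is additive Hermitian Gaussian on each B_l scaled to
`rel_level·‖B_l‖_F/N` — correlation-level noise, not detector shot noise,
because the package's inputs are correlations.

What the generator does *not* emulate: estimation of B_l from finite sets
of noisy 2D snapshots (detector geometry, Ewald curvature, multi-particle
exposures), non-smooth electron densities, and solvent contrast.  Passing
tests therefore demonstrate the correctness and self-consistency of the
reconstruction machinery, not robustness to experimental correlation
estimation errors beyond the simple noise model above.

## Numerical choices and limitations

- Double precision throughout; transforms cached per grid; determinism is
  bit-exact for a fixed seed and config (asserted in the tests).
- Eigenvalue clipping at `1e−12·λ_max` absorbs roundoff-negative modes of
  noiseless data and mildly regularizes noisy data.
- The magnitude projection's zero-phase convention (phase 1 where F = 0)
  only matters in the first iterations from random starts.
- Degenerate situations raise typed errors: empty support, all-zero density
  into shrinkwrap, NaN/Inf in any stage (named), non-Hermitian data.
- Recovery at desk scale (N=16, reduced schedule, 10 seeds) yields aligned
  Pearson correlations of ~0.89–0.96 against ground truth with 9–10 of 10
  above 0.9, ensemble PRTF above 1/e over the lowest third of shells, and a
  1/e crossing near q ≈ 20 (grid units) — numbers recomputed by
  `scripts/acceptance.py`.
- Point-group symmetry projectors, solvent flattening, GPU/MPI execution
  and experimental-data handling are out of scope.
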