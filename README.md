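# mtip — multitiered iterative phasing for fluctuation X-ray scattering

`mtip` reconstructs a 3D electron density from fluctuation X-ray scattering
(FXS) angular cross-correlation data.  In an FXS experiment, X-ray exposures
shorter than rotational diffusion preserve angular intensity fluctuations of
particles in solution; averaging angular correlations over many snapshots
yields, per spherical-harmonic order *l*, the matrices

```
B_l(q, q') = Σ_{m=-l}^{l} I_lm(q) I*_lm(q')
```

where `I_lm(q)` are the spherical-harmonic coefficients of the 3D intensity
`I(q) = |F(q)|²` and `F` is the Fourier transform of the electron density ρ.
The B_l retain far more structural information than a SAXS curve, but both
the intensity phases and the per-order unitary mixing of the `I_lm` are lost.
MTIP (multitiered iterative phasing) recovers ρ by alternating projections:

1. **Forward**: ρ → F (polar Fourier transform) → I = |F|² → I_lm (spherical
   harmonic transform per Fourier shell).
2. **Correlation projection**: replace the computed `I_lm` with the nearest
   set exactly reproducing the external B_l — factor each Hermitian PSD
   `B_l = F_l F_l†` (rank ≤ 2l+1, clipped eigendecomposition) and rotate the
   factor onto the computed coefficients with the orthogonal-Procrustes
   unitary.
3. **Inverse**: synthesize the modified intensity, impose it on `F` by
   magnitude projection (`F' = √I_mod · F/|F|`, phases kept), inverse polar
   Fourier transform.
4. **Real space**: support, nonnegativity and optional bounds, applied as an
   error-reduction (ER) step or a hybrid input–output (HIO) step with
   negative feedback β; the support is re-estimated periodically by
   shrinkwrap (threshold a Gaussian-smoothed density).

All fields live on spherical-polar grids: N equispaced radial shells, per
shell the inclinations are arccosines of Gauss–Legendre nodes and azimuths
are equispaced.  Real-space shells use a growing band limit
`L_n = ⌈πn⌉ + 1`, `M_n = 2L_n − 1`; Fourier shells share
`L = ⌈π(N−1)⌉ + 15`, `M = 2L − 1`.  Spherical harmonic transforms are FFTs
over azimuth plus associated-Legendre matrix products; the radial link
between real and Fourier space is the order-l spherical Hankel transform
(spherical Bessel kernels).  Independent replicas from random starts are
aligned (rotation grid + enantiomer flip + local refinement), averaged and
interpolated to a Cartesian voxel map; reconstruction quality is summarized
by the phase retrieval transfer function (PRTF) with the resolution read at
its 1/e crossing, and two runs are compared with a ±5 % rule on shells where
the PRTF exceeds 0.25.

Everything runs on synthetic Gaussian-blob phantoms through the same forward
model, so the whole pipeline is testable on a desk with no external data.

## Worked example

```
mtip simulate --n-shells 16 --out corr.h5 --truth-mrc truth.mrc
mtip reconstruct corr.h5 --outdir run --replicas 4 --base-seed 1
mtip prtf run
mtip validate run/prtf.csv run/prtf.csv
```

`simulate` evaluates the built-in three-blob phantom on the N=16 grid and
writes its even-order correlation matrices (32 orders, 16×16 each) to HDF5.
`reconstruct` runs four seeded replicas of the iterative stage (default
schedule 15 outer cycles × (60 HIO + 40 ER) + 200 refinement iterations),
writes one MRC map per replica plus the aligned average, and a JSON run log;
a typical run log reports final correlation residuals around
`0.005 – 0.02`, i.e. the computed B_l match the data to 0.5–2 % after the
reduced-noise refinement.  `prtf` aligns the replicas and writes the PRTF
curve; on this example the curve stays above 0.9 over the lowest third of
shells and crosses 1/e near `q ≈ 20–22` (inverse length units of the grid),
which the log prints as the resolution estimate.  `validate` compares two
PRTF CSVs and exits 1 if any shell above 0.25 deviates by more than 5 %.

The same machinery is available as a library:

```python
from mtip import (RunConfig, default_three_blob_spec, make_phantom,
                  simulate_external_Bl, run_ensemble)
from mtip.pipeline import build_grids

config = RunConfig(n_shells=16)
real_grid, fourier_grid = build_grids(config)
truth = make_phantom(default_three_blob_spec(1.0), real_grid)
data = simulate_external_Bl(truth, fourier_grid)
results = run_ensemble(data, config)
print(results[0].residual_log[-1])   # e.g. 0.0166
```

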