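"""One MTIP replica: the four-stage iteration under an HIO/ER/shrinkwrap schedule.

A single iteration is

    Stage 1 (forward):   rho -> F -> I = |F|^2 -> I_lm          (computed data)
    Stage 2 (matching):  I_lm -> I_lm^mod via correlation projection onto B_l^ext
    Stage 3 (inverse):   I_lm^mod -> I^mod -> F' (magnitude projection,
                         keeping the phases of F) -> rho' (inverse polar FT)
    Stage 4 (real space): HIO or ER update against the support mask and bounds.

A replica starts from a seeded uniform-random density inside a ball, runs
``outer_iter`` cycles of an HIO block then an ER block with periodic
shrinkwrap support re-estimation, and finishes with an ER-only refinement on
the frozen support.  The convergence metric logged each iteration is the
relative correlation mismatch  r = sum_l ||B_l^c - B_l^e||_F / sum_l ||B_l^e||_F.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .correlations import CorrelationData, compute_Bl, correlation_projection
from .grid import PolarGrid, build_fourier_grid, build_real_grid
from .polar_fourier import (
    HarmonicCoefficients,
    PolarField,
    field_to_harmonics,
    harmonics_to_field,
    intensity_from_structure_factors,
    inverse_polar_fourier_transform,
    polar_fourier_transform,
)
from .real_space import (
    DegenerateSupportError,
    ProjectorSettings,
    SupportMask,
    er_update,
    hio_update,
    magnitude_projection,
    shrinkwrap_update,
)

__all__ = [
    "ReconstructionResult",
    "NumericalInstabilityError",
    "build_grids",
    "initial_support",
    "random_initial_density",
    "mtip_iteration",
    "run_replica",
    "run_ensemble",
]


class NumericalInstabilityError(RuntimeError):
    """NaN/Inf appeared in an iteration stage."""

    def __init__(self, stage: str):
        super().__init__(f"non-finite values produced in stage: {stage}")
        self.stage = stage


@dataclass
class ReconstructionResult:
    """Output of one replica."""

    final_density: PolarField
    final_F: PolarField
    support: SupportMask
    seed: int
    residual_log: list[float]
    config_snapshot: dict
    error: str | None = None


def build_grids(config: RunConfig) -> tuple[PolarGrid, PolarGrid]:
    real_grid = build_real_grid(config.n_shells, config.r_max)
    fourier_grid = build_fourier_grid(config.n_shells, config.resolved_q_max())
    return real_grid, fourier_grid


def initial_support(real_grid: PolarGrid, frac: float = 0.8) -> SupportMask:
    """Generous starting support: the ball r <= frac * r_max."""
    r = real_grid.shell_radii_of_nodes()
    return SupportMask(real_grid, r <= frac * real_grid.radii[-1] + 1e-12)


def random_initial_density(
    real_grid: PolarGrid, mask: SupportMask, seed: int
) -> PolarField:
    """Uniform [0, 1) density inside the support, zero outside."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.0, 1.0, size=real_grid.n_nodes)
    return PolarField(real_grid, np.where(mask.inside, vals, 0.0))


def _check_finite(values: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(values)):
        raise NumericalInstabilityError(stage)


def _forward_stage(
    rho: PolarField, fourier_grid: PolarGrid
) -> tuple[PolarField, HarmonicCoefficients]:
    F = polar_fourier_transform(rho, fourier_grid)
    _check_finite(F.values, "forward polar Fourier transform")
    I = intensity_from_structure_factors(F)
    I_harm = field_to_harmonics(I)
    return F, I_harm


def _residual(I_harm: HarmonicCoefficients, Bl_ext: CorrelationData) -> float:
    Bc = compute_Bl(I_harm, Bl_ext.l_values)
    num = sum(
        float(np.linalg.norm(Bc.Bl[i] - Bl_ext.Bl[i])) for i in range(Bl_ext.Bl.shape[0])
    )
    den = sum(float(np.linalg.norm(Bl_ext.Bl[i])) for i in range(Bl_ext.Bl.shape[0]))
    return num / den if den > 0 else 0.0


def mtip_iteration(
    rho: PolarField,
    Bl_ext: CorrelationData,
    mask: SupportMask,
    settings: ProjectorSettings,
    mode: str,
    real_grid: PolarGrid | None = None,
    fourier_grid: PolarGrid | None = None,
    residual_out: list[float] | None = None,
) -> PolarField:
    """One full MTIP iteration; ``mode`` selects the Stage-4 update rule."""
    if mode not in ("HIO", "ER"):
        raise ValueError(f"mode must be 'HIO' or 'ER', got {mode!r}")
    real_grid = real_grid if real_grid is not None else rho.grid
    if fourier_grid is None:
        raise ValueError("a Fourier grid is required")
    # Stage 1: forward direction
    F, I_harm = _forward_stage(rho, fourier_grid)
    if residual_out is not None:
        residual_out.append(_residual(I_harm, Bl_ext))
    # Stage 2: correlation projection
    I_mod_harm = correlation_projection(I_harm, Bl_ext)
    _check_finite(
        np.concatenate([s.coeffs.ravel() for s in I_mod_harm.shells]),
        "correlation projection",
    )
    # Stage 3: inverse direction
    I_mod = harmonics_to_field(I_mod_harm, real_output=True)
    F_mod = magnitude_projection(F, I_mod)
    rho_proj = inverse_polar_fourier_transform(F_mod, real_grid)
    _check_finite(rho_proj.values, "inverse polar Fourier transform")
    # Stage 4: real-space update
    if mode == "HIO":
        return hio_update(rho, rho_proj, mask, settings)
    return er_update(rho_proj, mask, settings)


def run_replica(Bl_ext: CorrelationData, config: RunConfig, seed: int) -> ReconstructionResult:
    """Run the full iterative stage for one random start."""
    Bl_ext.validate()
    real_grid, fourier_grid = build_grids(config)
    if Bl_ext.q.shape != fourier_grid.radii.shape or not np.allclose(
        Bl_ext.q, fourier_grid.radii, rtol=1e-10, atol=0
    ):
        raise ValueError("correlation data q grid does not match the configured grid")
    sched = config.schedule
    sw = config.shrinkwrap
    settings = config.projector
    mask = initial_support(real_grid, config.initial_support_frac)
    rho = random_initial_density(real_grid, mask, seed)
    residuals: list[float] = []
    dr = real_grid.radial_step
    sigma = sw.sigma_factor * dr
    for outer in range(sched.outer_iter):
        for _ in range(sched.hio_iterations):
            rho = mtip_iteration(
                rho, Bl_ext, mask, settings, "HIO",
                real_grid, fourier_grid, residual_out=residuals,
            )
        for _ in range(sched.er_iterations):
            rho = mtip_iteration(
                rho, Bl_ext, mask, settings, "ER",
                real_grid, fourier_grid, residual_out=residuals,
            )
        if (outer + 1) % sched.shrinkwrap_every == 0:
            mask = shrinkwrap_update(rho, sigma, sw.threshold_frac, fourier_grid)
            sigma = max(sigma * sw.decay, sw.floor_factor * dr)
    for _ in range(sched.refine_iterations):
        rho = mtip_iteration(
            rho, Bl_ext, mask, settings, "ER",
            real_grid, fourier_grid, residual_out=residuals,
        )
    final_F = polar_fourier_transform(rho, fourier_grid)
    return ReconstructionResult(
        final_density=rho,
        final_F=final_F,
        support=mask,
        seed=seed,
        residual_log=residuals,
        config_snapshot=config.to_dict(),
    )


def run_ensemble(
    Bl_ext: CorrelationData,
    config: RunConfig,
    n_replicas: int | None = None,
    seeds: list[int] | None = None,
) -> list[ReconstructionResult]:
    """Independent replicas from different seeds (sequential loop).

    A failed replica is recorded with its error message instead of aborting
    the ensemble; if every replica fails, the first error is re-raised.
    """
    if seeds is None:
        seeds = config.replica_seeds()
    if n_replicas is not None:
        if len(seeds) < n_replicas:
            raise ValueError("fewer seeds than replicas")
        seeds = seeds[:n_replicas]
    if not seeds:
        raise ValueError("need at least one replica")
    results: list[ReconstructionResult] = []
    first_exc: Exception | None = None
    for s in seeds:
        try:
            results.append(run_replica(Bl_ext, config, int(s)))
        except (DegenerateSupportError, NumericalInstabilityError, ValueError) as exc:
            first_exc = first_exc or exc
            real_grid, fourier_grid = build_grids(config)
            results.append(
                ReconstructionResult(
                    final_density=PolarField.zeros(real_grid),
                    final_F=PolarField.zeros(fourier_grid, dtype=complex),
                    support=initial_support(real_grid, config.initial_support_frac),
                    seed=int(s),
                    residual_log=[],
                    config_snapshot=config.to_dict(),
                    error=str(exc),
                )
            )
    if all(r.error is not None for r in results):
        raise RuntimeError("all replicas failed") from first_exc
    return results
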