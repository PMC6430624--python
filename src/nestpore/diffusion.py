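"""Steady CO₂ diffusion through the pore space of a voxel image.

The steady limit of Fick's second law, ``∇·(D∇c) = 0``, is solved on the
pore phase with the bulk CO₂-in-air coefficient ``D_c ≈ 1.6×10⁻⁵ m²/s``;
the solid phase has zero diffusivity and the fluid–solid interface carries
no reaction, so solid faces are no-flux.  A fixed relative concentration of
1 at the inlet and 0 at the outlet drives the transport; the apparent
diffusivity is the flux-based effective coefficient referenced to the total
(pore + solid) cross-section, mirroring the permeability convention:

    D_app = Q · Δx / (A_total · (c_in − c_out))

so that tortuous, partially connected pore networks yield
``D_app ≤ φ·D_c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fv import ConductionSolution, solve_conduction
from .image import ScalarField, VectorField, VoxelImage, axis_index

__all__ = ["D_CO2_AIR", "DiffusionResult", "solve_diffusion", "co2_flux_scaled"]

#: bulk diffusion coefficient of CO₂ in air, m²/s
D_CO2_AIR = 1.6e-5

#: atmospheric CO₂ concentration (mol/m³) and the physiological relative
#: excess used to scale fluxes: a 5% concentration change per cm of wall
CO2_ATMOSPHERIC = 0.0164
CO2_RELATIVE_CHANGE = 0.05


@dataclass
class DiffusionResult:
    """Concentration field, flux field and apparent diffusivity."""

    concentration: ScalarField
    flux: VectorField  # mol/m²/s when c is mol/m³
    D_app: float  # m²/s
    D_bulk: float
    total_flux: float  # mol/s
    plane_flux: np.ndarray
    spanning: bool
    residual: float
    iterations: int
    axis: int
    c_in: float
    c_out: float
    length_m: float
    area_m2: float


def solve_diffusion(
    img: VoxelImage,
    axis: int | str = 0,
    c_in: float = 1.0,
    c_out: float = 0.0,
    D_bulk: float = D_CO2_AIR,
    tol: float = 1e-8,
    max_iter: int = 50_000,
) -> DiffusionResult:
    """Steady pore-space diffusion under a fixed concentration difference.

    When the pore space does not span the axis the result carries
    ``D_app = 0`` and ``spanning=False`` (a signal, not an exception).
    """
    ax = axis_index(axis)
    if D_bulk <= 0:
        raise ValueError("D_bulk must be positive")
    h = img.voxel_size * 1e-6  # m
    sigma = np.where(img.pore_mask(), D_bulk, 0.0)
    sol: ConductionSolution = solve_conduction(
        sigma, ax, c_in, c_out, h, rtol=tol, max_iter=max_iter
    )
    shape = img.shape
    area = np.prod([shape[k] for k in range(3) if k != ax]) * h**2
    return DiffusionResult(
        concentration=ScalarField(sol.field, unit="mol/m^3", support=sol.support),
        flux=VectorField(sol.flux_cell, unit="mol/m^2/s", support=sol.support),
        D_app=sol.sigma_eff,
        D_bulk=D_bulk,
        total_flux=sol.total_flux,
        plane_flux=sol.plane_flux,
        spanning=sol.spanning,
        residual=sol.residual,
        iterations=sol.iterations,
        axis=ax,
        c_in=c_in,
        c_out=c_out,
        length_m=shape[ax] * h,
        area_m2=float(area),
    )


def co2_flux_scaled(
    result: DiffusionResult,
    wall_thickness_cm: float | None = None,
) -> tuple[VectorField, float]:
    """Rescale a normalised solve to the physiological CO₂ condition.

    The target condition is a 5% change in CO₂ concentration (relative to
    the ≈0.0164 mol/m³ atmospheric level) across each centimetre of wall.
    Diffusion is linear in the concentration difference, so the solved flux
    field is simply multiplied by ``Δc_target / Δc_solver`` where
    ``Δc_target = 0.05 × 0.0164 × thickness_cm`` mol/m³.  The domain length
    is used when ``wall_thickness_cm`` is not given.

    Returns ``(scaled flux field, scaled total molar flux in mol/s)``.
    """
    if wall_thickness_cm is None:
        wall_thickness_cm = result.length_m * 100.0
    dc_solver = result.c_in - result.c_out
    if dc_solver == 0:
        raise ValueError("solver concentration difference is zero; nothing to scale")
    dc_target = CO2_RELATIVE_CHANGE * CO2_ATMOSPHERIC * wall_thickness_cm
    factor = dc_target / dc_solver
    scaled = VectorField(
        values=result.flux.values * factor,
        unit="mol/m^2/s",
        support=result.flux.support,
    )
    return scaled, result.total_flux * factor
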