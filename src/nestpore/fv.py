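"""Cell-centred finite-volume solver for steady conduction on voxel grids.

Solves ``∇·(σ∇u) = 0`` for a per-voxel coefficient field ``σ ≥ 0`` with
Dirichlet values on the two boundary faces of one axis and no-flux
conditions everywhere else (lateral boundaries and every face adjacent to a
``σ = 0`` voxel).  Face transmissibilities are harmonic means of the
adjacent cell coefficients, which is exact for one-dimensional series
composites and keeps the scheme conservative.  The same kernel serves the
CO₂-diffusion stage (σ = D in pores, 0 in solid) and the heat-conduction
stage (σ = phase conductivity, 0 in air).

Units: ``h`` is the voxel edge in metres; fluxes returned by the solver are
``σ · m · Δu`` (e.g. mol/s for diffusion when σ is m²/s and u is mol/m³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

__all__ = ["ConductionSolution", "solve_conduction", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ConductionSolution:
    """Steady conduction solution on a voxel grid.

    ``field`` holds the potential (NaN outside the conducting phase),
    ``flux_cell`` the cell-centred flux density ``−σ∇u`` (per-area units),
    ``plane_flux`` the integrated flux through each of the ``N+1``
    transverse planes along the solve axis (constant within solver
    tolerance when the medium spans), and ``sigma_eff`` the apparent
    coefficient referenced to the *total* cross-section.
    """

    field: np.ndarray
    support: np.ndarray
    flux_cell: np.ndarray
    plane_flux: np.ndarray
    total_flux: float
    sigma_eff: float
    spanning: bool
    residual: float
    iterations: int
    axis: int
    h: float


def solve_conduction(
    sigma: np.ndarray,
    axis: int,
    u_in: float,
    u_out: float,
    h: float,
    rtol: float = 1e-8,
    max_iter: int = 50_000,
    direct_threshold: int = 20_000,
) -> ConductionSolution:
    """Solve steady conduction; see module docstring for conventions.

    Conjugate gradients with Jacobi preconditioning on the SPD system;
    small systems (≤ ``direct_threshold`` unknowns) go through a sparse
    direct solve.  Conducting clusters that touch neither Dirichlet face
    are assigned the mid-potential (they are at an indeterminate
    equilibrium and carry no flux).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 3:
        raise ValueError("sigma must be a 3-D per-voxel coefficient field")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    shape = sigma.shape
    cond = sigma > 0
    mid = 0.5 * (u_in + u_out)

    struct = ndi.generate_binary_structure(3, 1)  # face connectivity
    lab, _ = ndi.label(cond, structure=struct)
    inlet_labs = np.unique(np.take(lab, 0, axis=axis))
    outlet_labs = np.unique(np.take(lab, -1, axis=axis))
    inlet_labs = set(inlet_labs[inlet_labs > 0].tolist())
    outlet_labs = set(outlet_labs[outlet_labs > 0].tolist())
    span_labs = inlet_labs & outlet_labs
    spanning = len(span_labs) > 0
    active_labs = np.array(sorted(inlet_labs | outlet_labs), dtype=lab.dtype)

    field = np.full(shape, np.nan)
    field[cond] = mid
    flux_cell = np.zeros(shape + (3,))
    n_ax = shape[axis]
    plane_flux = np.zeros(n_ax + 1)

    if not spanning and not active_labs.size:
        return ConductionSolution(field, cond, flux_cell, plane_flux,
                                  0.0, 0.0, False, 0.0, 0, axis, h)

    active = np.isin(lab, active_labs)
    n_active = int(active.sum())
    idx = np.full(shape, -1, dtype=np.int64)
    idx[active] = np.arange(n_active)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_active)
    rhs = np.zeros(n_active)

    def _pair_slices(d):
        sl_a = tuple(slice(0, -1) if k == d else slice(None) for k in range(3))
        sl_b = tuple(slice(1, None) if k == d else slice(None) for k in range(3))
        return sl_a, sl_b

    for d in range(3):
        sl_a, sl_b = _pair_slices(d)
        ia, ib = idx[sl_a].ravel(), idx[sl_b].ravel()
        sa, sb = sigma[sl_a].ravel(), sigma[sl_b].ravel()
        ok = (ia >= 0) & (ib >= 0) & (sa > 0) & (sb > 0)
        T = np.zeros_like(sa)
        T[ok] = 2.0 * sa[ok] * sb[ok] / (sa[ok] + sb[ok]) * h
        ia, ib, T = ia[ok], ib[ok], T[ok]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-T, -T]
        np.add.at(diag, ia, T)
        np.add.at(diag, ib, T)

    # Dirichlet boundary faces along the solve axis (half-cell spacing)
    for end, u_bc in ((0, u_in), (-1, u_out)):
        sl = np.take(idx, end, axis=axis).ravel()
        s = np.take(sigma, end, axis=axis).ravel()
        ok = (sl >= 0) & (s > 0)
        Tb = 2.0 * s[ok] * h
        np.add.at(diag, sl[ok], Tb)
        np.add.at(rhs, sl[ok], Tb * u_bc)

    rows.append(np.arange(n_active))
    cols.append(np.arange(n_active))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_active, n_active),
    ).tocsr()

    iterations = 0
    if n_active <= direct_threshold:
        u = spsolve(A.tocsc(), rhs)
    else:
        M = sparse.diags(1.0 / diag)
        counter = _IterCounter()
        u, info = cg(A, rhs, rtol=rtol, atol=0.0, maxiter=max_iter,
                     M=M, callback=counter)
        iterations = counter.n
        if info > 0:
            raise ConvergenceError(
                f"conduction solve did not reach rtol={rtol} in {max_iter} "
                "iterations"
            )
    res_vec = A @ u - rhs
    denom = np.linalg.norm(rhs) or 1.0
    residual = float(np.linalg.norm(res_vec) / denom)

    field[active] = u

    # face fluxes -> cell-centred flux density and per-plane totals
    fld = np.nan_to_num(field, nan=mid)
    for d in range(3):
        sl_a, sl_b = _pair_slices(d)
        sa, sb = sigma[sl_a], sigma[sl_b]
        both = (idx[sl_a] >= 0) & (idx[sl_b] >= 0) & (sa > 0) & (sb > 0)
        T = np.where(both, 2.0 * sa * sb / np.where(sa + sb > 0, sa + sb, 1.0) * h, 0.0)
        F = np.where(both, T * (fld[sl_a] - fld[sl_b]), 0.0)  # a -> b
        dens = F / h**2
        pad = [(0, 0)] * 3
        pad[d] = (1, 0)
        left = np.pad(dens, pad)  # face on the low side of each cell
        pad[d] = (0, 1)
        right = np.pad(dens, pad)
        flux_cell[..., d] = 0.5 * (left + right)
        if d == axis:
            ax_other = tuple(k for k in range(3) if k != axis)
            plane_flux[1:-1] = F.sum(axis=ax_other)

    # boundary plane fluxes (half-cell Dirichlet faces)
    s0 = np.take(sigma, 0, axis=axis)
    f0 = np.take(field, 0, axis=axis)
    a0 = np.take(active, 0, axis=axis)
    Fin = np.where(a0 & (s0 > 0), 2.0 * s0 * h * (u_in - np.nan_to_num(f0)), 0.0)
    plane_flux[0] = Fin.sum()
    sN = np.take(sigma, -1, axis=axis)
    fN = np.take(field, -1, axis=axis)
    aN = np.take(active, -1, axis=axis)
    Fout = np.where(aN & (sN > 0), 2.0 * sN * h * (np.nan_to_num(fN) - u_out), 0.0)
    plane_flux[-1] = Fout.sum()

    # boundary contribution to cell-centred flux density on the end slices
    _add_boundary_flux(flux_cell, Fin / h**2, axis, 0)
    _add_boundary_flux(flux_cell, Fout / h**2, axis, -1)

    total_flux = float(plane_flux[0]) if spanning else 0.0
    area = np.prod([shape[k] for k in range(3) if k != axis]) * h**2
    length = n_ax * h
    du = u_in - u_out
    sigma_eff = float(total_flux * length / (area * du)) if du != 0 and spanning else 0.0

    return ConductionSolution(field, cond, flux_cell, plane_flux, total_flux,
                              sigma_eff, spanning, residual, iterations, axis, h)


def _add_boundary_flux(flux_cell, dens_slice, axis, end):
    sl = [slice(None)] * 4
    sl[axis] = end
    sl[-1] = axis
    flux_cell[tuple(sl)] += 0.5 * dens_slice


class _IterCounter:
    def __init__(self):
        self.n = 0

    def __call__(self, _xk):
        self.n += 1
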