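"""Steady Stokes flow through the voxel pore space and permeability.

Air moving through nest-wall pores does so at Reynolds numbers of order
10⁻⁷–10⁻⁶, so the inertial terms of the Navier-Stokes equations are
negligible and the steady creeping-flow (Stokes) limit

    −μ∇²u + ∇p = 0,   ∇·u = 0

gives the same steady solution far more cheaply.  The discretisation is a
marker-and-cell staggered grid: pressures at pore-cell centres, velocity
components on cell faces, so the discrete velocity is divergence-free by
construction.  A fixed pressure is applied on the inlet and outlet faces of
the flow axis; all lateral boundaries and solid walls are no-slip (tangential
wall neighbours use a reflected ghost value, placing the wall half a voxel
from the first velocity row).  Permeability follows Darcy's law referenced
to the total (pore + solid) cross-section:

    k = U_D · μ · Δx / ΔP,   U_D = Q / A_total

with ``Δx = (N+1)h`` the distance between the ghost pressure centres, which
makes the straight-channel fixtures exact up to wall discretisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import minres, spsolve

from .image import ScalarField, VectorField, VoxelImage, axis_index
from .morphology import local_thickness

__all__ = [
    "FluidProperties",
    "AIR",
    "FlowResult",
    "solve_stokes",
    "velocity_statistics",
    "reynolds_number",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity (Pa·s) and density (kg/m³)."""

    mu: float = 1.8e-5
    rho: float = 1.2

    def __post_init__(self):
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")


#: ambient air at ~20 °C
AIR = FluidProperties()


@dataclass
class FlowResult:
    """Pressure/velocity fields with permeability and solver diagnostics."""

    pressure: ScalarField  # Pa
    velocity: VectorField  # m/s, cell-centred
    k_m2: float
    U_D: float  # Darcy velocity, m/s
    total_flow_m3_s: float
    plane_flow_m3_s: np.ndarray
    spanning: bool
    residual: float
    iterations: int
    axis: int
    delta_p: float
    fluid: FluidProperties
    length_m: float  # distance between the ghost pressure planes
    area_m2: float


def solve_stokes(
    img: VoxelImage,
    axis: int | str = 0,
    delta_p: float = 1.0,
    fluid: FluidProperties = AIR,
    tol: float = 1e-8,
    max_iter: int = 200_000,
    direct_threshold: int = 20_000,
    lateral_bc: str = "noslip",
) -> FlowResult:
    """Solve steady Stokes flow under a fixed pressure drop along ``axis``.

    A non-spanning pore space is a signal, not an error: the result comes
    back with ``spanning=False``, ``k_m2 = 0`` and zero fields.  The
    dimensionless saddle-point system is solved directly (sparse LU) below
    ``direct_threshold`` unknowns and by preconditioned MINRES above it;
    ``tol`` is the relative residual of the coupled momentum+mass system.

    ``lateral_bc`` controls the domain side boundaries: ``"noslip"``
    (default, side walls behave like solid, as in the nest-wall runs) or
    ``"slip"`` (free-slip symmetry planes, which turns the slit fixture
    into ideal plane Poiseuille flow for validation).  Solid walls inside
    the domain are always no-slip.
    """
    ax = axis_index(axis)
    if delta_p <= 0:
        raise ValueError("delta_p must be positive")
    h = img.voxel_size * 1e-6
    pore = img.pore_mask()
    shape = img.shape

    # restrict to pore clusters reachable from a pressure boundary (face conn.)
    lab, _ = ndi.label(pore, structure=ndi.generate_binary_structure(3, 1))
    lab_in = np.unique(np.take(lab, 0, axis=ax))
    lab_out = np.unique(np.take(lab, -1, axis=ax))
    lab_in = set(lab_in[lab_in > 0].tolist())
    lab_out = set(lab_out[lab_out > 0].tolist())
    spanning = len(lab_in & lab_out) > 0
    area = np.prod([shape[k] for k in range(3) if k != ax]) * h**2
    length = (shape[ax] + 1) * h

    if not spanning:
        return FlowResult(
            pressure=ScalarField(np.full(shape, np.nan), unit="Pa", support=pore),
            velocity=VectorField(np.zeros(shape + (3,)), unit="m/s", support=pore),
            k_m2=0.0, U_D=0.0, total_flow_m3_s=0.0,
            plane_flow_m3_s=np.zeros(shape[ax] + 1),
            spanning=False, residual=0.0, iterations=0, axis=ax,
            delta_p=delta_p, fluid=fluid, length_m=length, area_m2=float(area),
        )

    active_labs = np.array(sorted(lab_in | lab_out), dtype=lab.dtype)
    cell_act = np.isin(lab, active_labs)
    n_cells = int(cell_act.sum())
    cidx = np.full(shape, -1, dtype=np.int64)
    cidx[cell_act] = np.arange(n_cells)

    # --- face numbering ------------------------------------------------
    face_idx: list[np.ndarray] = []
    face_act: list[np.ndarray] = []
    n_faces = 0
    padded = np.pad(cell_act, 1)  # False border
    for d in range(3):
        fshape = tuple(n + (1 if k == d else 0) for k, n in enumerate(shape))
        # cells on the low/high side of each face (False outside the domain)
        sl_lo = tuple(
            slice(0, fshape[k] if k != d else fshape[k] - 0)
            for k in range(3)
        )
        lo = np.zeros(fshape, bool)
        hi = np.zeros(fshape, bool)
        sl_all = [slice(None)] * 3
        sl_all[d] = slice(1, None)
        lo[tuple(sl_all)] = cell_act
        sl_all[d] = slice(0, -1)
        hi[tuple(sl_all)] = cell_act
        act = lo & hi
        if True:  # open pressure boundaries along the flow axis
            if d == ax:
                sl0 = [slice(None)] * 3
                sl0[d] = 0
                act[tuple(sl0)] = np.take(cell_act, 0, axis=d)
                slN = [slice(None)] * 3
                slN[d] = fshape[d] - 1
                act[tuple(slN)] = np.take(cell_act, -1, axis=d)
        fi = np.full(fshape, -1, dtype=np.int64)
        nf = int(act.sum())
        fi[act] = n_faces + np.arange(nf)
        n_faces += nf
        face_idx.append(fi)
        face_act.append(act)

    n_unknowns = n_faces + n_cells

    # --- assemble A (dimensionless -∇² on faces) ------------------------
    rows_l, cols_l, vals_l = [], [], []
    diag = np.zeros(n_faces)
    rhs = np.zeros(n_unknowns)

    for d in range(3):
        fi = face_idx[d]
        act = face_act[d]
        ids = fi[act]
        for e in range(3):
            for s in (-1, 1):
                nb = np.roll(fi, -s, axis=e)
                # mark out-of-domain neighbours
                edge = [slice(None)] * 3
                edge[e] = -1 if s == 1 else 0
                oob = np.zeros_like(act)
                oob[tuple(edge)] = True
                nb_ids = nb[act]
                nb_oob = oob[act]
                nb_active = (nb_ids >= 0) & ~nb_oob
                # active neighbour: standard 5-point coupling
                a = nb_active
                rows_l.append(ids[a])
                cols_l.append(nb_ids[a])
                vals_l.append(-np.ones(int(a.sum())))
                np.add.at(diag, ids[a], 1.0)
                # inactive neighbour inside the domain, or lateral out-of-domain
                if e == d:
                    # wall face one cell away along the normal (u = 0 there);
                    # out-of-domain along the normal is the open boundary: drop
                    w = (~nb_active) & ~nb_oob
                    np.add.at(diag, ids[w], 1.0)
                else:
                    # tangential wall half a voxel away: reflected ghost (−u);
                    # free-slip domain sides drop the term instead
                    w = (~nb_active) & ~nb_oob
                    np.add.at(diag, ids[w], 2.0)
                    if lateral_bc == "noslip":
                        np.add.at(diag, ids[nb_oob], 2.0)
                    elif lateral_bc != "slip":
                        raise ValueError("lateral_bc must be 'noslip' or 'slip'")

    rows_l.append(np.arange(n_faces))
    cols_l.append(np.arange(n_faces))
    vals_l.append(diag)

    # --- pressure gradient G and boundary RHS ---------------------------
    for d in range(3):
        fi = face_idx[d]
        fshape = fi.shape
        sl_all = [slice(None)] * 3
        # cell on the high side (face position p borders cells p-1, p)
        sl_all[d] = slice(0, -1)
        hi_c = np.full(fshape, -1, dtype=np.int64)
        hi_c[tuple(sl_all)] = cidx
        sl_all[d] = slice(1, None)
        lo_c = np.full(fshape, -1, dtype=np.int64)
        lo_c[tuple(sl_all)] = cidx
        act = face_act[d]
        ids = fi[act]
        hi_ids = hi_c[act]
        lo_ids = lo_c[act]
        ok_hi = hi_ids >= 0
        rows_l.append(ids[ok_hi])
        cols_l.append(n_faces + hi_ids[ok_hi])
        vals_l.append(np.ones(int(ok_hi.sum())))
        ok_lo = lo_ids >= 0
        rows_l.append(ids[ok_lo])
        cols_l.append(n_faces + lo_ids[ok_lo])
        vals_l.append(-np.ones(int(ok_lo.sum())))
        # continuity rows (transpose of G)
        rows_l.append(n_faces + hi_ids[ok_hi])
        cols_l.append(ids[ok_hi])
        vals_l.append(np.ones(int(ok_hi.sum())))
        rows_l.append(n_faces + lo_ids[ok_lo])
        cols_l.append(ids[ok_lo])
        vals_l.append(-np.ones(int(ok_lo.sum())))
        if d == ax:
            # inlet ghost pressure p̂=1 (low side missing at position 0)
            inlet = act.copy()
            sl0 = [slice(None)] * 3
            sl0[d] = slice(1, None)
            inlet[tuple(sl0)] = False
            rhs[fi[inlet]] += 1.0  # p̂_in = 1, p̂_out = 0

    K = sparse.coo_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n_unknowns, n_unknowns),
    ).tocsr()

    iterations = 0
    if n_unknowns <= direct_threshold:
        x = spsolve(K.tocsc(), rhs)
    else:
        # block-diagonal SPD preconditioner: diag(A) and a Schur surrogate
        schur = np.zeros(n_cells)
        for d in range(3):
            fi = face_idx[d]
            act = face_act[d]
            fshape = fi.shape
            sl_all = [slice(None)] * 3
            sl_all[d] = slice(0, -1)
            hi_c = np.full(fshape, -1, dtype=np.int64)
            hi_c[tuple(sl_all)] = cidx
            sl_all[d] = slice(1, None)
            lo_c = np.full(fshape, -1, dtype=np.int64)
            lo_c[tuple(sl_all)] = cidx
            inv = 1.0 / diag[fi[act]]
            for cids in (hi_c[act], lo_c[act]):
                ok = cids >= 0
                np.add.at(schur, cids[ok], inv[ok])
        m_diag = np.concatenate([diag, schur])
        m_diag[m_diag <= 0] = 1.0
        M = sparse.diags(1.0 / m_diag)
        counter = _IterCounter()
        x, info = minres(K, rhs, rtol=tol, maxiter=max_iter, M=M,
                         callback=counter)
        iterations = counter.n
        if info != 0:
            raise RuntimeError(
                f"Stokes solve did not converge (info={info}) within "
                f"{max_iter} MINRES iterations"
            )
    residual = float(np.linalg.norm(K @ x - rhs) / np.linalg.norm(rhs))

    u_flat = x[:n_faces]
    p_flat = x[n_faces:]

    # --- physical fields -------------------------------------------------
    u_scale = delta_p * h / fluid.mu  # m/s per dimensionless unit
    vel = np.zeros(shape + (3,))
    for d in range(3):
        fi = face_idx[d]
        uf = np.zeros(fi.shape)
        uf[face_act[d]] = u_flat[fi[face_act[d]]]
        sl_lo = [slice(None)] * 3
        sl_lo[d] = slice(0, -1)
        sl_hi = [slice(None)] * 3
        sl_hi[d] = slice(1, None)
        vel[..., d] = 0.5 * (uf[tuple(sl_lo)] + uf[tuple(sl_hi)]) * u_scale

    pressure = np.full(shape, np.nan)
    pressure[cell_act] = p_flat * delta_p
    # pore cells cut off from both boundaries sit at the mid pressure
    pressure[pore & ~cell_act] = 0.5 * delta_p

    # plane-integrated volumetric flow (m³/s) along the axis
    fi = face_idx[ax]
    uf = np.zeros(fi.shape)
    uf[face_act[ax]] = u_flat[fi[face_act[ax]]]
    other = tuple(k for k in range(3) if k != ax)
    plane_flow = uf.sum(axis=other) * u_scale * h**2

    total_q = float(plane_flow[-1])
    U_D = total_q / area
    k = U_D * fluid.mu * length / delta_p

    return FlowResult(
        pressure=ScalarField(pressure, unit="Pa", support=pore),
        velocity=VectorField(vel, unit="m/s", support=pore),
        k_m2=float(k),
        U_D=float(U_D),
        total_flow_m3_s=total_q,
        plane_flow_m3_s=plane_flow,
        spanning=True,
        residual=residual,
        iterations=iterations,
        axis=ax,
        delta_p=delta_p,
        fluid=fluid,
        length_m=length,
        area_m2=float(area),
    )


class _IterCounter:
    def __init__(self):
        self.n = 0

    def __call__(self, _xk):
        self.n += 1


def velocity_statistics(
    result: FlowResult,
    img: VoxelImage,
    stagnant_cutoff_fraction: float = 0.01,
    bins: int = 40,
):
    """PDF of log₁₀ pore speeds and the stagnant-zone fraction.

    The stagnant fraction is the share of pore voxels whose speed falls
    below ``stagnant_cutoff_fraction`` × mean pore speed — the wide, heavy
    low tail of this distribution is the signature of dead-end and
    micropore regions that carry almost no flow.

    Returns ``(bin_centers_log10, density, stagnant_fraction)``.
    """
    pore = img.pore_mask()
    speed = np.linalg.norm(result.velocity.values, axis=-1)[pore]
    if speed.size == 0 or speed.max() == 0.0:
        raise ValueError("zero velocity everywhere (non-spanning pore space)")
    mean_speed = speed.mean()
    stagnant = float((speed < stagnant_cutoff_fraction * mean_speed).mean())
    pos = speed[speed > 0]
    logs = np.log10(pos)
    counts, edges = np.histogram(logs, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, stagnant


def reynolds_number(
    result: FlowResult,
    img: VoxelImage,
    fluid: FluidProperties | None = None,
    thickness: ScalarField | None = None,
) -> float:
    """Re = ρ·|u|_mean·d_char/μ with d_char = 2 × mean pore inscribed radius.

    The characteristic length is a declared choice (twice the mean
    local-thickness radius of the pore space); values ≪ 1 confirm the
    creeping-flow assumption behind the Stokes model.
    """
    if fluid is None:
        fluid = result.fluid
    pore = img.pore_mask()
    speed = np.linalg.norm(result.velocity.values, axis=-1)[pore]
    if speed.size == 0:
        return 0.0
    if thickness is None:
        thickness = local_thickness(img)
    d_char = 2.0 * thickness.values[pore].mean() * 1e-6  # m
    return float(fluid.rho * speed.mean() * d_char / fluid.mu)
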