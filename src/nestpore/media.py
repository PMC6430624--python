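"""Synthetic voxel porous media emulating termite nest-wall microstructure.

The micro-CT scans behind the published nest-wall analysis were never
deposited, so this module generates media with the same statistical
structure: random grain packs (the "random pack" control), two-scale
pellet packs in which fused soil pellets (radius 0.52 ± 0.44 mm) leave
inter-pellet macropores while correlated-noise carving provides the
intra-pellet micropores (≈19 μm mean radius), cracked low-porosity clayey
matrices, drained air/water occupancy states, and exact analytic geometries
(tubes, slits, layered slabs, tetrahedral pellet cells, spherical cavities)
with closed-form transport properties for solver validation.

All generators are deterministic under ``MediumSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi

from .image import VoxelImage, axis_index
from .morphology import local_thickness

__all__ = [
    "MediumSpec",
    "CrackParams",
    "PackingError",
    "generate_sphere_pack",
    "generate_pellet_pack",
    "generate_analytic_geometry",
    "generate_cracked_matrix",
    "generate_drained_state",
]


class PackingError(RuntimeError):
    """Raised when a target porosity cannot be reached by sphere placement."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"target porosity {target:.3f} unreachable; "
            f"achieved {achieved:.3f} before exhausting attempts"
        )


@dataclass
class CrackParams:
    """Planar shrinkage cracks crossing a clayey matrix."""

    count: int = 3
    aperture_um: float = 30.0
    #: 'uniform' random plane normals, or 'z'/'y'/'x' for planes normal to an axis
    orientation: str = "uniform"


@dataclass
class MediumSpec:
    """Parameters of a synthetic nest-wall medium.

    Defaults describe the Senegal-like outer wall: total porosity 28%,
    pellets of radius 0.52 ± 0.44 mm, intra-pellet micropores of mean
    radius 19.3 ± 10.6 μm carving an 18.3% porosity inside pellets.  The
    split of total porosity between the two scales is not published
    separately, so ``micro_porosity`` is a free parameter.  The domain
    defaults to 160³ voxels at 15 μm (2.4 mm across, above the ≈2.2 mm
    representative-volume scale of the real samples).
    """

    domain_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size: float = 15.0  # μm
    pellet_radius_mean_mm: float = 0.52
    pellet_radius_sd_mm: float = 0.44
    target_porosity: float = 0.28
    micropore_radius_mean_um: float = 19.3
    micropore_radius_sd_um: float = 10.6
    #: porosity carved inside pellets; 0 disables micropores
    micro_porosity: float = 0.183
    #: grain radius for single-scale random packs (fine-sand scale), μm
    grain_radius_mean_um: float = 65.0
    grain_radius_sd_um: float = 15.0
    #: allowed grain overlap fraction for sphere packs (0 = hard spheres)
    overlap: float = 0.0
    #: pellet centres may approach factor × (r_i + r_j)/2 (fusion of moist pellets)
    pellet_overlap_factor: float = 1.45
    crack_params: CrackParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_porosity < 1.0):
            raise ValueError("target_porosity must lie in (0, 1)")
        if not (0.0 <= self.micro_porosity < 1.0):
            raise ValueError("micro_porosity must lie in [0, 1)")
        for name in ("voxel_size", "pellet_radius_mean_mm", "grain_radius_mean_um",
                     "micropore_radius_mean_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.domain_shape = tuple(int(n) for n in self.domain_shape)
        if len(self.domain_shape) != 3 or min(self.domain_shape) < 1:
            raise ValueError("domain_shape must be three positive integers")

    # -- config round-trip ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MediumSpec":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("MediumSpec config requires an explicit seed")
        if d.get("crack_params") is not None and not isinstance(
            d["crack_params"], CrackParams
        ):
            d["crack_params"] = CrackParams(**d["crack_params"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())))

    @classmethod
    def from_yaml(cls, text: str) -> "MediumSpec":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, size=None):
    """Normal draws redrawn until above ``lo`` (simple rejection)."""
    out = rng.normal(mean, sd, size=size)
    scalar = np.isscalar(out)
    out = np.atleast_1d(out)
    for _ in range(1000):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    out = np.maximum(out, lo)
    return float(out[0]) if scalar else out


def _paint_sphere(solid: np.ndarray, centre: np.ndarray, radius: float) -> int:
    """Set voxels within ``radius`` of ``centre`` solid; return newly set count."""
    shape = solid.shape
    lo = np.maximum(np.floor(centre - radius).astype(int), 0)
    hi = np.minimum(np.ceil(centre + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return 0
    zz, yy, xx = np.meshgrid(
        *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
    )
    inside = (
        (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    ) <= radius**2
    view = solid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    new = int((inside & ~view).sum())
    view |= inside
    return new


def _pack_spheres(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    radius_sampler,
    target_solid_fraction: float,
    min_dist_factor: float,
    max_attempts: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random sequential addition of spheres until the solid target is met.

    ``min_dist_factor`` scales the allowed centre distance relative to
    ``(r_i + r_j)``: 1.0 means hard (tangent) spheres, smaller values allow
    overlap/fusion.  Raises :class:`PackingError` when attempts run out.
    """
    solid = np.zeros(shape, dtype=bool)
    total = solid.size
    centres: list[np.ndarray] = []
    radii: list[float] = []
    c_arr = np.empty((0, 3))
    r_arr = np.empty(0)
    attempts = 0
    while solid.sum() / total < target_solid_fraction:
        if attempts >= max_attempts:
            raise PackingError(1 - target_solid_fraction, 1 - solid.sum() / total)
        attempts += 1
        r = radius_sampler()
        c = rng.uniform(0, 1, 3) * np.array(shape)
        if len(radii):
            d2 = ((c_arr - c) ** 2).sum(axis=1)
            if np.any(d2 < (min_dist_factor * (r_arr + r)) ** 2):
                continue
        centres.append(c)
        radii.append(r)
        c_arr = np.asarray(centres)
        r_arr = np.asarray(radii)
        _paint_sphere(solid, c, r)
    return solid, c_arr, r_arr


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_sphere_pack(spec: MediumSpec, max_attempts: int = 200_000) -> VoxelImage:
    """Single-scale random grain pack (the slurry "random pack" control).

    Solid grains of radius ``grain_radius_mean_um ± sd`` are placed by
    random sequential addition until porosity reaches the target within
    ±1% absolute.  Hard-sphere addition jams near 62% void, so denser
    packs (like the ≈36% random-pack porosity) need ``spec.overlap > 0``.
    """
    rng = np.random.default_rng(spec.seed)
    r_vox_mean = spec.grain_radius_mean_um / spec.voxel_size
    r_vox_sd = spec.grain_radius_sd_um / spec.voxel_size
    if r_vox_mean < 2.0:
        raise ValueError("grain radius below 2 voxels; coarsen voxel_size")
    sampler = lambda: _truncated_normal(rng, r_vox_mean, r_vox_sd, 2.0)
    solid, _, _ = _pack_spheres(
        spec.domain_shape,
        rng,
        sampler,
        target_solid_fraction=1.0 - spec.target_porosity,
        min_dist_factor=(1.0 - spec.overlap),
        max_attempts=max_attempts,
    )
    labels = np.where(solid, 1, 0).astype(np.uint8)
    return VoxelImage(labels=labels, voxel_size=spec.voxel_size,
                      phase_table={0: "air", 1: "solid"})


def generate_pellet_pack(
    spec: MediumSpec,
    carve_micropores: bool = True,
    max_attempts: int = 400_000,
) -> VoxelImage:
    """Two-scale medium: fused pellet spheres plus intra-pellet micropores.

    Pellets (spheres, radius from the pellet distribution) are added with
    centre distances allowed down to ``pellet_overlap_factor × (r_i+r_j)/2``
    — the fusion of moist pellets pressed together — until the inter-pellet
    void fraction reaches its share of the porosity budget.  Micropores are
    then carved inside the pellet solid by thresholding Gaussian-filtered
    white noise with correlation length set by the micropore radius, at
    exactly ``micro_porosity`` of the solid.  Total porosity lands within
    ±1% (absolute) of ``target_porosity`` by construction of the split
    φ_macro = (φ_total − φ_micro) / (1 − φ_micro).
    """
    rng = np.random.default_rng(spec.seed)
    phi_total = spec.target_porosity
    phi_micro = spec.micro_porosity
    # the porosity split is fixed by the spec; disabling carving removes the
    # micropore contribution and leaves the inter-pellet voids only
    phi_macro = (phi_total - phi_micro) / (1.0 - phi_micro)
    if phi_macro <= 0:
        raise ValueError(
            f"infeasible split: micro_porosity {phi_micro:.3f} alone exceeds "
            f"target porosity {phi_total:.3f}"
        )
    r_vox_mean = spec.pellet_radius_mean_mm * 1000.0 / spec.voxel_size
    r_vox_sd = spec.pellet_radius_sd_mm * 1000.0 / spec.voxel_size
    if r_vox_mean < 4.0:
        raise ValueError("pellet radius below 4 voxels; refine voxel_size")
    sampler = lambda: _truncated_normal(rng, r_vox_mean, r_vox_sd, 4.0)
    pellet_solid, _, _ = _pack_spheres(
        spec.domain_shape,
        rng,
        sampler,
        target_solid_fraction=1.0 - phi_macro,
        min_dist_factor=spec.pellet_overlap_factor / 2.0,
        max_attempts=max_attempts,
    )

    pore = ~pellet_solid
    if carve_micropores and phi_micro > 0:
        if spec.micropore_radius_mean_um < spec.voxel_size:
            raise ValueError("micropore radius below 1 voxel; refine voxel_size")
        sigma = spec.micropore_radius_mean_um / spec.voxel_size
        noise = ndi.gaussian_filter(
            rng.standard_normal(spec.domain_shape), sigma=sigma
        )
        inside = noise[pellet_solid]
        cut = np.quantile(inside, 1.0 - phi_micro)
        pore |= pellet_solid & (noise > cut)

    labels = np.where(pore, 0, 1).astype(np.uint8)
    return VoxelImage(labels=labels, voxel_size=spec.voxel_size,
                      phase_table={0: "air", 1: "solid"})


def generate_micropore_matrix(spec: MediumSpec) -> VoxelImage:
    """Micropore-only medium: correlated-noise pores in a solid block.

    Emulates a cubical subset of wall material containing only the small
    intra-pellet pores: Gaussian-filtered white noise (correlation length
    set by the micropore radius) thresholded so exactly
    ``spec.micro_porosity`` of the volume is void.  This is also the
    carving process applied inside pellets by :func:`generate_pellet_pack`,
    so comparing transport through this medium against the full two-scale
    pack isolates the effect of the inter-pellet macropore network.
    """
    if spec.micro_porosity <= 0:
        raise ValueError("micro_porosity must be positive for a micropore matrix")
    if spec.micropore_radius_mean_um < spec.voxel_size:
        raise ValueError("micropore radius below 1 voxel; refine voxel_size")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.micropore_radius_mean_um / spec.voxel_size
    noise = ndi.gaussian_filter(rng.standard_normal(spec.domain_shape), sigma=sigma)
    cut = np.quantile(noise, 1.0 - spec.micro_porosity)
    labels = np.where(noise > cut, 0, 1).astype(np.uint8)
    return VoxelImage(labels=labels, voxel_size=spec.voxel_size,
                      phase_table={0: "air", 1: "solid"})


def generate_analytic_geometry(
    kind: str,
    shape: tuple[int, int, int],
    voxel_size: float = 1.0,
    **params,
) -> VoxelImage:
    """Exact voxelisations of geometries with closed-form transport behaviour.

    Kinds
    -----
    tube
        Circular channel of ``radius`` (voxels) along ``axis``.
    parallel_plates
        Open slit of ``aperture`` voxel layers normal to ``gap_axis``,
        spanning the domain along every other axis.
    layered_slab
        Stack of solid layers along ``axis``; ``layers`` is a sequence of
        ``(phase_name, thickness_voxels)``.
    tetrahedral_cell
        Four mutually tangent equal spheres of ``radius`` (voxels) in the
        closest-packing arrangement; the central pore admits an inscribed
        sphere of radius ``(sqrt(3/2) − 1)·R ≈ 0.2247·R``.
    spherical_cavity
        Single spherical pore of ``radius`` (voxels) in solid.
    """
    shape = tuple(int(n) for n in shape)
    zc, yc, xc = [(n - 1) / 2.0 for n in shape]
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")

    def check_feature(extent_vox: float, name: str) -> None:
        if extent_vox < 4:
            raise ValueError(f"{name} of {extent_vox} voxels is below the "
                             "4-voxel resolution floor")

    if kind == "tube":
        r = float(params["radius"])
        ax = axis_index(params.get("axis", 0))
        check_feature(2 * r, "tube diameter")
        coords = [zz - zc, yy - yc, xx - xc]
        trans = [coords[i] for i in range(3) if i != ax]
        pore = trans[0] ** 2 + trans[1] ** 2 <= r**2
        labels = np.where(pore, 0, 1).astype(np.uint8)
        table = {0: "air", 1: "solid"}

    elif kind == "parallel_plates":
        a = int(params["aperture"])
        gax = axis_index(params.get("gap_axis", 1))
        check_feature(a, "slit aperture")
        n = shape[gax]
        start = (n - a) // 2
        idx = (zz, yy, xx)[gax]
        pore = (idx >= start) & (idx < start + a)
        labels = np.where(pore, 0, 1).astype(np.uint8)
        table = {0: "air", 1: "solid"}

    elif kind == "layered_slab":
        layers: Sequence = params["layers"]
        ax = axis_index(params.get("axis", 0))
        if sum(t for _, t in layers) != shape[ax]:
            raise ValueError("layer thicknesses must sum to the domain extent")
        # dense labels, air (if present) always label 0
        names: list[str] = []
        for name, _ in layers:
            if name not in names:
                names.append(name)
        if "air" in names:
            names.remove("air")
            names.insert(0, "air")
        name_to_label = {name: i for i, name in enumerate(names)}
        table = {i: name for name, i in name_to_label.items()}
        labels = np.zeros(shape, dtype=np.uint8)
        pos = 0
        sl: list = [slice(None)] * 3
        for name, t in layers:
            sl[ax] = slice(pos, pos + t)
            labels[tuple(sl)] = name_to_label[name]
            pos += t

    elif kind == "tetrahedral_cell":
        R = float(params["radius"])
        check_feature(2 * R, "pellet diameter")
        s = R / np.sqrt(2.0)
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
        ) * s + np.array([zc, yc, xc])
        solid = np.zeros(shape, bool)
        for v in verts:
            solid |= (
                (zz - v[0]) ** 2 + (yy - v[1]) ** 2 + (xx - v[2]) ** 2
            ) <= R**2
        labels = np.where(solid, 1, 0).astype(np.uint8)
        table = {0: "air", 1: "solid"}

    elif kind == "spherical_cavity":
        r = float(params["radius"])
        check_feature(2 * r, "cavity diameter")
        pore = ((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2) <= r**2
        labels = np.where(pore, 0, 1).astype(np.uint8)
        table = {0: "air", 1: "solid"}

    else:
        raise ValueError(f"unknown analytic geometry kind {kind!r}")

    return VoxelImage(labels=labels, voxel_size=voxel_size, phase_table=table)


def generate_cracked_matrix(
    spec: MediumSpec,
    planes: Sequence[tuple] | None = None,
) -> VoxelImage:
    """Solid clayey matrix crossed by planar shrinkage cracks.

    Cracks are slabs of the given aperture about random (or axis-normal)
    planes through random interior points.  ``planes`` may supply explicit
    ``(point_vox, normal, aperture_um)`` triples for reproducible fixtures;
    otherwise ``spec.crack_params`` drives random generation.  The achieved
    crack porosity is recorded in ``img.provenance``.
    """
    shape = spec.domain_shape
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pore = np.zeros(shape, bool)
    if planes is None:
        cp = spec.crack_params or CrackParams(count=0)
        planes = []
        for _ in range(cp.count):
            point = rng.uniform(0.15, 0.85, 3) * np.array(shape)
            if cp.orientation == "uniform":
                n = rng.standard_normal(3)
                n /= np.linalg.norm(n)
            else:
                n = np.zeros(3)
                n[axis_index(cp.orientation)] = 1.0
            planes.append((point, n, cp.aperture_um))
    for point, normal, aperture_um in planes:
        point = np.asarray(point, float)
        normal = np.asarray(normal, float)
        normal = normal / np.linalg.norm(normal)
        half = aperture_um / spec.voxel_size / 2.0
        if 2 * half < 1.0:
            raise ValueError("crack aperture below one voxel")
        dist = (
            (zz - point[0]) * normal[0]
            + (yy - point[1]) * normal[1]
            + (xx - point[2]) * normal[2]
        )
        pore |= np.abs(dist) <= half
    labels = np.where(pore, 0, 1).astype(np.uint8)
    img = VoxelImage(labels=labels, voxel_size=spec.voxel_size,
                     phase_table={0: "air", 1: "clay"})
    img.provenance = {"crack_porosity": float(pore.mean())}  # type: ignore[attr-defined]
    return img


def generate_drained_state(
    img: VoxelImage,
    inlet_axis: int | str = 0,
    entry_radius_um: float = 0.0,
    connectivity: int = 6,
    thickness=None,
) -> VoxelImage:
    """Morphological invasion of air into a two-phase medium (drainage).

    Air, the non-wetting phase, occupies pore voxels whose local
    inscribed-sphere radius is at least ``entry_radius_um`` *and* that
    connect to the inlet face through such voxels; all remaining pores stay
    water-filled.  This is the morphological idealisation of capillary
    drainage: larger pores offer less resistance to air entry and fill
    first.  Face (6-) connectivity matches the transport solvers.
    """
    pore = img.pore_mask()
    if entry_radius_um < 0:
        raise ValueError("entry_radius_um must be non-negative")
    if 0 < entry_radius_um < img.voxel_size / 2:
        raise ValueError(
            f"entry radius {entry_radius_um} μm is below the voxel "
            f"resolution ({img.voxel_size} μm voxels)"
        )
    ax = axis_index(inlet_axis)
    if entry_radius_um == 0:
        invadable = pore
    else:
        if thickness is None:
            thickness = local_thickness(img)
        invadable = pore & (thickness.values >= entry_radius_um)
    struct = ndi.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labeled, _ = ndi.label(invadable, structure=struct)
    inlet_labels = np.unique(np.take(labeled, 0, axis=ax))
    inlet_labels = inlet_labels[inlet_labels > 0]
    air = np.isin(labeled, inlet_labels)
    labels = np.ones(img.shape, dtype=np.uint8)  # solid
    labels[pore] = 2  # water
    labels[air] = 0  # invading air
    table = {0: "air", 1: "solid", 2: "water"}
    # preserve multi-phase solids (e.g. clay) if present
    solid_names = {k: v for k, v in img.phase_table.items() if v != "air"}
    if set(solid_names.values()) - {"solid"}:
        labels = labels.astype(np.int16)
        for lab, name in solid_names.items():
            sel = img.labels == lab
            new_lab = max(table) + 1
            table[new_lab] = name
            labels[sel] = new_lab
    return VoxelImage(labels=labels, voxel_size=img.voxel_size, phase_table=table)
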