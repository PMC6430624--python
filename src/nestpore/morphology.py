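"""Morphological descriptors of labeled voxel images.

These are the descriptors used to characterise nest-wall microstructure:
porosity with its slice-to-slice scatter, representative-elementary-volume
(REV) curves, local thickness maps built from maximal inscribed spheres,
pore-size distributions, axis connectivity of the pore network, the
percolation threshold radius, phase occupancy of drained media per pore-size
class, and dilation/erosion-masked structure thickness.

Conventions
-----------
* The Euclidean distance transform ``dt`` is measured in voxels between
  voxel centres; radii are converted to micrometres on output.
* A sphere of radius ``r`` centred on voxel ``y`` *covers* voxel ``x`` when
  ``|x - y| < r``; the local thickness at ``x`` is the largest ``dt(y)``
  among covering centres.  This is the maximal-inscribed-sphere definition.
* Cluster connectivity defaults to 26-neighbour for connectivity and
  percolation analysis (the convention of common commercial toolkits),
  while the transport solvers use face (6-) connectivity; both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .image import PORE_PHASES, ScalarField, VoxelImage, axis_index

__all__ = [
    "segment_binary",
    "porosity",
    "rev_curve",
    "local_thickness",
    "PoreSizeDistribution",
    "PoreSizeDistributions",
    "pore_size_distribution",
    "axis_connectivity",
    "PercolationResult",
    "percolation_threshold",
    "pore_occupancy",
    "structure_thickness",
    "MorphologyReport",
    "morphology_report",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


# ---------------------------------------------------------------------------
# segmentation (simple global-threshold surrogate)
# ---------------------------------------------------------------------------

def segment_binary(
    gray: ScalarField | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    voxel_size: float = 1.0,
    pore_is_low: bool = True,
) -> VoxelImage:
    """Threshold a grayscale volume into a two-phase (air/solid) image.

    In CT data pores are dark, so voxels below the threshold become air by
    default.  The chosen threshold is recorded on the returned image as
    ``img.provenance``.
    """
    values = gray.values if isinstance(gray, ScalarField) else np.asarray(gray, float)
    if values.ndim != 3:
        raise ValueError("expected a 3-D grayscale volume")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("degenerate histogram: grayscale volume is constant")
    if method == "otsu":
        thr = float(threshold_otsu(values))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    low = values < thr
    labels = np.where(low if pore_is_low else ~low, 0, 1).astype(np.uint8)
    img = VoxelImage(labels=labels, voxel_size=voxel_size,
                     phase_table={0: "air", 1: "solid"})
    img.provenance = {"method": method, "threshold": thr}  # type: ignore[attr-defined]
    return img


# ---------------------------------------------------------------------------
# porosity and REV
# ---------------------------------------------------------------------------

def porosity(
    img: VoxelImage,
    slice_axis: int | str = 0,
    phases: frozenset[str] | set[str] = PORE_PHASES,
) -> tuple[float, float]:
    """Void fraction φ = pore voxels / all voxels, with per-slice scatter.

    The second return value is the standard deviation of the porosities of
    the 2-D slices taken along ``slice_axis``, the same slice-wise scatter
    used to attach an uncertainty to sample porosities.
    """
    ax = axis_index(slice_axis)
    pore = img.pore_mask(phases)
    phi = float(pore.mean())
    other = tuple(i for i in range(3) if i != ax)
    per_slice = pore.mean(axis=other)
    return phi, float(per_slice.std())


def rev_curve(img: VoxelImage, side_lengths) -> pd.DataFrame:
    """Porosity of centred cubical subsets, normalised to the largest cube.

    Flat curves beyond some side length indicate the representative
    elementary volume has been reached.
    """
    sides = sorted(int(s) for s in side_lengths)
    if sides[0] <= 0:
        raise ValueError("side lengths must be positive")
    if sides[-1] > min(img.shape):
        raise ValueError(
            f"largest side {sides[-1]} exceeds smallest image dimension "
            f"{min(img.shape)}"
        )
    pore = img.pore_mask()
    centre = np.array(img.shape) // 2
    rows = []
    for s in sides:
        lo = np.maximum(centre - s // 2, 0)
        hi = np.minimum(lo + s, img.shape)
        lo = hi - s
        sub = pore[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        rows.append((s, s * img.voxel_size, float(sub.mean())))
    df = pd.DataFrame(rows, columns=["side_voxels", "side_um", "porosity"])
    ref = df["porosity"].iloc[-1]
    df["normalized"] = df["porosity"] / ref if ref > 0 else np.nan
    return df


# ---------------------------------------------------------------------------
# local thickness (maximal inscribed spheres)
# ---------------------------------------------------------------------------

def local_thickness(
    img: VoxelImage,
    phase: str = "air",
    max_radii: int | None = None,
) -> ScalarField:
    """Largest inscribed-sphere radius (μm) covering each phase voxel.

    For each candidate radius ``r`` (descending), the set of sphere centres
    ``{dt >= r}`` is dilated by a Euclidean ball of radius ``r``; voxels
    reached for the first time get local thickness ``r``.  Iterating every
    distinct value of the distance transform makes the result exactly the
    maximal-inscribed-sphere field; ``max_radii`` caps the number of radii
    (subsampled, largest kept) for big images at the cost of quantising the
    output to the retained radii.
    """
    mask = img.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"phase {phase!r} has no voxels")
    # all lattice distances have integer squares: exact tie-breaking
    dt2 = np.round(ndi.distance_transform_edt(mask) ** 2).astype(np.int64)
    radii2 = np.unique(dt2[mask])
    radii2 = radii2[radii2 > 0][::-1]  # descending
    if max_radii is not None and len(radii2) > max_radii:
        idx = np.unique(np.linspace(0, len(radii2) - 1, max_radii).astype(int))
        radii2 = radii2[idx]
    lt2 = np.zeros(img.shape, dtype=np.int64)
    for r2 in radii2:
        centres = dt2 >= r2
        # squared distance from every voxel to the nearest eligible centre
        reach2 = np.round(
            ndi.distance_transform_edt(~centres) ** 2
        ).astype(np.int64)
        covered = mask & (reach2 < r2) & (lt2 == 0)
        lt2[covered] = r2
    return ScalarField(
        values=np.sqrt(lt2.astype(float)) * img.voxel_size,
        unit="um",
        support=mask,
    )


# ---------------------------------------------------------------------------
# pore-size distributions
# ---------------------------------------------------------------------------

@dataclass
class PoreSizeDistribution:
    """Histogram of pore radii with summary moments.

    ``density`` integrates to one over the bins; ``cumulative`` rises
    monotonically to one.  ``weighting`` records whether every phase voxel
    contributed ('per-voxel', from the local-thickness field) or only
    maximal spheres seeded on the medial axis ('medial-axis').
    """

    bin_edges_um: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray
    mean_um: float
    sd_um: float
    weighting: str
    values_um: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_values(cls, values_um, bins, weighting: str) -> "PoreSizeDistribution":
        values_um = np.asarray(values_um, float)
        if values_um.size == 0:
            raise ValueError("no radii to build a distribution from")
        counts, edges = np.histogram(values_um, bins=bins)
        total = counts.sum()
        widths = np.diff(edges)
        density = counts / (total * widths) if total else counts * 0.0
        cumulative = np.cumsum(counts) / total if total else counts * 0.0
        return cls(
            bin_edges_um=edges,
            density=density,
            cumulative=cumulative,
            mean_um=float(values_um.mean()),
            sd_um=float(values_um.std()),
            weighting=weighting,
            values_um=values_um,
        )

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_um": self.bin_centers_um,
                "density": self.density,
                "cumulative": self.cumulative,
            }
        )


@dataclass
class PoreSizeDistributions:
    """Per-voxel and medial-axis weighted distributions of the same image."""

    per_voxel: PoreSizeDistribution
    medial_axis: PoreSizeDistribution


def pore_size_distribution(
    img: VoxelImage,
    phase: str = "air",
    bins=32,
    thickness: ScalarField | None = None,
) -> PoreSizeDistributions:
    """Pore-radius distributions from maximal inscribed spheres.

    Two weightings are reported: *per-voxel* (each pore voxel contributes
    its local thickness) and *medial-axis* (inscribed-sphere radii sampled
    where the spheres are seeded, i.e. the distance transform on the
    topological skeleton of the pore phase).
    """
    mask = img.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"phase {phase!r} has no voxels")
    if thickness is None:
        thickness = local_thickness(img, phase=phase)
    per_voxel_values = thickness.values[mask]

    skel = skeletonize(mask)
    dt = ndi.distance_transform_edt(mask) * img.voxel_size
    ma_values = dt[skel & mask]
    if ma_values.size == 0:  # degenerate tiny phases: fall back to maxima
        ma_values = np.array([dt[mask].max()])

    # shared bin edges so the two weightings are directly comparable
    all_vals = np.concatenate([per_voxel_values, ma_values])
    edges = np.histogram_bin_edges(all_vals, bins=bins)
    return PoreSizeDistributions(
        per_voxel=PoreSizeDistribution.from_values(per_voxel_values, edges, "per-voxel"),
        medial_axis=PoreSizeDistribution.from_values(ma_values, edges, "medial-axis"),
    )


# ---------------------------------------------------------------------------
# connectivity and percolation
# ---------------------------------------------------------------------------

def axis_connectivity(
    img_or_mask: VoxelImage | np.ndarray,
    phase: str = "air",
    axis: int | str = 0,
    connectivity: int = 26,
) -> tuple[float, np.ndarray]:
    """Fraction of a phase in clusters spanning the image along ``axis``.

    Returns ``(fraction, mask)`` where ``mask`` selects the voxels of every
    cluster that touches both end faces.  A boolean array may be passed
    directly in place of an image.
    """
    if isinstance(img_or_mask, VoxelImage):
        mask = img_or_mask.phase_mask(phase)
    else:
        mask = np.asarray(img_or_mask, bool)
    ax = axis_index(axis)
    total = int(mask.sum())
    if total == 0:
        return 0.0, np.zeros_like(mask)
    labeled, _ = ndi.label(mask, structure=_structure(connectivity))
    first = np.take(labeled, 0, axis=ax)
    last = np.take(labeled, -1, axis=ax)
    spanning = np.intersect1d(np.unique(first), np.unique(last))
    spanning = spanning[spanning > 0]
    if spanning.size == 0:
        return 0.0, np.zeros_like(mask)
    span_mask = np.isin(labeled, spanning)
    return float(span_mask.sum() / total), span_mask


@dataclass
class PercolationResult:
    """Outcome of the threshold-radius search on the local-thickness field.

    ``threshold_um`` is the largest inscribed-sphere radius at which the
    sub-pore-space of at least that local size still spans ``axis``; one
    radius step above it the filtered pore space disconnects.
    """

    percolating: bool
    threshold_um: float
    axis: int
    cluster_mask: np.ndarray
    cluster_radii_um: np.ndarray
    candidate_radii_um: np.ndarray

    def radius_distribution(self, bins=16) -> PoreSizeDistribution:
        return PoreSizeDistribution.from_values(
            self.cluster_radii_um, bins, "percolating-cluster"
        )


def percolation_threshold(
    img: VoxelImage,
    axis: int | str = 0,
    phase: str = "air",
    connectivity: int = 26,
    thickness: ScalarField | None = None,
) -> PercolationResult:
    """Largest sphere radius whose sub-pore-space still spans the axis.

    The search bisects the sorted distinct radii of the local-thickness
    field; spanning is monotone in the radius so the bisection result is
    the exact discrete argmax (equal to a linear scan).
    """
    ax = axis_index(axis)
    if thickness is None:
        thickness = local_thickness(img, phase=phase)
    lt = thickness.values
    mask = img.phase_mask(phase)
    radii = np.unique(lt[mask])
    radii = radii[radii > 0]

    def spans(r: float) -> tuple[bool, np.ndarray]:
        frac, span_mask = axis_connectivity(mask & (lt >= r), axis=ax,
                                            connectivity=connectivity)
        return frac > 0, span_mask

    ok0, mask0 = spans(radii[0])
    if not ok0:
        return PercolationResult(False, float("nan"), ax,
                                 np.zeros_like(mask), np.array([]), radii)
    lo, hi = 0, len(radii) - 1  # invariant: spans(radii[lo]) is True
    ok_hi, mask_hi = spans(radii[hi])
    if ok_hi:
        lo, best_mask = hi, mask_hi
    else:
        best_mask = mask0
        while hi - lo > 1:
            mid = (lo + hi) // 2
            ok, m = spans(radii[mid])
            if ok:
                lo, best_mask = mid, m
            else:
                hi = mid
    r_star = float(radii[lo])
    return PercolationResult(
        percolating=True,
        threshold_um=r_star,
        axis=ax,
        cluster_mask=best_mask,
        cluster_radii_um=lt[best_mask],
        candidate_radii_um=radii,
    )


# ---------------------------------------------------------------------------
# pore occupancy of drained media
# ---------------------------------------------------------------------------

def pore_occupancy(
    multiphase: VoxelImage,
    dry_thickness: ScalarField,
    bins=12,
    axis: int | str = 0,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Occupancy of {water, connected air, disconnected air} per radius bin.

    ``dry_thickness`` is the local-thickness field of the corresponding dry
    (two-phase) image, so each pore voxel is binned by the size class it
    belongs to before drainage.  Connected air means air clusters spanning
    the sample along ``axis``; the three fractions sum to one in every bin
    that contains pore voxels.
    """
    names = set(multiphase.phase_table.values())
    if "water" not in names or "air" not in names:
        raise ValueError("multiphase image must contain both water and air phases")
    air = multiphase.phase_mask("air")
    water = multiphase.phase_mask("water")
    pore = air | water
    if dry_thickness.shape != multiphase.shape:
        raise ValueError("dry_thickness shape does not match image")
    _, conn_air = axis_connectivity(air, axis=axis, connectivity=connectivity)
    radii = dry_thickness.values[pore]
    edges = np.histogram_bin_edges(radii, bins=bins)
    idx = np.clip(np.digitize(radii, edges) - 1, 0, len(edges) - 2)
    rows = []
    flat_water = water[pore]
    flat_conn = conn_air[pore]
    flat_disc = (air & ~conn_air)[pore]
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            rows.append((edges[b], edges[b + 1], 0, np.nan, np.nan, np.nan))
            continue
        rows.append(
            (
                edges[b],
                edges[b + 1],
                n,
                flat_water[sel].mean(),
                flat_conn[sel].mean(),
                flat_disc[sel].mean(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "radius_lo_um",
            "radius_hi_um",
            "n_voxels",
            "water",
            "connected_air",
            "disconnected_air",
        ],
    )


# ---------------------------------------------------------------------------
# structure thickness with dilation/erosion masking
# ---------------------------------------------------------------------------

def structure_thickness(
    img: VoxelImage,
    dilation_px: int = 0,
    erosion_px: int = 0,
    target: str = "channels",
    bins=32,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Widths of channels or walls inside a dilation/erosion mask.

    The solid phase is dilated by ``dilation_px`` then eroded by
    ``erosion_px`` (Euclidean balls); the resulting mask excludes structures
    near the outer boundary so the histogram reflects internal features
    only.  Widths are ``2 ×`` the distance-transform value on the medial
    axis of the remaining structure, in μm.

    Returns ``(widths_um, histogram)``.
    """
    solid = ~img.pore_mask()
    if dilation_px == 0 and erosion_px == 0:
        region = np.ones(img.shape, bool)
    else:
        dilated = solid if dilation_px == 0 else (
            ndi.distance_transform_edt(~solid) <= dilation_px
        )
        region = dilated if erosion_px == 0 else (
            ndi.distance_transform_edt(dilated) > erosion_px
        )
    if target == "channels":
        struct = img.pore_mask() & region
    elif target == "walls":
        struct = solid & region
    else:
        raise ValueError("target must be 'channels' or 'walls'")
    if not struct.any():
        raise ValueError(
            "mask eliminated the structure entirely; reduce erosion_px"
        )
    dt = ndi.distance_transform_edt(struct)
    skel = skeletonize(struct)
    widths = 2.0 * dt[skel] * img.voxel_size
    if widths.size == 0:  # single-voxel-thin structures have empty skeletons
        widths = 2.0 * np.array([dt[struct].max()]) * img.voxel_size
    counts, edges = np.histogram(widths, bins=bins)
    hist = pd.DataFrame(
        {
            "width_lo_um": edges[:-1],
            "width_hi_um": edges[1:],
            "count": counts,
        }
    )
    return widths, hist


# ---------------------------------------------------------------------------
# bundled report
# ---------------------------------------------------------------------------

@dataclass
class MorphologyReport:
    """Summary morphology of one image: φ, connectivity, PSD, REV."""

    porosity: float
    porosity_slice_sd: float
    connected_fraction: dict[str, float]
    psd: PoreSizeDistributions
    rev: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "porosity": self.porosity,
            "porosity_slice_sd": self.porosity_slice_sd,
            "connected_fraction": self.connected_fraction,
            "psd_mean_um": {
                "per_voxel": self.psd.per_voxel.mean_um,
                "medial_axis": self.psd.medial_axis.mean_um,
            },
            "psd_sd_um": {
                "per_voxel": self.psd.per_voxel.sd_um,
                "medial_axis": self.psd.medial_axis.sd_um,
            },
        }


def morphology_report(
    img: VoxelImage,
    rev_sides=None,
    connectivity: int = 26,
    bins=32,
) -> MorphologyReport:
    """Compute the standard morphology bundle for one image."""
    phi, sd = porosity(img)
    thickness = local_thickness(img)
    psd = pore_size_distribution(img, bins=bins, thickness=thickness)
    conn = {
        name: axis_connectivity(img, axis=i, connectivity=connectivity)[0]
        for i, name in enumerate(("z", "y", "x"))
    }
    if rev_sides is None:
        n = min(img.shape)
        rev_sides = sorted({max(4, int(round(n * f))) for f in
                            (0.25, 0.4, 0.55, 0.7, 0.85, 1.0)})
    rev = rev_curve(img, rev_sides)
    return MorphologyReport(
        porosity=phi,
        porosity_slice_sd=sd,
        connected_fraction=conn,
        psd=psd,
        rev=rev,
    )
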