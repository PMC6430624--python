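"""Reading, writing, cropping and exporting voxel images and fields.

Images travel as multipage TIFF, MHD/RAW or NRRD.  TIFF stores no physical
spacing we can rely on, so every writer also drops a small JSON sidecar
(``<file>.json``) carrying ``voxel_size_um`` and the phase table; MHD and
NRRD additionally carry the spacing in their native headers.  Fields are
exported as legacy ASCII VTK structured points so any standard viewer
(ParaView, VisIt) can load them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .image import ScalarField, VectorField, VoxelImage

__all__ = [
    "read_image",
    "write_image",
    "export_field_vtk",
    "read_field_vtk",
    "crop_subset",
]

_FORMATS = {".tif": "tiff", ".tiff": "tiff", ".mhd": "mhd", ".nrrd": "nrrd"}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower().lstrip(".")
        if fmt not in set(_FORMATS.values()):
            raise ValueError(f"unknown format {format_hint!r}")
        return fmt
    fmt = _FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer format from suffix {path.suffix!r}; "
            "pass format_hint of 'tiff', 'mhd' or 'nrrd'"
        )
    return fmt


def write_image(img: VoxelImage, path: str | Path, format: str | None = None) -> None:
    """Write a labeled image to disk, bit-exact and re-readable.

    A JSON sidecar with the voxel size (μm) and phase table is always
    written next to the image file; for TIFF it is the only carrier of the
    physical spacing.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    labels = img.labels
    # narrowest integer type that holds the labels, for compact files
    if labels.min() >= 0 and labels.max() <= 255:
        data = labels.astype(np.uint8)
    elif labels.min() >= -(2**15) and labels.max() < 2**15:
        data = labels.astype(np.int16)
    else:
        data = labels.astype(np.int32)

    if fmt == "tiff":
        tifffile.imwrite(path, data)
    else:
        sitk_img = sitk.GetImageFromArray(data)
        # SimpleITK spacing is (x, y, z); voxels are isotropic
        sitk_img.SetSpacing((img.voxel_size,) * 3)
        sitk.WriteImage(sitk_img, str(path))

    sidecar = {
        "voxel_size_um": img.voxel_size,
        "phase_table": {str(k): v for k, v in img.phase_table.items()},
        "axes": "zyx",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_image(
    path: str | Path,
    format_hint: str | None = None,
    voxel_size_override: float | None = None,
    phase_table: dict[int, str] | None = None,
    label_map: dict[int, int] | None = None,
    resample_anisotropic: bool = False,
) -> VoxelImage:
    """Read a labeled voxel image from TIFF stack, MHD/RAW or NRRD.

    Parameters
    ----------
    voxel_size_override
        Voxel edge length in μm; required when neither the file header nor
        a JSON sidecar provides one (plain TIFF).
    label_map
        Optional relabeling applied after reading, e.g. ``{0: 1, 255: 0}``
        to turn an 8-bit 0/255 mask into solid/pore labels.
    resample_anisotropic
        Nearest-neighbour resample anisotropic input onto the finest axis
        spacing.  Off by default: anisotropic images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)

    spacing_um: float | None = None
    if fmt == "tiff":
        data = tifffile.imread(path)
    else:
        sitk_img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(sitk_img)
        sp = np.asarray(sitk_img.GetSpacing(), dtype=float)  # (x, y, z)
        if not np.allclose(sp, sp[0], rtol=1e-6):
            if not resample_anisotropic:
                raise ValueError(
                    f"anisotropic voxel spacing {tuple(sp)} in {path.name}; "
                    "pass resample_anisotropic=True to resample"
                )
            data, sp = _resample_nearest(data, sp)
        spacing_um = float(sp[0])

    sidecar_table = None
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if spacing_um is None:
            spacing_um = meta.get("voxel_size_um")
        if meta.get("phase_table"):
            sidecar_table = {int(k): v for k, v in meta["phase_table"].items()}

    if voxel_size_override is not None:
        spacing_um = float(voxel_size_override)
    if spacing_um is None:
        raise ValueError(
            f"{path.name} carries no voxel size; pass voxel_size_override"
        )

    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(
                "non-integer voxel data; segment or threshold before reading "
                "as a labeled image (see morphology.segment_binary)"
            )
    if data.ndim == 2:  # single-slice stack
        data = data[None]

    if label_map is not None:
        out = np.empty_like(data)
        present = np.unique(data)
        unknown = set(present.tolist()) - set(label_map)
        if unknown:
            raise ValueError(f"label_map missing entries for values {sorted(unknown)}")
        for src, dst in label_map.items():
            out[data == src] = dst
        data = out

    table = phase_table or sidecar_table
    if table is None:
        table = _default_table(np.unique(data))
    return VoxelImage(labels=data, voxel_size=spacing_um, phase_table=table)


def _default_table(present: np.ndarray) -> dict[int, str]:
    names = {0: "air", 1: "solid", 2: "water", 3: "clay", 4: "quartz", 5: "hematite"}
    table = {}
    for lab in present.tolist():
        table[int(lab)] = names.get(int(lab), f"phase{lab}")
    return table


def _resample_nearest(data: np.ndarray, spacing_xyz: np.ndarray):
    """Nearest-neighbour resample onto the finest (isotropic) spacing."""
    target = spacing_xyz.min()
    sp_zyx = spacing_xyz[::-1]
    new_shape = np.maximum(1, np.round(np.array(data.shape) * sp_zyx / target)).astype(int)
    idx = [
        np.minimum((np.arange(n) * target / sp).astype(int), s - 1)
        for n, sp, s in zip(new_shape, sp_zyx, data.shape)
    ]
    out = data[np.ix_(idx[0], idx[1], idx[2])]
    return out, np.full(3, target)


def crop_subset(img: VoxelImage, origin, shape) -> VoxelImage:
    """Copy a sub-lattice ``[origin, origin + shape)`` in (z, y, x) order."""
    origin = tuple(int(o) for o in origin)
    shape = tuple(int(s) for s in shape)
    if len(origin) != 3 or len(shape) != 3:
        raise ValueError("origin and shape must each have three components")
    for o, s, n in zip(origin, shape, img.shape):
        if o < 0 or s <= 0 or o + s > n:
            raise IndexError(
                f"crop [{origin}, +{shape}) exceeds image of shape {img.shape}"
            )
    sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
    return VoxelImage(
        labels=img.labels[sl].copy(),
        voxel_size=img.voxel_size,
        phase_table=dict(img.phase_table),
    )


# ---------------------------------------------------------------------------
# legacy VTK structured-points export (fields)
# ---------------------------------------------------------------------------

def export_field_vtk(
    field: ScalarField | VectorField,
    parent: VoxelImage,
    path: str | Path,
    name: str = "field",
    fill_value: float = 0.0,
) -> None:
    """Export a lattice field as a legacy ASCII VTK structured-points file.

    Physical spacing equals the parent's voxel size; voxels outside the
    field's support are written as ``fill_value``.
    """
    path = Path(path)
    if field.shape != parent.shape:
        raise ValueError(
            f"field shape {field.shape} does not match image shape {parent.shape}"
        )
    values = field.values.astype(float)
    if field.support is not None:
        values = values.copy()
        values[~field.support] = fill_value
    nz, ny, nx = parent.shape
    h = parent.voxel_size
    lines = [
        "# vtk DataFile Version 3.0",
        f"nestpore field: {name} [{field.unit}]",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN 0 0 0",
        f"SPACING {h:.9g} {h:.9g} {h:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    if isinstance(field, VectorField):
        # VTK expects (x, y, z) component order; ours is (z, y, x)
        comp = values[..., ::-1].reshape(-1, 3)
        lines.append(f"VECTORS {name} double")
        body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in comp)
    else:
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        body = "\n".join(f"{v:.9g}" for v in values.ravel())
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_field_vtk(path: str | Path):
    """Read back a file written by :func:`export_field_vtk`.

    Returns ``(field, spacing_um)``.  Only the structured-points layout this
    package writes is supported; it exists so exports can be verified
    without a full VTK dependency.
    """
    text = Path(path).read_text().splitlines()
    dims = spacing = None
    kind = None
    data_start = None
    name = ""
    for i, line in enumerate(text):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "DIMENSIONS":
            dims = tuple(int(t) for t in tok[1:4])  # (nx, ny, nz)
        elif tok[0] == "SPACING":
            spacing = float(tok[1])
        elif tok[0] == "SCALARS":
            kind, name = "scalar", tok[1]
        elif tok[0] == "VECTORS":
            kind, name = "vector", tok[1]
            data_start = i + 1
            break
        elif tok[0] == "LOOKUP_TABLE":
            data_start = i + 1
            break
    if dims is None or kind is None or data_start is None:
        raise ValueError(f"{path}: not a nestpore VTK structured-points file")
    nx, ny, nz = dims
    flat = np.array(" ".join(text[data_start:]).split(), dtype=float)
    if kind == "scalar":
        field = ScalarField(values=flat.reshape(nz, ny, nx), unit="")
    else:
        vec = flat.reshape(nz, ny, nx, 3)[..., ::-1]  # back to (z, y, x)
        field = VectorField(values=vec, unit="")
    return field, spacing
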