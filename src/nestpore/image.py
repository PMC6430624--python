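"""Labeled voxel images and lattice-aligned fields.

A :class:`VoxelImage` is the carrier passed between every stage of the
pipeline: a 3-D lattice of integer phase labels on an isotropic grid with a
physical voxel edge length in micrometres.  Axes are always ordered
``(z, y, x)`` and voxel ``i`` along an axis is the cell ``[i, i+1)`` in
lattice units, so the physical centre of a voxel is ``(index + 0.5) *
voxel_size``.  One fixed convention avoids silent transposition bugs between
generators, morphology and the transport solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AXES",
    "axis_index",
    "VoxelImage",
    "ScalarField",
    "VectorField",
    "PHASE_AIR",
    "PHASE_SOLID",
    "PHASE_WATER",
]

#: axis-name convention; index 0 is the slowest-varying array axis
AXES = ("z", "y", "x")

# canonical label values used by the synthetic generators; readers may map
# arbitrary labels as long as the phase_table names them
PHASE_AIR = 0
PHASE_SOLID = 1
PHASE_WATER = 2

#: phase names understood by downstream stages
KNOWN_PHASES = frozenset(
    {"air", "water", "solid", "quartz", "clay", "hematite", "metallic"}
)

#: phases that count as void space when measuring porosity of a dry image
PORE_PHASES = frozenset({"air"})

#: phases that count as void space in a drained (air + water) image
VOID_PHASES = frozenset({"air", "water"})


def axis_index(axis: int | str) -> int:
    """Resolve an axis given by name ('z','y','x') or integer index."""
    if isinstance(axis, str):
        try:
            return AXES.index(axis.lower())
        except ValueError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}") from None
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index {axis} out of range for a 3-D image")
    return axis


@dataclass
class VoxelImage:
    """3-D integer phase-label lattice with isotropic voxel size.

    Parameters
    ----------
    labels
        ``(nz, ny, nx)`` integer array of phase labels.
    voxel_size
        Edge length of a (cubic) voxel in micrometres.
    phase_table
        Mapping from label value to phase name.  Every label present in
        ``labels`` must have an entry.
    """

    labels: np.ndarray
    voxel_size: float
    phase_table: Mapping[int, str] = field(
        default_factory=lambda: {PHASE_AIR: "air", PHASE_SOLID: "solid"}
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError(
                f"labels must be a 3-D array with positive dimensions, "
                f"got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(
                "labels must be integer phase labels; threshold or segment "
                "grayscale data first"
            )
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.phase_table = {int(k): str(v) for k, v in self.phase_table.items()}
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.phase_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from phase_table")

    # -- basic queries -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def labels_for(self, phase: str) -> list[int]:
        return [lab for lab, name in self.phase_table.items() if name == phase]

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean mask of voxels whose label maps to ``phase``."""
        labs = self.labels_for(phase)
        if not labs:
            raise ValueError(f"phase {phase!r} not present in phase_table")
        return np.isin(self.labels, labs)

    def pore_mask(self, phases: frozenset[str] | set[str] = PORE_PHASES) -> np.ndarray:
        """Boolean mask of void space (default: the 'air' phase)."""
        labs = [lab for lab, name in self.phase_table.items() if name in phases]
        return np.isin(self.labels, labs)

    def phase_fraction(self, phase: str) -> float:
        return float(self.phase_mask(phase).mean())

    def with_labels(self, labels: np.ndarray, phase_table=None) -> "VoxelImage":
        """New image sharing voxel size, with different labels (and table)."""
        return VoxelImage(
            labels=labels,
            voxel_size=self.voxel_size,
            phase_table=self.phase_table if phase_table is None else phase_table,
        )

    def copy(self) -> "VoxelImage":
        return replace(self, labels=self.labels.copy(), phase_table=dict(self.phase_table))

    def __eq__(self, other: object) -> bool:  # lattice + metadata identity
        if not isinstance(other, VoxelImage):
            return NotImplemented
        return (
            self.labels.shape == other.labels.shape
            and bool(np.array_equal(self.labels, other.labels))
            and np.isclose(self.voxel_size, other.voxel_size, rtol=1e-9)
            and self.phase_table == other.phase_table
        )


@dataclass
class ScalarField:
    """Scalar values on the lattice of a parent :class:`VoxelImage`.

    ``values`` has the parent's ``(nz, ny, nx)`` shape.  Voxels outside the
    declared support phase carry no physical meaning; ``support`` (boolean,
    optional) marks where the field is defined.
    """

    values: np.ndarray
    unit: str = ""
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarField values must be 3-D")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape:
                raise ValueError("support mask shape must match values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def defined_values(self) -> np.ndarray:
        if self.support is None:
            return self.values.ravel()
        return self.values[self.support]


@dataclass
class VectorField:
    """Per-voxel 3-vectors ``(..., 3)`` ordered (z, y, x) like the axes."""

    values: np.ndarray
    unit: str = ""
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[-1] != 3:
            raise ValueError("VectorField values must have shape (nz, ny, nx, 3)")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape[:3]:
                raise ValueError("support mask shape must match the lattice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> ScalarField:
        return ScalarField(
            values=np.linalg.norm(self.values, axis=-1),
            unit=self.unit,
            support=self.support,
        )
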