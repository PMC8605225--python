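"""Voxel lattice and binary structure masks.

A :class:`GridSpec` is a regular, axis-aligned 3D lattice with anisotropic
physical spacing in millimetres.  Indices are 0-based, slice ranges are
half-open ``[lo, hi)``, and all physical coordinates refer to voxel
*centers*: the center of voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.

One axis is designated *superior*: increasing index along it moves in the
cranial direction (the conventional feet-to-head ordering of an axial MR
stack).  Cranio-caudal cropping and the inferior-half subsets are defined
along this axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError

#: Tolerance (mm) within which two grids count as identical.
GRID_TOL_MM = 1e-4

# Canonical structure labels of the study.
PROSTATE = "prostate"
NVB_LEFT = "NVB_left"
NVB_RIGHT = "NVB_right"
IPA_LEFT = "IPA_left"
IPA_RIGHT = "IPA_right"

BASE_STRUCTURES = (PROSTATE, IPA_LEFT, IPA_RIGHT, NVB_LEFT, NVB_RIGHT)

#: Suffix appended to a structure label for its derived inferior-half subset.
INFERIOR_HALF_SUFFIX = "__inf_half"
#: Suffix for a mask written back after cranio-caudal harmonization.
HARMONIZED_SUFFIX = "__harmonized"


def inferior_half_label(structure: str) -> str:
    return structure + INFERIOR_HALF_SUFFIX


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel lattice with physical spacing.

    Parameters
    ----------
    dims
        Number of voxels along each axis, all >= 1.
    spacing
        Voxel spacing (dx, dy, dz) in mm, all > 0.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    superior_axis
        Axis index whose increasing coordinate points cranially.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    superior_axis: int = 2

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if self.superior_axis not in (0, 1, 2):
            raise ValueError("superior_axis must be 0, 1 or 2")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def slice_spacing_mm(self) -> float:
        """Spacing along the superior axis."""
        return self.spacing[self.superior_axis]

    @property
    def n_slices(self) -> int:
        return self.dims[self.superior_axis]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of all voxels along ``axis``."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def slice_coords(self) -> np.ndarray:
        """Center coordinates along the superior axis, inferior to superior."""
        return self.axis_coords(self.superior_axis)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical-coordinate arrays, one per axis."""
        shapes = [[1, 1, 1] for _ in range(3)]
        out = []
        for ax in range(3):
            shapes[ax][ax] = self.dims[ax]
            out.append(self.axis_coords(ax).reshape(shapes[ax]))
        return tuple(out)

    def matches(self, other: "GridSpec", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.dims == other.dims
            and self.superior_axis == other.superior_axis
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def require_match(self, other: "GridSpec", context: str = "") -> None:
        if not self.matches(other):
            where = f" ({context})" if context else ""
            raise GridMismatchError(
                f"grids differ{where}: {self} vs {other}"
            )


@dataclass
class StructureMask:
    """One rater's binary contour of one structure on a :class:`GridSpec`."""

    grid: GridSpec
    occupancy: np.ndarray
    patient_id: str = ""
    rater_id: str = ""
    structure: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.dims:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        self.occupancy = occ.astype(bool, copy=False)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def with_occupancy(self, occ: np.ndarray) -> "StructureMask":
        """Copy of this mask with a new occupancy field (metadata kept)."""
        return StructureMask(
            grid=self.grid,
            occupancy=occ,
            patient_id=self.patient_id,
            rater_id=self.rater_id,
            structure=self.structure,
        )

    def relabeled(self, structure: str) -> "StructureMask":
        return StructureMask(
            grid=self.grid,
            occupancy=self.occupancy,
            patient_id=self.patient_id,
            rater_id=self.rater_id,
            structure=structure,
        )
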