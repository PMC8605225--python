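"""Cranio-caudal harmonization of multi-rater contours.

Tubular pelvic structures (neurovascular bundle, internal pudendal artery)
continue far superior to the region of clinical interest, and raters stop
contouring at different levels.  To keep longitudinal extent differences
from swamping the agreement metrics, all raters' contours of a structure
are cropped to their *maximal common superior-inferior extent* — the
intersection of the per-rater slice intervals — before comparison.  From
the harmonized extent of the neurovascular bundle, the *exact inferior
half* (approximately prostate midgland to apex) is derived as a subset.

Conventions
-----------
* An interval is slice-center based: ``inf_mm``/``sup_mm`` are the center
  coordinates of its lowest/highest slice.  The reported "distance between
  superior and inferior border" spans whole slices, i.e. equals
  (number of slices) x slice spacing (outer border to outer border).
* With an odd slice count the inferior half includes the middle slice,
  erring toward the clinically critical apex-side region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, NoLongitudinalOverlapError
from .grid import StructureMask

_EPS_MM = 1e-6


@dataclass(frozen=True)
class LongitudinalInterval:
    """Closed slice-center interval [inf_mm, sup_mm] along the superior axis."""

    inf_mm: float
    sup_mm: float

    def __post_init__(self) -> None:
        if self.sup_mm < self.inf_mm - _EPS_MM:
            raise ValueError(f"sup_mm {self.sup_mm} < inf_mm {self.inf_mm}")

    def n_slices(self, slice_spacing_mm: float) -> int:
        return int(round((self.sup_mm - self.inf_mm) / slice_spacing_mm)) + 1

    def border_distance_mm(self, slice_spacing_mm: float) -> float:
        """Outer-border to outer-border length: n_slices x slice spacing."""
        return self.n_slices(slice_spacing_mm) * slice_spacing_mm

    def contains(self, z_mm: float) -> bool:
        return self.inf_mm - _EPS_MM <= z_mm <= self.sup_mm + _EPS_MM


@dataclass
class HarmonizedSet:
    """All raters' masks of one structure cropped to a common extent."""

    structure: str
    patient_id: str
    masks: dict[str, StructureMask]  # rater id -> cropped mask
    interval: LongitudinalInterval


def _occupied_slices(mask: StructureMask) -> np.ndarray:
    other_axes = tuple(ax for ax in range(3) if ax != mask.grid.superior_axis)
    return np.flatnonzero(mask.occupancy.any(axis=other_axes))


def longitudinal_extent(mask: StructureMask) -> LongitudinalInterval:
    """Interval spanning the lowest and highest occupied slice (gaps ignored)."""
    if mask.is_empty:
        raise EmptyMaskError(
            f"extent of empty mask (patient={mask.patient_id!r} "
            f"structure={mask.structure!r})"
        )
    occ = _occupied_slices(mask)
    zc = mask.grid.slice_coords()
    return LongitudinalInterval(inf_mm=float(zc[occ[0]]), sup_mm=float(zc[occ[-1]]))


def common_extent(masks: list[StructureMask]) -> LongitudinalInterval:
    """Intersection of all raters' longitudinal extents.

    Raises :class:`NoLongitudinalOverlapError` when the raters share no
    slice, naming the offending patient/structure.
    """
    if len(masks) < 2:
        raise ValueError("common extent needs >= 2 masks")
    grid = masks[0].grid
    for m in masks[1:]:
        grid.require_match(m.grid, "common_extent")
    extents = [longitudinal_extent(m) for m in masks]
    inf = max(e.inf_mm for e in extents)
    sup = min(e.sup_mm for e in extents)
    if sup < inf - _EPS_MM:
        m = masks[0]
        raise NoLongitudinalOverlapError(
            f"no longitudinal overlap (patient={m.patient_id!r} "
            f"structure={m.structure!r}): intersection [{inf}, {sup}] mm empty"
        )
    return LongitudinalInterval(inf_mm=inf, sup_mm=sup)


def crop_to_interval(
    mask: StructureMask, interval: LongitudinalInterval
) -> StructureMask:
    """Clear occupancy on slices whose centers fall outside the interval.

    In-plane occupancy is untouched.  Raises :class:`EmptyMaskError` if the
    rater had no voxels inside the interval.
    """
    zc = mask.grid.slice_coords()
    keep = (zc >= interval.inf_mm - _EPS_MM) & (zc <= interval.sup_mm + _EPS_MM)
    shape = [1, 1, 1]
    shape[mask.grid.superior_axis] = len(keep)
    occ = mask.occupancy & keep.reshape(shape)
    if not occ.any():
        raise EmptyMaskError(
            f"crop left no voxels (patient={mask.patient_id!r} "
            f"rater={mask.rater_id!r} structure={mask.structure!r})"
        )
    return mask.with_occupancy(occ)


def inferior_half(
    interval: LongitudinalInterval, slice_spacing_mm: float
) -> LongitudinalInterval:
    """Sub-interval of slices at or below the physical midpoint.

    With an even slice count this is exactly the lower half; with an odd
    count the middle slice (whose center sits on the midpoint) is included.
    """
    n = interval.n_slices(slice_spacing_mm)
    n_inf = (n + 1) // 2
    return LongitudinalInterval(
        inf_mm=interval.inf_mm,
        sup_mm=interval.inf_mm + (n_inf - 1) * slice_spacing_mm,
    )


def harmonize(masks: list[StructureMask]) -> HarmonizedSet:
    """Crop all raters' masks of one structure to their common extent."""
    interval = common_extent(masks)
    cropped = {m.rater_id: crop_to_interval(m, interval) for m in masks}
    first = masks[0]
    return HarmonizedSet(
        structure=first.structure,
        patient_id=first.patient_id,
        masks=cropped,
        interval=interval,
    )


def inferior_half_set(hset: HarmonizedSet) -> HarmonizedSet:
    """Derive the inferior-half subset of an already-harmonized set."""
    spacing = next(iter(hset.masks.values())).grid.slice_spacing_mm
    sub = inferior_half(hset.interval, spacing)
    from .grid import inferior_half_label

    cropped = {
        r: crop_to_interval(m, sub).relabeled(inferior_half_label(m.structure))
        for r, m in hset.masks.items()
    }
    return HarmonizedSet(
        structure=inferior_half_label(hset.structure),
        patient_id=hset.patient_id,
        masks=cropped,
        interval=sub,
    )
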