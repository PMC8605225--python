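"""Reading and writing structure masks, slice-polygon contours and manifests.

Volumetric masks travel as NIfTI (read/write) or NRRD (read-only).  Clinical
contours drawn as closed planar polygons per axial slice can be rasterized
onto a grid, and a cohort manifest (JSON or CSV) maps every
(patient, rater, structure) triple to a mask file or marks it missing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import (
    GridMismatchError,
    ManifestError,
    MissingSpacingError,
    PolygonError,
    UnsupportedFormatError,
)
from .grid import GRID_TOL_MM, GridSpec, StructureMask

_NIFTI_EXTS = (".nii", ".nii.gz")
_NRRD_EXTS = (".nrrd", ".nhdr")


def _has_ext(path: Path, exts: tuple[str, ...]) -> bool:
    name = path.name.lower()
    return any(name.endswith(e) for e in exts)


def write_mask(mask: StructureMask, path: str | Path) -> Path:
    """Write a mask as NIfTI (uint8, 0/1).  Lossless round trip with read_mask.

    NRRD output is deliberately not offered; NRRD support is read-only.
    """
    import nibabel as nib

    path = Path(path)
    if not _has_ext(path, _NIFTI_EXTS):
        raise UnsupportedFormatError(
            f"can only write NIfTI (.nii/.nii.gz), got {path.name!r}"
        )
    g = mask.grid
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = g.spacing
    affine[:3, 3] = g.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.header.set_zooms(g.spacing)
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, GridSpec]:
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 3:
        raise UnsupportedFormatError(f"{path.name}: expected a 3D volume, got {img.ndim}D")
    # nibabel silently repairs zero pixdims to 1.0 on load; inspect the raw
    # on-disk header so absent spacing metadata is reported, not invented
    try:
        from nibabel.openers import ImageOpener

        with ImageOpener(str(path), "rb") as fh:
            raw = nib.Nifti1Header.from_fileobj(fh, check=False)
        raw_zooms = tuple(float(z) for z in raw["pixdim"][1:4])
    except Exception:
        raw_zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(z) or z <= 0 for z in raw_zooms):
        raise MissingSpacingError(
            f"{path.name}: missing spacing (non-positive pixdim {raw_zooms})"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine, dtype=float)
    origin = tuple(float(v) for v in affine[:3, 3])
    arr = np.asanyarray(img.dataobj)
    grid = GridSpec(dims=arr.shape, spacing=zooms, origin=origin)
    return arr, grid


def _read_nrrd(path: Path) -> tuple[np.ndarray, GridSpec]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise UnsupportedFormatError(
            f"{path.name}: expected a 3D volume, got {img.GetDimension()}D"
        )
    spacing = tuple(float(s) for s in img.GetSpacing())
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise MissingSpacingError(f"{path.name}: missing spacing ({spacing})")
    origin = tuple(float(o) for o in img.GetOrigin())
    # sitk returns (z, y, x); transpose back to (x, y, z)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = GridSpec(dims=arr.shape, spacing=spacing, origin=origin)
    return arr, grid


def read_mask(
    path: str | Path,
    expected_grid: GridSpec | None = None,
    **metadata: str,
) -> StructureMask:
    """Read a volumetric mask; any nonzero voxel counts as occupied.

    Raises :class:`UnsupportedFormatError`, :class:`MissingSpacingError`
    or :class:`GridMismatchError` distinctly.  ``metadata`` may carry
    patient_id/rater_id/structure labels onto the returned mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _has_ext(path, _NIFTI_EXTS):
        arr, grid = _read_nifti(path)
    elif _has_ext(path, _NRRD_EXTS):
        arr, grid = _read_nrrd(path)
    else:
        raise UnsupportedFormatError(
            f"unsupported mask format {path.name!r} (expected .nii/.nii.gz/.nrrd/.nhdr)"
        )
    if expected_grid is not None and not grid.matches(expected_grid, GRID_TOL_MM):
        raise GridMismatchError(
            f"{path.name}: grid {grid} does not match expected {expected_grid}"
        )
    if expected_grid is not None:
        grid = expected_grid
    return StructureMask(grid=grid, occupancy=arr != 0, **metadata)


# ---------------------------------------------------------------------------
# Slice-polygon rasterization
# ---------------------------------------------------------------------------

#: One closed polygon on one axial slice: (slice coordinate in mm along the
#: superior axis, vertex array of shape (n, 2) in in-plane mm coordinates).
SlicePolygon = tuple[float, np.ndarray]


def _check_simple(verts: np.ndarray) -> None:
    from shapely.geometry import LinearRing

    if len(verts) < 3:
        raise PolygonError(f"polygon needs >= 3 vertices, got {len(verts)}")
    ring = LinearRing(verts)
    if not ring.is_simple or not ring.is_valid:
        raise PolygonError("self-intersecting polygon")


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd crossing test with a half-open boundary convention.

    A rightward ray from each point counts edge crossings with the half-open
    rule ``(y0 > py) != (y1 > py)`` and strict ``px < x_intersect``, so a
    point lying exactly on a shared edge belongs to exactly one of two
    abutting polygons (top-left rule) and counts are deterministic.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        if y0 == y1:
            continue
        cond = (y0 > py) != (y1 > py)
        xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= cond & (px < xint)
    return inside


def rasterize_slice_polygons(
    polygons: Iterable[SlicePolygon],
    grid: GridSpec,
    **metadata: str,
) -> StructureMask:
    """Rasterize per-slice closed polygons onto a grid.

    A voxel is occupied iff its center lies inside an odd number of that
    slice's polygons (even-odd rule, so nested polygons cut holes).  Each
    polygon's plane must coincide with a slice center within half a slice
    spacing; slices without polygons stay empty.
    """
    sup = grid.superior_axis
    in_plane = [ax for ax in range(3) if ax != sup]
    zc = grid.slice_coords()
    dz = grid.slice_spacing_mm

    xs = grid.axis_coords(in_plane[0])
    ys = grid.axis_coords(in_plane[1])
    px, py = np.meshgrid(xs, ys, indexing="ij")

    occ = np.zeros(grid.dims, dtype=bool)
    for z_mm, verts in polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise PolygonError("polygon vertices must have shape (n, 2)")
        # drop an explicitly repeated closing vertex
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        _check_simple(verts)
        k = int(np.argmin(np.abs(zc - z_mm)))
        if abs(zc[k] - z_mm) > dz / 2 + 1e-9:
            raise PolygonError(
                f"polygon plane z={z_mm} mm not aligned with any slice "
                f"(nearest center {zc[k]} mm, spacing {dz} mm)"
            )
        sl: list[slice | int] = [slice(None)] * 3
        sl[sup] = k
        occ[tuple(sl)] ^= _points_in_polygon(px, py, verts)
    return StructureMask(grid=grid, occupancy=occ, **metadata)


def read_polygon_csv(path: str | Path) -> dict[str, list[SlicePolygon]]:
    """Read slice polygons from CSV with columns
    structure, slice_z_mm, polygon_index, vertex_index, x_mm, y_mm
    (polygon_index optional; defaults to one polygon per slice).

    Returns structure label -> list of (slice_z_mm, vertices).
    """
    rows: dict[tuple[str, float, int], list[tuple[int, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (
                rec["structure"],
                float(rec["slice_z_mm"]),
                int(rec.get("polygon_index", 0) or 0),
            )
            rows.setdefault(key, []).append(
                (int(rec["vertex_index"]), float(rec["x_mm"]), float(rec["y_mm"]))
            )
    out: dict[str, list[SlicePolygon]] = {}
    for (structure, z_mm, _poly), verts in sorted(rows.items()):
        verts.sort()
        arr = np.array([(x, y) for _, x, y in verts], dtype=float)
        out.setdefault(structure, []).append((z_mm, arr))
    return out


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Maps every (patient, rater, structure) triple to a mask file.

    ``entries`` values may be ``None`` for a triple explicitly marked
    missing; every triple in the cross product must appear.
    """

    patients: list[str]
    raters: list[str]
    structures: list[str]
    entries: dict[tuple[str, str, str], Path | None] = field(default_factory=dict)
    root: Path | None = None

    def validate(self) -> None:
        for p in self.patients:
            for r in self.raters:
                for s in self.structures:
                    if (p, r, s) not in self.entries:
                        raise ManifestError(
                            f"manifest has no entry (not even 'missing') for "
                            f"patient={p} rater={r} structure={s}"
                        )

    def path_for(self, patient: str, rater: str, structure: str) -> Path | None:
        p = self.entries[(patient, rater, structure)]
        if p is None:
            return None
        if self.root is not None and not p.is_absolute():
            return self.root / p
        return p

    def load(self, patient: str, rater: str, structure: str) -> StructureMask | None:
        path = self.path_for(patient, rater, structure)
        if path is None:
            return None
        return read_mask(
            path, patient_id=patient, rater_id=rater, structure=structure
        )


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    masks = []
    for (p, r, s), loc in sorted(manifest.entries.items()):
        masks.append(
            {
                "patient_id": p,
                "rater_id": r,
                "structure": s,
                "path": None if loc is None else str(loc),
            }
        )
    payload = {
        "patients": manifest.patients,
        "raters": manifest.raters,
        "structures": manifest.structures,
        "masks": masks,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a manifest from JSON ({patients, raters, structures, masks}) or
    CSV (columns patient_id, rater_id, structure, path).  Relative mask
    paths resolve against the manifest's directory."""
    path = Path(path)
    root = path.parent
    entries: dict[tuple[str, str, str], Path | None] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        patients = list(payload["patients"])
        raters = list(payload["raters"])
        structures = list(payload["structures"])
        for rec in payload["masks"]:
            loc = rec.get("path")
            entries[(rec["patient_id"], rec["rater_id"], rec["structure"])] = (
                None if loc in (None, "") else Path(loc)
            )
    elif path.suffix.lower() == ".csv":
        patients_seen: dict[str, None] = {}
        raters_seen: dict[str, None] = {}
        structures_seen: dict[str, None] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                p, r, s = rec["patient_id"], rec["rater_id"], rec["structure"]
                patients_seen[p] = raters_seen[r] = structures_seen[s] = None
                loc = rec.get("path", "")
                entries[(p, r, s)] = None if loc in (None, "") else Path(loc)
        patients = list(patients_seen)
        raters = list(raters_seen)
        structures = list(structures_seen)
    else:
        raise ManifestError(f"unsupported manifest format {path.suffix!r}")
    manifest = CohortManifest(
        patients=patients, raters=raters, structures=structures,
        entries=entries, root=root,
    )
    manifest.validate()
    return manifest
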