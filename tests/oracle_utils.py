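"""Independent brute-force oracles for the surface-distance metrics.

Deliberately naive: boundary voxels by an explicit 6-neighbor scan in
Python loops, distances by all-pairs Euclidean search.  Only ever run on
tiny masks; the implementation under test must match these to 1e-9 mm.
"""

import numpy as np


def oracle_surface_points(mask):
    """Centers (mm) of occupied voxels with >=1 unoccupied face neighbor."""
    occ = mask.occupancy
    nx, ny, nz = occ.shape
    spacing = np.asarray(mask.grid.spacing)
    origin = np.asarray(mask.grid.origin)
    pts = []
    for i, j, k in np.argwhere(occ):
        boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            a, b, c = i + di, j + dj, k + dk
            if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not occ[a, b, c]:
                boundary = True
                break
        if boundary:
            pts.append(origin + np.array([i, j, k]) * spacing)
    return np.array(pts)


def _directed_all_pairs(pa, pb):
    diffs = pa[:, None, :] - pb[None, :, :]
    return np.sqrt((diffs**2).sum(axis=2)).min(axis=1)


def oracle_surface_distances(a, b, asd_mode="pooled"):
    """(avg surface distance, Hausdorff) by exhaustive all-pairs search."""
    pa = oracle_surface_points(a)
    pb = oracle_surface_points(b)
    dab = _directed_all_pairs(pa, pb)
    dba = _directed_all_pairs(pb, pa)
    if asd_mode == "pooled":
        asd = float(np.concatenate([dab, dba]).mean())
    else:
        asd = float((dab.mean() + dba.mean()) / 2.0)
    hd = float(max(dab.max(), dba.max()))
    return asd, hd
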