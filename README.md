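# concord

Interrater contour-agreement analysis for pelvic radiotherapy structures,
with a synthetic phantom-cohort test bed.

When several radiation oncologists independently contour the same
structures — here the prostate, the neurovascular bundles (NVB) and the
internal pudendal arteries (IPA), the structures-to-spare in
neurovascular-sparing prostate radiotherapy — their contours disagree, and
that disagreement must be quantified before the structures can be used
clinically. `concord` implements the full analysis:

* **Volumetric overlap.** For masks $A$, $B$ of two raters, the Dice
  similarity coefficient $\mathrm{DSC} = 2|A \cap B| / (|A| + |B|)$
  (0 = no overlap, 1 = complete overlap).
* **Surface distances**, computed symmetrically in 3D between boundary
  voxel centers in physical mm. With $d(p, S)$ the Euclidean distance from
  point $p$ to the nearest point of surface $S$, the *average surface
  distance* is the mean of the pooled multiset
  $\{d(p, S_B) : p \in S_A\} \cup \{d(q, S_A) : q \in S_B\}$ and the
  *Hausdorff distance* is
  $\max(\max_{p \in S_A} d(p, S_B),\; \max_{q \in S_B} d(q, S_A))$.
* **Cranio-caudal harmonization.** Tubular structures continue far superior
  to the clinically relevant region and raters stop at different levels, so
  before comparison all raters' contours of a structure are cropped to
  their maximal common superior–inferior extent, per structure and patient.
  From the harmonized NVB a subset of its exact inferior half
  (≈ prostate midgland to apex, where dose-sparing conflict is greatest)
  is derived.
* **Study pipeline.** Metrics are computed for all $\binom{n}{2}$ rater
  pairs (4 raters → 6 pairs per patient per structure) and summarized as
  median (IQR) in a report table, alongside per-rater volumes (cc) and the
  per-patient harmonized border distance (mm).
* **Synthetic cohort.** Because clinical contours are rarely shareable, a
  seeded generator builds phantom pelvic anatomies (ellipsoidal prostate,
  tubular NVB/IPA) and simulates raters through a noise model with smooth
  random surface displacement, systematic margin bias, cranio-caudal extent
  jitter, and extra divergence toward the superior end where the NVB is
  hardest to see on MRI.

## Worked example

```python
import numpy as np
import concord as cc

grid = cc.GridSpec(dims=(25, 15, 15), spacing=(1.0, 1.0, 1.0))
a = np.zeros(grid.dims, dtype=bool); a[0:10, 2:12, 2:12] = True
b = np.zeros(grid.dims, dtype=bool); b[5:15, 2:12, 2:12] = True
r1 = cc.StructureMask(grid=grid, occupancy=a, rater_id="r1")
r2 = cc.StructureMask(grid=grid, occupancy=b, rater_id="r2")

print(f"Dice                 : {cc.dice(r1, r2):.3f}")
print(f"avg surface distance : {cc.avg_surface_distance(r1, r2):.3f} mm")
print(f"Hausdorff distance   : {cc.hausdorff(r1, r2):.3f} mm")
```

prints

```
Dice                 : 0.500
avg surface distance : 2.008 mm
Hausdorff distance   : 5.000 mm
```

Two 1 cc boxes shifted by 5 mm overlap in half their volume (Dice 0.5);
the worst-case boundary discrepancy equals the translation (Hausdorff
5 mm) while the average surface distance stays much smaller because most
of the two surfaces lie close together — the reason overlap and distance
metrics are reported side by side.

The `examples/` directory contains short narrative scripts for each
capability: pair metrics on hand-built masks, harmonization plus the
inferior-half subset, and an end-to-end synthetic cohort producing the
median (IQR) report table.

## Command line

```sh
concord synth --patients 15 --raters 4 --seed 42 --out cohort_dir
concord run --manifest cohort_dir/manifest.json --out report_dir
```

`run` writes `pair_metrics.csv` (one row per patient × structure × rater
pair), `summary_table.{csv,json,txt}`, `run_log.txt` and
`config_used.json`; two runs over the same cohort are byte-identical.
Masks travel as NIfTI (NRRD is read-only); per-slice closed polygons in a
CSV can be rasterized onto a grid; the cohort manifest is JSON or CSV.

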