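# Methods

## Data model

Masks live on a regular axis-aligned lattice (`GridSpec`) with anisotropic
spacing in mm. Indices are 0-based, slice ranges half-open, and all
physical coordinates refer to voxel centers: voxel $(i,j,k)$ sits at
`origin + (i,j,k) * spacing`. One axis (default the third) is *superior*:
increasing index is cranial, the conventional feet-to-head ordering of an
axial MR stack. The orientation is configurable per grid but never
inferred from file metadata beyond the affine's translation and zooms;
non-axis-aligned volumes are rejected rather than resampled.

Rasterization of per-slice closed polygons uses the even–odd rule on voxel
centers with a half-open (top-left) boundary convention: a center exactly
on a shared edge belongs to exactly one of two abutting polygons, so
counts are deterministic and adjacent contours never double-cover.

## Agreement metrics

The surface of a mask is the set of occupied voxels with at least one of
their six face neighbors unoccupied (out-of-grid counts as unoccupied),
represented by their physical centers. Distances are point-to-point
Euclidean mm between voxel centers. This voxel-center convention is the
dominant published one and, unlike mesh-based surfaces, is exactly
checkable against an exhaustive all-pairs oracle; the test suite asserts
agreement to 1e-9 mm on random masks. The production path evaluates
nearest-surface distances through `scipy.ndimage.distance_transform_edt`
(exact Euclidean, `sampling=spacing`), cropped to the padded bounding box
of the masks' union, and computes each rater's surface and distance map
once per structure so four raters' six pairs reuse them.

Two reductions of the symmetric average exist in the literature. The
default pools both directed distance multisets and takes one mean
(surface-size-weighted); `mean-of-means` averages the two directed means.
Both are implemented; the pooled form is the default and the summation is
ordered so the result is exactly symmetric in the argument order.
Hausdorff is the exact maximum by default; a percentile variant (e.g. 95)
exists but is off, since the quantity reported here is the *maximum*
surface distance.

Degenerate inputs are errors, not conventions: Dice of two empty masks and
surface distances involving any empty mask raise, as does any grid
mismatch (tolerance 1e-4 mm on spacing and origin).

## Harmonization

For each patient and structure independently, the common extent is the
intersection of the raters' longitudinal extents (lowest to highest
occupied slice, internal gaps ignored); each rater's mask is cropped to
it. An empty intersection is an error naming the patient and structure. A
structure's reported "distance between superior and inferior border"
spans whole slices: $n_\text{slices} \times$ slice spacing,
outer border to outer border, which makes all reported border distances
integer multiples of the slice spacing.

The inferior half of a harmonized interval keeps the slices whose centers
lie at or below the physical midpoint; with an odd slice count the middle
slice is included, erring toward the clinically critical apex-side region.
The prostate is never cropped and gets no inferior-half subset — its
border-distance cell renders NA. Harmonization is idempotent, and only
cranio-caudal cropping is ever applied; no in-plane trimming or
registration.

## Study pipeline

Per patient and structure the pipeline computes all unordered rater-pair
metrics (harmonized except for the prostate), the per-patient border
distance, and per-rater volumes. Volumes of cropped structures are
reported **post-harmonization** by default (switchable to pre-), since
the analyzed contours are the cropped ones; inferior-half volumes are
always post-crop. Summaries are median with IQR; quartiles use linear
interpolation between order statistics, the common default of mainstream
statistics software, pinned so numbers are reproducible. Report values
are rounded to 2 decimals; no hypothesis tests are performed — the study
is descriptive.

Failures (missing mask, no longitudinal overlap, a rater emptied by the
crop) are logged per affected pair and skipped, so per structure
records + logged failures $= \binom{n_\text{raters}}{2} \times
n_\text{patients}$; a run aborts only if failures exceed a configurable
fraction (default 50%). Reports avoid timestamps and use fixed float
formatting, so two runs over the same cohort are byte-identical.

## Synthetic cohort

The phantom emulates the geometry that makes this analysis hard: a large
ellipsoidal prostate (~44 cc, semi-axes 25 × 21 × 20 mm), two NVB tubes
(r = 6.5 mm) hugging its dorsolateral surface with a gentle dorsal bow,
spanning slightly beyond the prostate cranio-caudally, and two thinner
IPA tubes (r = 3.4 mm) further lateral with a ventral turn toward the
inferior end. The default lattice is 120 × 120 mm in-plane at 1 mm with
64 slices of 2 mm — 2 mm slice thickness makes the harmonized border
distances even-mm values, as in clinical practice. Structure placement
keeps a 7 mm clearance, sized by a worst-case calculation so that
per-patient anatomical jitter (≤ 6% on sizes, ≤ 1.5 mm on centers, ≤ 1
slice on tube ends) can never make ground-truth structures overlap.

A simulated rater perturbs the truth in three ways:

* **Smooth surface displacement.** The truth's signed Euclidean distance
  field (negative inside; center-to-center, so never zero) is thresholded
  against a Gaussian random field band-limited to a 6 mm correlation
  length and scaled to `surface_sigma_mm`. Smoothness keeps simulated
  contours simply connected, like human contours; i.i.d. voxel flips would
  not be.
* **Margin bias.** A constant threshold offset $b$; for $b > 0$
  boundary-distance ties are included and for $b < 0$ excluded, which
  makes a ±1 mm bias at 1 mm spacing exactly the morphological
  dilation/erosion by a Euclidean unit ball between voxel centers — the
  oracle the tests assert against.
* **Extent jitter and divergence.** Whole slices are randomly truncated or
  extended (extensions copy the nearest true slice before perturbation),
  and the displacement amplitude ramps by `1 + divergence_gain * t` from
  the inferior (t = 0) to the superior end (t = 1), reflecting that the
  NVB fans out and is harder to distinguish toward the base.

An all-zero model returns the truth bit-exactly, and each
(patient, rater, structure) draw takes an independent seed derived from
one master seed. The default conditions — σ = 1.5 mm, per-rater margin
biases (0, +0.5, −0.5, +1.0) mm, 2-slice extent jitter, divergence gain
1.0 over 15 patients × 4 raters — are illustrative: they produce
cohort-median Dice around 0.9 for the prostate and in the mid range
(0.6–0.8) for the tubular structures, with the inferior-half NVB agreeing
better than the whole NVB. The generator emulates geometry and rater
behavior, not MR appearance: there is no imaging noise, no
anatomy-dependent visibility, and rater errors are independent across
raters (no shared atlas bias), so passing tests demonstrate the
correctness of the metrics and pipeline, not the clinical difficulty of
the real task.

## Problem sizes

Unit and property tests run on small hand-built masks and, for
cohort-level properties (record counts, monotone degradation with noise,
the inferior-half direction-of-effect), on the same physical anatomy
voxelized at 3 mm isotropic — these properties are resolution-independent
by construction. The acceptance script runs the main (15-patient) and
pilot (5-patient) cohorts at the full default resolution and its
zero-noise identity check at 2 mm isotropic. The brute-force distance
oracle runs on 12³ grids, where exhaustive all-pairs search is exact and
cheap.

## Known limitations

* Surfaces are boundary voxel centers; sub-voxel (mesh) surface models
  give slightly different distances, particularly at coarse spacing.
* DICOM RTSTRUCT is not parsed; contours arrive as masks or slice-polygon
  CSV.
* The noise model's parameters are not calibrated to any clinical
  cohort — no per-rater bias estimates exist to calibrate against — so
  simulated agreement levels are indicative only.
* Harmonization assumes a shared grid per patient and structure;
  registration between raters' grids is out of scope.
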