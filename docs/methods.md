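# Methods

This note documents the models, conventions and design choices behind
`pelvimetry`, and what the synthetic validation does and does not
demonstrate.

## Coordinate conventions

Label volumes are 3D integer lattices with a 4×4 voxel-to-world affine.
Axis 0 is the superior–inferior in-plane direction (image rows), axis 1 the
second in-plane direction, axis 2 the through-plane stack.  All measurements
are computed in world space (mm), derived from the affine's column norms, so
anisotropic voxels — typically 0.27–0.86 mm in-plane versus 3.0–3.5 mm
through-plane for T2-weighted pelvic MRI — are handled correctly by
construction.  Voxel indexing is 0-based; a voxel's physical position is its
center.  No sub-voxel refinement is performed anywhere: boundaries live on
the pixel grid, and all stated tolerances are in voxel units.

## Measurement algorithms

**Slice selection.**  Structures are delineated in a single mid-plane slice
per orientation, so each measurement runs on the 2D slice with the maximal
structure area along the through-plane axis.  An alternative reading —
largest 3D connected component — was considered and rejected because the
single-slice annotation protocol concentrates each structure in one slice.
Area ties break to the lowest slice index and are logged.

**MUL.**  For the selected urethra slice, every occupied image row
contributes one polyline point: the mean physical position of its true
pixels.  The MUL is the polyline's arc length.  This makes the MUL of a
straight vertical tube exactly `(n_rows − 1) × row_spacing`, and makes the
measurement invariant to symmetric widening of the cross-section.  Rows
inside the component's span with no pixels are skipped and logged.

When the urethra fragments into two components (prostate-attached and
corpus-attached), the two largest components are measured separately and
combined; any further components are ignored and logged.  Whether the gap
between the facing endpoints belongs to the urethra is genuinely open: the
anatomical urethra is continuous, so excluding the gap systematically
shortens the MUL.  Both policies are implemented (`--mul-bridge
{include,exclude}`); **include** is the default, and the bridge length is
recorded per case so the other policy's value is always recoverable
(`exclude = include − bridge`, an identity the tests assert).

**IPPL.**  The bladder–prostate interface is the intersection of the
prostate with a one-pixel dilation of the bladder.  The structuring element
is the 4-connected cross — the minimal reading of "one-pixel dilation" — so
purely diagonal contact yields no interface; the 8-connected element is
available by configuration.  The chord connects the interface pair with
maximal pairwise distance (ties: lexicographically smallest coordinate pair,
logged).  Candidate contour points are prostate boundary pixels (8-boundary)
whose signed perpendicular offset from the chord has the same sign as the
bladder centroid's — this operationalizes "protrudes into the bladder"
deterministically.  The IPPL is the maximum perpendicular distance over
candidates, and exactly 0 for a flat interface with nothing on the bladder
side.

**Muscle thickness.**  Per in-plane slice: the medial-axis centerline
(`skimage.morphology.medial_axis`) is sampled on the Euclidean distance
transform to the background, computed in mm with per-axis sampling.  The
thickness is twice the maximum centerline-to-border distance over all
slices, with the slice and point of the maximum recorded.  The computation
is deliberately 2D per slice rather than a 3D medial surface: with 3.0–3.5
mm slices, through-plane distances would dominate incorrectly.  Which slice
holds the maximum is not prescribed, so the maximum over slices is reported
("maximum thickness").  The medial-axis skeleton itself is computed on the
pixel grid and assumes near-isotropic in-plane spacing, which holds for the
supported acquisitions; the distances sampled on it are metric.

## Segmentation metrics

The surface model is fully specified rather than borrowed: a surface voxel
is a mask voxel with at least one face-adjacent (6-neighbourhood) background
neighbour, with out-of-lattice positions counting as background.  Directed
distances are Euclidean, in mm, between surface-voxel centers.  MSD is the
mean of both directed distance lists pooled; HD95 is the maximum of the two
directed 95th percentiles, with linear interpolation between order
statistics.  This voxel-center convention can differ by a fraction of a
voxel from sub-voxel surfel models used by other toolkits; it is validated
against an exhaustive all-pairs oracle to 1e-9 mm.  Conventions for empty
masks: Dice of two empty masks is 1.0 (logged), empty-versus-nonempty is
0.0; surface distances are undefined for empty masks and reported as flagged
missing values, never numbers.

## Agreement statistics

**ICC.**  The implemented form is ICC(2,1): two-way random effects, absolute
agreement, single rater — the form appropriate when individual raters'
measurements (not rater means) are the unit of analysis.  Mean squares come
from the standard two-way ANOVA decomposition without replication.  The 95%
CI uses the McGraw–Wong (1996) F-based approximation with a
Satterthwaite-style degrees-of-freedom estimate for the rater term; the
implementation is cross-checked against `pingouin`'s ICC2 row in the tests.
A zero-variance table is defined as ICC 1.0 with a degenerate-variance
warning.  Band assignment uses the conventional closed ranges (≤ 0 no
agreement; 0.01–0.20 none-to-slight; 0.21–0.40 fair; 0.41–0.60 moderate;
0.61–0.80 substantial; 0.81–1.00 almost perfect); values are rounded
half-up to two decimals first, so gap values such as 0.204 fall to the lower
band, matching how two-decimal published values are banded.

**Bland–Altman.**  Difference = first input − second input; limits at mean ±
1.96 × SD (n−1 denominator).  Per-pair means are retained for plotting.

**Wilcoxon signed-rank.**  Zero differences are dropped; absolute
differences are ranked with midranks for ties.  For effective n ≤ 25 the
exact two-sided p is computed from the full null distribution (dynamic
programming over doubled ranks, so midranks stay integral); beyond that, the
normal approximation with tie correction and 0.5 continuity correction is
used.  The exact branch is verified against full 2^n enumeration for all
n ≤ 12, including ties.

**Quantiles.**  Medians and IQRs use the linear-interpolation (type-7)
rule, stated so printed IQRs can be compared like-for-like.

## Phantoms

The generator produces a coronal and a sagittal label volume per case, on a
160×160×24 grid at (0.63, 0.63, 3.0) mm — the dominant acquisition geometry
for this application, with generation well under a second:

- the **urethra** is a radius-1.5 mm tube (urethra-like caliber) swept along
  a piecewise-linear centerline confined to the mid through-plane slice,
  with flat ends (no spherical caps), so the per-row centroid polyline
  terminates at the true endpoints and the analytic centerline length is the
  MUL ground truth; control-point rows are snapped to pixel centers;
- the **prostate** and **corpus spongiosum** are ellipsoids abutting the
  tube's superior and inferior ends;
- the **bladder** (sagittal only) sits above a flat interface row; an
  optional semicircular prostatic bump of height *h* protrudes through the
  interface into the bladder, giving IPPL truth *h* (0 = flat);
- each **muscle** is a slab of known thickness, optionally rotated in-plane
  (0°/30°/60° in the sweeps), placed in slice bands clear of the other
  structures.

Randomized sweeps sample MUL uniformly in [8, 22] mm, IPPL in [0, 8] mm
(one case in four exactly flat), and muscle thickness in [5, 25] mm —
brackets spanning clinically reported magnitudes for post-prostatectomy
cohorts.  Boundary jitter (independently deleting surface voxels with a
seeded probability) is available for exercising the segmentation metrics;
it defaults to 0 so that analytic truth holds exactly.

Expected recovery tolerances are set by rasterization, not by the
algorithms: MUL within 2 in-plane pixels (±1.26 mm at default spacing), IPPL
within one in-plane pixel, thickness within 2 pixels.  The acceptance sweep
confirms all three with margin (typical maxima ≈ 0.7, 0.61 and 1.24 mm over
30 seeds).

**What the phantoms do not show.**  They are geometric scenes — ellipsoids,
slabs, straight-to-gently-curved tubes — not anatomy.  Passing the sweeps
demonstrates that the measurement algorithms are correct on label maps, with
errors bounded by voxel quantization; it says nothing about segmentation
quality on real MRI, about strongly curved or partially missing urethras
beyond the two-component split case, or about muscles whose maximal
thickness lies oblique to the imaging plane.

## Numerical choices and degenerate inputs

- All ties (slice areas, chord endpoints) break deterministically and are
  logged with a `WARN` prefix; identical inputs give bit-identical outputs.
- Scaling the voxel spacing by k scales every reported mm value by exactly k
  (the suite asserts this at machine precision for k ∈ {0.5, 2}).
- Empty or missing structures produce flagged results (`NaN` in the API,
  empty cells in CSV) and never abort a batch.
- Measurement CSVs round to 2 decimal mm; provenance JSONs (polylines,
  chord endpoints, argmax points) keep full precision.
- Ellipsoid rasterization includes boundary voxels with a 1e-12 relative
  tolerance so apex voxels that land exactly on the surface are kept.

## Problem sizes used in the validation suite

The default test/validation scales — 30-seed phantom sweeps, 100 random
mask pairs up to 16³ against the brute-force surface oracle, 50 ICC tables
plus 500 simulation replicates at n = 200, k = 3, 100 Wilcoxon samples up to
n = 12, Bland–Altman coverage at n = 10,000 — were chosen so the full suite
runs in well under a minute while every stochastic check has enough
replicates to be stable across seeds.

## Known limitations

- The IPPL chord search is quadratic in the number of interface points;
  fine for single-slice interfaces, not intended for 3D interfaces.
- ICC confidence intervals are approximate (F-based); exact intervals for
  unbalanced or missing-data designs are out of scope (incomplete subjects
  are dropped, with a log message).
- The medial-axis skeleton assumes near-isotropic in-plane pixels; strongly
  anisotropic in-plane grids would bias the centerline location (not the
  metric distances).
- Coronal and sagittal volumes are measured independently; no cross-plane
  registration or consistency check is performed.
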