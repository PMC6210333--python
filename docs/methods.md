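# Methods

This note documents the models, numerical choices and assumptions behind
`leaf3d`, in the order the pipeline runs.

## Input model

The input is a colored point cloud of a single plant in centimetres, as
produced by a scaled structure-from-motion reconstruction (camera work,
reconstruction and metric scaling are upstream of this package and are
assumed done). Points carry RGB in 0–255. Coordinates must be finite;
the cloud is otherwise unordered and may contain duplicates.

## Green filter

Leaf tissue is isolated by the normalized green value g = G/(R+G+B).
Points with g **strictly below** the threshold (default 0.4) are cut;
a point at exactly the threshold is retained. Black points (R=G=B=0)
have an undefined index and are always removed — they cannot be leaf
tissue. Filtering runs on points, before voxelization. The threshold is
the single knob for residual branch/stem clutter; lowering it admits
yellowish leaves, raising it cuts pale stems.

## Voxelization

Each point maps to voxel index `round((p − origin)/s)` per axis, with
**round-half-away-from-zero**. The convention matters only on exact
half-coordinates, a measure-zero event for real scans (the phantom
generator avoids them); fixing it keeps indices a pure function of the
coordinate. The origin is the filtered cloud's minimum corner, so
indices are non-negative, and the grid stores origin and per-axis voxel
size so voxel centres convert back to world coordinates exactly.
Occupancy is binary: any number of points in a cell gives attribute 1,
which makes all downstream quantities invariant to point density,
duplication and ordering. Voxel edge `s` defaults to 0.1 cm; 0.03–0.2 cm
is the sensible range for plants of 20–60 cm, smaller plants taking
smaller voxels.

## Top-view initialization

The occupied voxels are flattened along Z (`any` over the column) into a
binary top view. Background enclosed by foreground — sampling holes — is
filled by morphological reconstruction (background is flood-filled
4-connected from the border; anything unreached becomes foreground).
Foreground connectivity is 8, background 4, the standard complementary
raster convention.

The initial per-leaf segmentation is the watershed of the negated
Euclidean distance transform of the foreground, restricted to the
foreground. Marker selection is where rasterized point-sampled masks
differ most from clean silhouettes, and three numerical defenses are
applied, all configurable:

* **Boundary de-noising** (`mask_smooth_radius`, default 1 px): the mask
  used for the distance map is smoothed by morphological closing then
  opening with a 1-px disc. Poisson-sampled boundaries are ragged at the
  single-pixel scale, and that raggedness propagates inward as spurious
  maxima along the distance ridge; removing it at the source is far more
  effective than any amount of maxima suppression afterwards. The
  watershed itself still floods the *original* foreground, so the output
  labels always partition the input mask; any foreground component the
  smoothing erased entirely (isolated specks) keeps its own label.
* **Distance smoothing** (`marker_smooth_sigma`, default 1 px Gaussian):
  flattens sub-pixel dips along ridge plateaus of elongated leaves.
* **h-maxima suppression** (`h_maxima`, default 0.1 px): the residual
  prominence filter. The default is deliberately small — biased toward
  over-segmentation — because the true saddle between a large leaf and a
  deeply overlapped smaller one can be very shallow (a fraction of a
  pixel after smoothing), while over-segmentation is repaired later by
  the 3D merge step below. Setting
  `h_maxima=0, marker_smooth_sigma=0, mask_smooth_radius=0` reproduces
  the naive reading: raw regional maxima of the exact distance map.

Labels are renumbered consecutively 1..K; the pipeline is fully
deterministic.

## Seed regions

Each 2D leaf region is contracted to **1/10 of its scale about its own
centroid** (configurable `shrink_factor`) and re-rasterized with the same
half-away rounding as voxelization. A region whose contraction
rasterizes to nothing — possible for thin regions a few pixels wide —
keeps its pixel nearest the centroid, so every leaf always owns at least
one seed pixel; contested pixels go to the smaller label. Seeds are then
projected into the grid onto the **topmost occupied voxel** of their
column: the seed image derives from a top view, so it can only speak for
the surface actually visible from above. Projecting to every voxel in
the column would stamp labels onto occluded lower leaves, exactly the
baseline failure the 3D method exists to fix.

## Seed merging by 3D component

Before growth, seed regions whose voxels fall in the same 3D connected
component of the occupancy are fused (smallest leaf number wins). The
rationale is the growth stage's own operating assumption: expansion can
only separate leaves that are distinct connected components — each
leaf's edge is apart from other leaves in 3D — so two seeds inside one
component are necessarily fragments of one over-segmented leaf. Leaves
overlapped in the top view but vertically separated live in different
components and are never merged. This step is what lets the marker
stage run with a small `h_maxima` safely; it can be disabled
(`merge_seed_components=False`) to study the raw watershed behavior.

## Attribute expansion

Growth is synchronous multi-source BFS on the occupied voxels: at each
round, every unlabeled occupied voxel adjacent to a labeled voxel takes
that label; a voxel reached by two labels in the same round takes the
**smaller leaf number**, a deterministic rule independent of seed
insertion order. Adjacency defaults to 26-connectivity, because leaf
sheets voxelized from oblique planes are frequently only
corner-connected; 6 and 18 are available. Iteration stops when no voxel
changes. Occupied voxels in components containing no seed remain
unlabeled (label 0) and are counted in the run report rather than
force-assigned. The implementation advances an explicit frontier on flat
voxel indices; it is exactly equivalent to whole-grid per-round min
filtering (an unlabeled voxel's labeled neighbours are always members of
the previous round's frontier) and is tested against that oracle. A
sequential (voxel-at-a-time) growth variant could differ by at most one
voxel at boundaries where two leaves touch; with the phantoms' inter-leaf
gaps the two variants coincide.

The **simple-projection baseline** stamps the 2D watershed label of each
pixel down its entire voxel column. It is kept verbatim as the
comparison method: a lower leaf occluded in the top view either inherits
the upper leaf's label or is missed entirely.

## Leaf area

Per leaf, the leaf's own points are re-voxelized at
`(s, s, z_rebin_factor·s)` and the area is the occupied-voxel count times
the horizontal face area `s²`. The Z-stretch (default factor 3)
suppresses the vertical surface noise that would otherwise stack extra
voxels and inflate the area. The factor is a **multiplier of the XY
voxel size**, not an absolute 3 cm bin: an absolute bin would exceed the
leaf-height span of many small plants, while a ×3 rebin matches the
stated purpose of damping vertical noise. Re-voxelization is per leaf
from its points, not a rebinning of the segmentation grid — the two
differ at leaf boundaries shared between grid cells.

The formula is implemented verbatim and its accuracy characterized
rather than corrected. For a planar leaf of area A at inclination θ, in
the dense-sampling limit a voxel column of width `s` spans `s·tanθ` of
height and touches on average `1 + tanθ/z_rebin_factor` Z-bins, so the
estimate tends to `A·(cosθ + sinθ/z_rebin_factor)` plus a positive
boundary term of order `perimeter·s/2`: −5.7% at θ = 45° with the
default rebin, partly cancelled by the boundary overcount. At θ ≤ 45°
the net bias stays within about 5% (tested on analytic discs),
degrading for very steep leaves. The estimate needs
point density high enough that every voxel column on the leaf contains a
point; at density ρ points/cm² the expected points per column are
`ρ·s²/cosθ`, and below ~3 the footprint develops holes and the area is
underestimated. Area is invariant to rigid translation, point
duplication and ordering, and for horizontal leaves equals the top-view
footprint times `s²` exactly.

## Leaf inclination

The inclination is the angle between the leaf plane and the horizontal,
`θ = arccos |n·ẑ| ∈ [0°, 90°]`, with `n` the unit normal of a
**total-least-squares** plane fit (smallest principal direction of the
centered neighborhood; vertical least squares would be ill-conditioned
for steep leaves). The fit neighborhood is the set of leaf points within
`plane_fit_radius_frac` (default 0.3) of the leaf bounding-box diagonal
from the leaf centroid — the central lamina, excluding curled edges; the
fraction is configurable since "around the centroid" is inherently a
modeling choice. Degenerate neighborhoods (fewer than 3 points, or
collinear) raise an error naming the leaf. The estimate is invariant to
rotation about the vertical axis and to uniform scaling.

## Phantom generator

The generator emulates what the pipeline actually consumes: a dense SfM
cloud of a small rosette plant.

* **Leaves** are ellipses (semi-axes `a`, `b = 0.6a` by default, `a`
  uniform in 2–4 cm) sampled uniformly at 250 points/cm² — dense enough
  that voxel columns at the default grid hold multiple points, matching
  the hole-free clouds dense photogrammetry yields — tilted to a known
  inclination (uniform 10–60° by default), rotated in azimuth, and
  jittered along the local normal by isotropic Gaussian noise
  (σ = 0.02 cm default, ~1/5 voxel). An optional parabolic sag models
  gently curved laminae. Colors are randomized greens with g ≥ 0.43.
* **Layout**: leaves (one designated overlapped pair counting as a unit)
  sit on a ring whose radius grows until every non-pair leaf pair keeps
  a clear 3D gap (≥ ~3 voxels, verified by nearest-neighbor distance),
  with staggered heights. Truth labels therefore correspond to separate
  3D components, the regime the growth method targets.
* **Overlap control**: the designated pair is stacked with a vertical
  gap of `vertical_gap_voxels` (default 3) voxels and a horizontal
  offset found by bisection so the rasterized top-view footprint
  intersection over the smaller footprint hits the requested fraction
  to ±0.02 (validated at ±5%).
* **Clutter**: an optional brown vertical "branch" of points at the
  plant centre, entirely below the green threshold.
* **Truth**: per-point labels; per-leaf planar area πab (exact for
  curvature 0; for sagged leaves it is the generating ellipse's area),
  generating inclination, and the voxel-count area of the true labels at
  the stated grid. All randomness flows through one seeded generator:
  identical spec + seed gives a bit-identical phantom.

What the phantoms do **not** model: leaves touching in 3D, strongly
curled or lobed laminae, anisotropic SfM reconstruction noise, color
gradients, specular highlights, partial leaf transparency. Passing the
phantom benchmarks therefore demonstrates the pipeline's correctness in
its intended operating regime (separated, gently curved leaves at dense
sampling), not performance on arbitrary real scans.

## Evaluation

Estimated and true leaves are matched greedily by shared-cell count
(largest overlap first, each side used once, ties to smaller labels).
Success rate is the percentage of leaves whose relative area error is
**strictly below** 10%, with unmatched true leaves counted as failures.
Accuracy statistics are RMSE, MAPE (reported as mean ± sample SD of
per-leaf absolute percent errors; pairs with true value 0 are excluded
and counted), and the coefficient of determination R² = 1 − SS_res/SS_tot.
Method comparison runs both methods on identical phantoms and tests the
paired per-phantom MAPE difference with an **exact two-sided sign-flip
permutation test** on the mean (all 2ⁿ sign assignments enumerated);
the test is labeled as such since it is this package's choice.

## Benchmark problem sizes

The standard studies use 30 single-leaf phantoms (inclination, area),
10 plants of 4–11 leaves (success rate), and 10 overlapped two-leaf
phantoms (method comparison) — each plant segments in a couple of
seconds at the default grid, so a full benchmark run takes well under a
minute on one core. Larger batches scale linearly.

## Known limitations

* Leaves forming a single 3D component (physically touching) cannot be
  separated by growth, and the component merge will deliberately fuse
  their seeds; this mirrors the method's stated assumption.
* Deep top-view overlap (≳ 0.4 of the smaller footprint) can erase the
  distance-map saddle entirely; no marker rule recovers the hidden leaf
  from the top view alone.
* Very steep leaves (≳ 80°) leave footprints a few pixels wide; area
  estimates degrade as 1/cosθ quantization dominates.
* The voxel-count area is a surface proxy, not a mesh integral; its
  inclination-dependent bias is documented above and left uncorrected by
  design.
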