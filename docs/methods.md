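# Methods

`gliomorph` quantifies the architecture of the gliovascular unit in 2D
fluorescence micrographs (maximum-intensity projections): astrocyte
morphology, vessel network geometry, connexin puncta coverage of
vessels, neuron laminar density, and the spatial relationships between
these compartments.  This note documents the model behind each stage,
the parameters that matter, the numerical choices, what the synthetic
benchmark scenes do and do not emulate, and the known limitations.

All operations run on an isotropic pixel grid with a single µm/pixel
calibration.  Coordinates are 0-based and row-major; the centre of
pixel *(i, j)* is at *((i+0.5)·ps, (j+0.5)·ps)* µm.  Micrometre-valued
parameters are converted to pixels once, as `r_px = r_um / ps`, and the
distance tests themselves are never rounded.

## Segmentation

**Adaptive local threshold.** A pixel is foreground iff its intensity
is *strictly* greater than the mean intensity over the exact discrete
disc of radius 20 µm centred on it (a pixel belongs to the window iff
the centre-to-centre distance is ≤ the radius in pixels).  Near the
border the disc is clipped to the grid and the mean taken over
in-bounds pixels only — no out-of-field intensities are invented.  The
disc mean is computed by row-chord sliding sums (exact to float
accuracy against a nested-loop enumeration); before thresholding,
intensities are anchored at the first pixel's value, which leaves the
strict comparison mathematically unchanged but makes constant regions
sum to exactly zero, so they can never leak into the foreground through
floating-point residue.  The threshold is mean-relative, hence
invariant under positive affine intensity rescaling.

**Size filters.** Connected components (8-connectivity throughout)
whose area in µm² is *strictly smaller* than the threshold are deleted;
components exactly at the threshold survive.  Defaults: 25 µm² for
astrocyte processes, 15 µm² for connexin puncta.

**Process segmentation** is Gaussian smoothing (σ configurable, default
1 µm; the appropriate value depends on the acquisition PSF), adaptive
threshold, size filter, then union with the detected body mask — the
size filter runs before the union.

**Body and vessel detection** are pluggable: any callable returning a
mask on the input grid (e.g. a trained segmentation network) can be
substituted.  The classical defaults are:

* *Somata*: smooth → adaptive threshold ∧ global Otsu → optional
  area-capped hole filling (default off; filling also closes regions
  enclosed by processes, which then masquerade as somata) → binary
  opening with a 3 µm disc (erases structures thinner than ~6 µm while
  preserving compact somata) → watershed split of touching blobs at
  peaks of the interior distance transform (minimum peak separation
  6 µm) → discard objects below 50 µm² (≈ an 8 µm-diameter soma, the
  smallest astrocyte body we expect; also safely above the area of
  process-crossing knots that survive the opening).  Labels are
  renumbered in row-major centroid order for determinism.
* *Vessels*: smooth → adaptive threshold → morphological closing (2 µm
  disc) → remove components below 50 µm².

## Medial lines and graphs

**Thinning.** Masks are reduced to 1-pixel-wide medial lines by
topology-preserving 2D thinning (Guo–Hall base pass).  Two corrections
are applied on top:

1. Residual 2×2 skeleton blocks are removed by sequential deletion of
   *simple points* (exact test: one 8-connected foreground component in
   the neighbourhood and one 4-connected background component adjacent
   to the centre), which cannot change the component count.  A 2×2
   block with four diagonal arms anchored at distinct corners is
   topologically irreducible and is left in place; such configurations
   do not arise from thresholded smooth images.
2. The result is made *exactly equivariant to 90° rotations* by running
   the base thinning in all four axis orientations and selecting a
   canonical result by rotation-invariant integer keys (pixel count,
   sums of the integer squared distance transform over the skeleton,
   the neighbour-count histogram).  Published 2D thinning passes are
   directional and violate this equivariance, which would leak into
   every downstream length and branch count under image rotation.

**Classification.** Skeleton pixels with one 8-neighbour are
terminations, with ≥ 3 bifurcations, with none isolated.  Adjacent
bifurcation pixels form a junction cluster that collapses to a single
graph node (placed at the integer-rounded cluster centroid), so branch
points are never double counted.

**Arc length** along a pixel path is one pixel size per axial step and
√2 per diagonal step.  On straight segments of random orientation this
octile rule overestimates Euclidean length by ~5 % on average (at most
8.2 % at 22.5°); tip retraction by the thinning pass acts in the
opposite direction, so recovered lengths on the benchmark scenes land
within a few percent of truth.

**Per-cell graphs.** Each skeleton connected component is assigned to
the body whose (1-pixel-dilated) mask it intersects; components
touching several bodies are split by the nearest-body label of each
pixel; components touching none become *rootless* graphs that enter
sample-level totals but not per-cell statistics.  Skeleton pixels on or
adjacent to the body collapse into a single root node placed at the
member pixel nearest the body centroid — intra-soma medial lines are
absorbed into the root.  Edges are traced deterministically (fixed
neighbour scan order); pure cycles are anchored at their
lexicographically smallest pixel and kept as self-loops.

**Spur pruning.** Terminal edges with arc length strictly below 4 µm
are removed iteratively, shortest first; after each removal, chains
through degree-2 nodes are re-merged and node kinds refreshed.  Only
termination-incident edges are candidates, so the graph never
disconnects; pruning is idempotent.  Vessel graphs are built the same
way without a root, under the same 4 µm rule (overridable).

## Astrocyte morphometrics

* **Density**: detected bodies / sample area (cells/mm²).
* **Extension length density**: total medial-line arc length / area
  (µm/µm²).  Skeleton pixels inside the detected body mask are excluded
  — the planted (and anatomical) process length starts at the soma
  boundary, whereas thinning the body-unioned mask adds intra-soma
  medial lines.  The cut uses the body mask eroded by one pixel,
  because the thresholded soma mask carries a ~1 px blur/anti-aliasing
  halo that would otherwise clip the proximal end of every process.
* **Branching density**: graph nodes of degree ≥ 3 per mm², counted on
  pruned graphs.  A root with ≥ 3 incident edges counts (the criterion
  is degree, not node kind); rootless-graph bifurcations count toward
  the sample.
* **Angle entropy**: at every skeleton pixel, the local orientation is
  the principal axis (total least squares — vertical segments are not
  degenerate) of all same-skeleton points geodesically reachable within
  a Euclidean window of 4.5 µm; geodesic reachability prevents
  borrowing points from a nearby unrelated process.  Windows with fewer
  than two points are skipped.  Orientations are undirected angles in
  [0, π), binned into 18 bins of 10° (bin origin at 0, angles
  unweighted by length), and the Shannon entropy (base 2) of the
  normalized histogram is the cell's angle entropy; the sample value is
  the mean over cells with at least one defined orientation (cells with
  none are excluded with a logged warning).  Bin count, origin, entropy
  base and weighting are free choices recorded in the provenance block.

## Vessels

The vessel mask is thinned and graphed as above.  The local radius at
each skeleton pixel is the exact Euclidean distance transform (EDT) of
the mask evaluated there, in µm; diameter is twice that.  The exact EDT
matters because the 4.5 µm diameter split downstream is a hard boundary
that chamfer approximations would bias.  Junction pixels take their
radius from the same EDT (junction inflation accepted); terminal
skeleton pixels within one local radius of the image border are flagged
so border-truncated vessels can be excluded from diameter statistics.
Vessel density is total medial-line arc length per area; branching
density counts degree-≥ 3 nodes per mm².

## Neurons

Images are globally histogram-equalized onto [0, 1] (rank-preserving),
then filtered with scale-normalized Laplacian-of-Gaussian responses
(−σ²·∇²(G_σ∗I)) over 8 geometrically spaced scales spanning σ = 4.5–9
µm.  Detections are local maxima of the (scale, y, x) volume with
response strictly above 0.1: a candidate must be ≥ all 26 neighbours,
plateaus of equal response keep only their lexicographically smallest
member, and overlapping detections (centre distance below 0.7·(r_i+r_j)
with r = √2σ) keep the higher response.  The number of scales and the
response normalization behind the 0.1 threshold are configuration, not
claims.  Depth below the manually traced cortical surface (tissue
assumed on the larger-row side of an x-monotone trace) is the Euclidean
distance to the polyline, binned into 50 µm bands; band areas are
measured on the pixel grid from the EDT of the rasterized trace, so
densities respect field clipping.  Detections above the surface are
excluded and counted.

## Gliovascular relationships

* **Contact fraction**: every process/body pixel is labelled with its
  nearest detected body; an astrocyte contacts a vessel iff its
  labelled territory shares ≥ 1 pixel with the vessel mask; the
  fraction is contacting / total (undefined when no astrocytes).
* **Radial profiles**: distance from the vessel wall is the EDT of the
  vessel mask (zero on the mask; pixels inside vessels excluded from
  annuli).  Annulus *k* collects non-vessel pixels at distance
  [k·step, (k+1)·step) µm (step 1 µm).  Body density uses centroids,
  signal density uses mask area; each is normalized by the
  whole-sample density over the full non-vessel field, so a uniform
  quantity profiles flat at 1 and the area-weighted mean of the
  normalized profile is exactly 1 when annuli cover the field.  Note
  that at calibrations ≥ 1 µm/px the first annulus [0, 1) is
  structurally empty (off-mask grid distances are ≥ 1 px); sub-µm
  profiling requires sub-µm pixels.
* **Connexin coverage**: connexin pixels within 6 µm of the vessel mask
  (boundary included; a 10⁻⁹ guard absorbs float representation at
  exact boundaries) count as vessel-associated.  Each vessel pixel
  belongs to the small (≤ 4.5 µm) or large (> 4.5 µm) calibre stratum
  of its nearest skeleton pixel, and each associated connexin pixel to
  the stratum of its nearest vessel pixel.  Both nearest-set lookups
  are implemented by comparing two distance transforms (distance to the
  small set vs the large set, ties to small): this is deterministic and
  exactly equivariant to grid rotations, unlike nearest-index lookups
  with raster-order tie-breaking.  The strata partition the vessel mask
  exactly, and coverage per stratum is associated connexin area /
  stratum vessel area (values above 1 are possible and flagged).

## Synthetic benchmark scenes

The generator plants, with exact ground-truth tables: somata with
straight tree-structured processes, a vessel network of tubes with
varying calibre, puncta placed preferentially near vessel walls,
neuron-like Gaussian blobs in depth layers, and a cortical surface
trace; rendering draws anti-aliased capsules/discs/blobs (coverage
`clip(r + 0.5 − d, 0, 1)`, so the 0.5 level set is exactly `d ≤ r`),
then blurs (Gaussian, default σ 0.5 µm) and adds clipped additive
Gaussian noise.  One integer seed drives a single PCG64 stream in a
documented consumption order; regeneration is bit-identical, and
rendering is translation-equivariant for whole-pixel shifts.

Default conditions (the package's standard benchmark): 1 mm² field at
1 µm/px, 50 somata/mm² placed with ≥ 70 µm centre separation and a
10 µm object-free border margin, 4–6 primary processes per soma
(15–22 µm), secondary branches on 16 % of primaries (12–16 µm, 50–90°
from the parent), 3 mm vessel centerline per mm² with radii 1.5–4.5 µm
(straddling the 4.5 µm diameter split), 150 puncta of 16–30 µm² with
80 % placed within 3 µm of a vessel wall, and three neuron layers
(50–150, 150–300, 300–500 µm at 300/600/400 cells/mm²).

Three generator choices exist specifically so that the planted truth is
*recoverable at the rendered resolution* — a scene whose own geometry
is below the 2 px stroke width cannot serve as a recovery oracle:
primaries tile the soma perimeter (evenly spaced slots with ±0.2-slot
jitter) instead of i.i.d. angles, because near-parallel siblings merge
into a single medial line; secondaries branch at 50–90° with a 6 µm
clearance to every other branch of the cell (closer planted junctions
do not exist as junctions in the image); and soma separation keeps
neighbouring territories disjoint, because process crossings between
cells create image bifurcations the planted truth does not contain.
The planted branch-point count follows the same degree convention as
the measurement: one per secondary attachment plus one per soma with
≥ 3 primaries.

What the scenes do **not** emulate: realistic optics (only Gaussian
blur; no PSF anisotropy), shot noise or photobleaching, curved or
tapering processes, endfeet, 3D structure collapsed by projection,
background autofluorescence texture, or touching/overlapping cell
territories.  Passing recovery tests therefore demonstrates the
correctness of the measurement chain on resolvable geometry, not
segmentation robustness on real tissue.

## Validation problem sizes

The shipped validation suite runs: the windowed-mean oracle on 100
random 16×16 grids (radii 1–5 px); thinning contracts on 200 random
blob masks; morphometric recovery on 20 seeded noiseless 1 mm² scenes
(density exact; extension length and branching within 10 %, measured
margins ~2 % and ~5 %); entropy ordering on 20 matched aligned/
isotropic seed pairs at 0.25 mm²; LoG recovery of 30 planted blobs;
gliovascular exactness on constructed scenes plus radial uniformity
pooled over 10 scenes at 0.5 µm/px with 20 000 planted points each; and
byte-identical reruns plus 90°-rotation invariance of all reported
metrics.

## Known limitations

* The strict mean-window threshold marks ~half of a *structureless*
  noisy background as foreground (level-set percolation at the median),
  and smoothing correlates the speckle into components that survive the
  size filter.  This is a property of the thresholding rule itself; on
  real micrographs the background carries structure that raises the
  local mean.  Validation scenes are rendered noiseless; masks from
  noisy acquisitions should be inspected before trusting downstream
  numbers.
* Processes that cross or run closer than about the stroke width merge
  into one medial line: crossings add spurious branch points and merged
  stretches are counted once.  This is inherent to 2D projection
  morphometry, not a property of the synthetic scenes alone.
* The LoG detector undercounts dense, mutually overlapping neuron
  populations (overlap suppression keeps the higher response); counts
  in crowded layers are conservative.
* Diameters at vessel junctions are inflated by the EDT (no special
  casing); the border flag only marks, it does not remove, truncated
  vessels.
* Arc lengths carry the octile-metric bias (+5 % on average on straight
  segments) partially offset by tip retraction; both are documented
  above and bounded by the recovery tests.
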