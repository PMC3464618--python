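# Methods

## Scope and data model

The package analyses triangle surface meshes of single dicot plants with one
near-vertical tubular main stem, petioles attached at distinct heights, and
lobed, bilaterally symmetric blades with finite thickness. Coordinates are
millimetres by convention; no unit metadata is read from files (the CLI
`--scale` option applies a uniform factor at load). The up direction
defaults to +Z and is configurable. Meshes may contain holes and several
connected components; nothing assumes manifoldness or watertightness.
Adjacency is purely topological: two vertices are neighbours iff they share
a triangle edge. Vertex normals are the normalised mean of incident
non-degenerate triangle unit normals; vertices with no valid incident
triangle carry an undefined normal and are excluded from normal clustering.

## Stem curve fitting

The stem curve c_p is found in three passes:

1. **Walk.** The mesh is sliced into 40 horizontal bins. The lowest
   populated slice is anchored at the centroid of the densest cell of a 2D
   planar histogram (5 mm cells). Each subsequent slice recentres within a
   12 mm planar window around the previous centre; a slice is accepted only
   if the window holds ≥ 4 vertices whose median planar spread stays below
   6 mm (tube-likeness), which stops the walk from wandering into a leaf
   lying over the stem apex. Two consecutive rejections terminate the walk.
2. **Robust reference axis.** An iteratively reweighted linear fit of the
   accepted centres over height rejects slices contaminated by organ mass
   passing close to the stem (petiole bodies, blade bases near their
   insertion). Stems are treated as near-straight at this stage.
3. **Ring refinement.** Around the reference line, each slice reselects the
   tube ring (radial residual within 2.5 robust standard deviations, floor
   0.6 mm) and recomputes its centroid; a smoothing spline through the
   cleaned centroids, linearly extended to the vertical extremes of the stem
   cluster, is the final curve.

"No stem found" is raised when fewer than 5 slices validate, the chain spans
under 20 mm vertically, or the densest cluster's spread exceeds 12 mm (a
flat sheet, not a tube).

## Coarse partition

The estimated stem radius is the median planar distance to c_p of vertices
within the 12 mm window; region M is every vertex within 1.5× that radius
(planar distance, i.e. with the up-component removed). An organ sweeping
through that spatial band is *topologically* disconnected from the stem
tube, so minor connected components of M (below 25% of the largest) are
demoted back to the organ pool. Remaining vertices split into regions N_i as
connected components of the non-M subgraph — a floating piece (detached
blade) seeds its own region, which is what makes the stage robust to
reconstruction defects. Fragments smaller than 60 vertices are folded into
the nearest labelled organ at the end (debris from hole-cutting; at the
package's working resolutions no real organ is that small).

## Stem refinement and internodes

A single-radius tube around c_p is fitted robustly to M: alternate the
least-squares radius update (mean radial distance of inliers) with inlier
reselection (radial residual within 2.5 robust SDs, floor 0.1 mm) until the
radius moves < 1e-3 mm or 50 iterations. M-vertices within 1.3× the fitted
radius are stem; the rest are handed to the topologically adjacent organ
region. Junctions are the organ vertices welded to the stem, clustered by 1D
connectivity of their normalised curve parameter with gap threshold 0.02
(clusters need ≥ 2 vertices); internode k spans junction k to k+1, plus base
and apex segments. Zero junctions is valid (a defoliated or very young
plant: one internode).

## Petiole–blade separation

For each region attached to the stem, on-surface (Dijkstra) distances from
the attachment vertex order the region; 3 mm bins of that distance yield
local centres of mass, whose polyline is the petiole curve (extended through
the blade to its apex). The petiole tube radius is 2.2× the median
curve-distance of the near-attachment bins. B_i is the *on-surface* closest
vertex outside the tube; petiole = inside the tube and on-surface closer
than B_i. Measuring proximity to the stem along the surface (rather than
Euclidean) is equivalent for an intact petiole and remains correct when a
merged region contains a second petiole, whose vertices are Euclid-near but
surface-far. Detached regions skip the step entirely (whole region = blade,
petiole metrics are NA). Petioles steeper than ~25° from the stem axis
partially hide inside the coarse stem band and their metrics degrade — a
known limitation.

## Merged-leaf detection and split

A leaf region whose surface area exceeds **1.75×** the median leaf area is
split by the plane through the midpoint of its two farthest-apart vertices
(convex-hull accelerated search), normal along midpoint→far-vertex. The
threshold was calibrated on the generator's default populations: the natural
max/median area ratio across plants stays ≤ ~1.5, while two fused
typical-size blades form a region ≥ ~2× the median; 1.75 separates the two
populations. A merge of two far-below-median leaves is undetectable by any
size criterion — size-based detection is inherently limited to
"largely greater volume" cases. Regions under 20 vertices are never split.

## Leaf sub-segmentation

*Sagittal*: blade vertices are projected onto the plane normal to the stem
axis; side = sign of the signed angle between (stem→apex) and (stem→vertex),
with the stem reference being the c_p point closest to the blade centroid
and the apex the farthest projected vertex. Exact ties go LEFT. *Transversal*:
iterative two-cluster normal sort — start from the mean blade normal, assign
by angle ≶ π/2, recompute the mean over one cluster, repeat until the
assignment is fixed (cap 100 iterations). The up-facing cluster is named
adaxial. A single-sheet blade (one cluster empty) is flagged: its area is
the single surface's sum and thickness is NA.

## Phenotypic parameters

Stem height is the vertical extent of the stem region (the tube surface is
included, so a strongly inclined thick stem reads slightly taller than its
axis chord — consistent with the external-measurement convention); length
is the arc length of c_p; inclination the angle between the lowest→highest
stem-vertex direction and up. Petiole length is the arc length of the
centre-of-mass curve through the petiole region, clipped where it exits the
fitted stem tube and anchored at the extreme vertices (binning otherwise
trims half a bin per end); the initiation angle is between the stem axis and
the vector from the curve's stem-nearest point to its highest point (ties on
height resolved to the farthest point along the curve, so horizontal
petioles read 90°). Leaf width/length are projected on-surface path lengths
between the sagittal/coronal extreme points; because the projection removes
the orthogonal component, lattice zig-zag in the shortest path cancels and
the result approximates the developed dimension (bent blades recover their
laid-flat length). Area assigns each triangle to a surface by vertex
majority; thickness is the mean adaxial→nearest-abaxial distance. Undefined
values propagate as NA, never 0, so downstream statistics are not silently
biased.

## Temporal matching

Translation: lowest stem point to lowest stem point. Rotation: exhaustive 1°
grid over [0°, 360°) of the summed nearest-leaf-centroid distance, refined
by bounded scalar minimisation in the best ±1° bracket (the metric has many
local minima — a phyllotactic spiral nearly maps onto itself one rank over —
so gradient-only search is unsafe; the grid member is kept if refinement
does not improve it). The rotation axis is the up direction through the stem
base: with near-vertical stems this is the stable reading of "about the main
stem axis", and it matches how potted plants are actually re-oriented
(about the pot's vertical); rotating about a fitted axis inclined a few
degrees measurably corrupts the metric. Assignment uses the optimal
linear-sum solver on the centroid-distance matrix, padded square with a
10⁹ mm sentinel; pairs with azimuthal separation beyond the 45° gate are
ineligible, and sentinel matches are discarded as unmatched. Matching uses
segmentation centroids, not measurement frames, so flagged/unmeasurable
leaves still track. Chains terminate at an unmatched step; never-matched
organs keep length-1 trajectories.

## Agreement statistics

For pairs (a_i automated, m_i reference): relative error ε = |a−m|/m,
MAPE = 100·mean(ε), RMSE = √mean((a−m)²), MBE = mean(a−m), σ = sample SD of
100·ε. Trimmed variants drop ⌊0.05 n⌋ pairs at each tail of ε (ties broken
on the provenance key, so trimming is deterministic). σ is defined as the SD
of relative errors (the only reading consistent with its trimmed
companion). ICC(2,1) is computed from the two-way ANOVA decomposition with
k = 2 raters — (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)) — and cross-checked
in the test suite against pingouin's ICC(A,1). The Bland–Altman variant
plots relative error against log₁₀ of the pair mean. The reported
`mean_abs_error_mm` column is the mean absolute difference in mm (a range-
style column is ambiguous; the explicit name avoids the ambiguity).

## Synthetic plants: what they emulate and what they do not

The generator realises: a capped stem tube (radius 3 mm, default height
sampled 170.9 ± 12 mm) optionally inclined up to ~6°; petioles as thinner
tubes (radius 1.2 mm, length 45 ± 8 mm, initiation 40–75°) welded
topologically into the stem surface by stitch triangles; blades as two
offset sheets (thickness 1 mm) closed by a side wall, with a three-lobed,
bilaterally symmetric outline of width 88.9 ± 10 mm and length 78.9 ± 9 mm,
truncated at the base (~40% of maximal half-width) the way cotton blades
flare straight out of the petiole. Leaf sizes follow field-observed means
for vegetative cotton; counts default to 5–8 with jittered 137.5°
phyllotaxis. Blade bending is a circular arc about the coronal axis, an
isometry of the developed surface, so true width/length/area are exact
whatever the bend and equal the destructive laid-flat convention — which is
precisely what makes them a fair oracle for the bend-corrected
measurements. Growth sequences scale the stem and leaves per step (defaults
1.10 and 1.12 per interval), drift each azimuth within ±10°, insert young
leaves near the apex, and re-pot (rotate/translate) the whole plant;
persistent leaf identities are the tracking gold standard. Defects: holes as
connected triangle patches, detached petioles (removing the petiole tube,
leaving a floating blade), merged leaves (bridging triangles between the
closest blade points), and Gaussian vertex jitter.

Not emulated: photogrammetric noise structure (anisotropic, correlated),
texture, self-occlusion artefacts beyond the three defect types,
non-constant organ mesh density, leaf margin serration, and non-straight
stems. Passing the synthetic suites therefore demonstrates correctness of
the geometry processing under realistic dimensions and defect topologies,
not performance on real reconstructions.

## Problem sizes and determinism

Default meshes target ~6000 triangles per plant (the scale at which heavily
decimated reconstructions are analysed); the recovery studies use 20 plants
and the tracking study 6 plants × 4 time-points, which keeps the full suite
and the acceptance script in tens of seconds on one CPU. All randomness
flows through explicit integer seeds (generator specs, growth sequences,
defect injection); segmentation and measurement are deterministic given a
mesh and a configuration, and every threshold lives in `PipelineConfig`,
whose content hash is recorded in each record's provenance.

## Known limitations

- Petioles steeper than ~25° from the stem axis lose their proximal part to
  the coarse stem band; their length and angle degrade.
- Merged-leaf detection is size-based and cannot see merges of small leaves.
- The sagittal split degrades for blades strongly rotated about their own
  midrib (the planar-angle sign becomes uninformative).
- Organ tracking assumes consecutive imaging dates with bounded azimuth
  drift; skipped dates terminate chains by design.
- Width/length depend mildly (≲0.5%) on shortest-path tie-breaking on
  regular lattices.
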