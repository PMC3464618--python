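# phytomesh

Mesh-based 3D plant phenotyping for dicotyledons with a single main stem
(cotton-like architecture). Given a triangulated surface mesh of one plant
(OBJ or PLY, coordinates in millimetres, stem roughly vertical), the package

1. **segments** the mesh into morphological parts — stem internodes,
   petioles, and leaf blades with left/right and adaxial/abaxial sub-labels;
2. **measures** the classic morphological traits: main stem height, length
   and inclination; petiole length and initiation angle; leaf width, length,
   area, thickness and inclination;
3. **tracks** individual organs across imaging dates by rigid alignment and
   optimal assignment, turning per-date measurements into per-organ growth
   series;
4. **validates** automated against reference measurements with the standard
   agreement statistics (MAPE, RMSE, MBE, trimmed variants, R², ICC(2,1),
   and a Bland–Altman-style scatter).

A procedural generator of cotton-like plants with exact per-vertex ground
truth (`phytomesh.synthetic_plants`) replaces photogrammetric
reconstructions for development and testing, including the typical
reconstruction defects: holes, detached petioles leaving a floating blade,
and two leaves fused together.

## The method in brief

**Segmentation** is a four-stage hybrid of region growing and primitive
fitting. (1) A curve c_p is fitted to the main stem (robust slice-wise mode
walk plus a smoothing spline); every vertex within a planar radius of c_p
forms the coarse stem region M, and the remaining vertices grow into regions
N_i over topological neighbours — floating pieces seed their own region, so
holes and detached parts cannot break the pass. (2) A tube around c_p is
tightened to the stem; vertices inside it are stem, the organ vertices
welded to it mark the junctions that partition the stem into internodes.
(3) Within each attached region, a curve through local centres of mass
follows the petiole into the blade; a thin tube around it and the first
vertex outside the tube (B_i) delimit petiole P_i from blade L_i. (4) A
region far larger than the median leaf is split in two by the plane through
the midpoint of its farthest-apart vertex pair; each blade is then split
sagittally by the sign of the planar angle around the stem axis, and
transversally by iterative two-cluster normal clustering.

**Leaf measurement** uses the blade's sagittal plane π₁ = (L_c, u₁) and
coronal plane π₂ = (L_c, u₂), where L_c is the blade centroid, u₁ the mean
centroid-to-right-side direction and u₂ the centroid-to-apex direction.
Width (resp. length) is the arc length of the on-surface shortest path
between the extreme points S₁,S₂ of π₁ (resp. C₁,C₂ of π₂), projected onto
the other plane — a *developed* (laid-flat) dimension that is robust to
blade bending. Area averages the adaxial and abaxial triangle-area sums;
thickness averages adaxial-to-nearest-abaxial vertex distances.

**Tracking** aligns consecutive dates with the translation between the
lowest stem points and the rotation angle α about the stem axis minimising

&nbsp;&nbsp;&nbsp;&nbsp;m_α = Σᵢ minⱼ D(L_c(T,i), L_c(T+1,j)),

then matches leaves one-to-one by minimising summed centroid distances
(optimal assignment), with pairs beyond a 45° azimuthal gate declared
ineligible. Petioles inherit their leaf's match; internodes match by
normalised-height interval overlap (one-to-many when a new petiole splits an
internode).

## Worked example

```bash
phytomesh synth --out synth1 --seed 1          # synthetic plant + ground truth
phytomesh segment synth1/plant_t0.ply --out labels.csv
phytomesh measure synth1/plant_t0.ply labels.csv --out phen.csv
```

prints

```
wrote 1 time-point(s) to synth1
6 leaves, 7 internodes -> labels.csv
measured 6 leaves -> phen.csv
```

and `phen.csv` begins

```
plant,timepoint,organ_type,organ_index,parameter,value,flag
plant_t0,0,stem,0,height,180.6227873414755,
plant_t0,0,stem,0,length,181.23755231198848,
plant_t0,0,stem,0,inclination,2.9284245679250334,
plant_t0,0,petiole,0,length,45.481746491757434,
plant_t0,0,petiole,0,initiation_angle,69.62772170586842,
```

The stem is 180.6 mm tall, its curve is 181.2 mm long (a near-straight stem
leaning 2.9° from vertical), and the first petiole is 45.5 mm long leaving
the stem at 69.6°. The generator's ground-truth table
(`synth1/ground_truth.csv`) carries the true values for comparison; heights
and leaf dimensions recover to ~1% on clean meshes. Lengths are mm, areas
mm², angles degrees; undefined measurements (e.g. a detached petiole) are
empty cells, never zeros.

For a time series:

```bash
phytomesh synth --out series2 --seed 2 --timepoints 3
phytomesh track series2/plant_t0.ply series2/plant_t1.ply series2/plant_t2.ply --out trackout
```

writes `trackout/trajectories.csv`, one row per (organ trajectory,
time-point) with the measured parameters attached, plus per-pair alignment
diagnostics (rotation angle α, metric m_α, unmatched organs).

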