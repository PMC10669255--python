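# Methods

This note records how `bsgkit` models the guide-design problem, the numerical
choices behind the implementation, and what the synthetic phantom does and
does not establish about real data.

## Coordinate frame and phantom

All geometry lives in a right-handed patient frame in millimetres: +z
anterior (out of the chest), the chest-wall/pectoralis plane at z = 0, +x
patient-left, +y superior. Voxel index `(i,j,k)` maps to the voxel-centre
position `origin + index·spacing`.

The phantom emulates the *structure* a supine contrast-enhanced breast MRI
hands to the design pipeline, not MR physics. The breast is a superellipsoid
dome `(ρ/R)^e + (z/H)^e ≤ 1` (default `e = 2`, `R = H = 60 mm`: a
hemisphere — the simplest shape with a well-defined apex for the nipple).
The tumour is a rotated ellipsoid, by default 24×16×12 mm centred at
(38, 0, 20) mm; the lateral position keeps the nipple hole, its collar and
the channel annulus mutually clear at the default hole diameter. Intensities
are label-constant (gland 100, enhanced tumour 300, outside 0) plus additive
Gaussian noise (σ = 15 by default, i.e. a contrast-to-noise ratio of ~13 —
comfortable for thresholding, which is all that matters downstream).
Labelling is analytic: a voxel gets a label iff its centre is inside the
shape, with priority tumour > breast > pectoralis; the pectoralis stratum is
the one-voxel chest-plane layer outside the dome footprint, from which the
injection normal is fitted (exactly +z here). The nipple landmark is the
most anterior breast voxel centre; the manubrium sits superior-midline at
(0, 120, 0).

Voxel spacings of 3 mm or more are rejected at phantom construction and
flagged by `validate_slice_spacing` (strict bound: 2.9 mm passes, 3.0 fails),
matching the acquisition-resolution requirement the pipeline assumes.

What passing tests on the phantom do **not** show: robustness to bias
fields, breathing deformation, multicentric or ill-enhancing lesions, or
prone-supine registration error. The phantom is geometrically ideal by
design; the pipeline's accuracy claims are claims about the geometry
processing, not about segmentation of difficult clinical images.

## Segmentation and tumour axes

Manual radiologist thresholding is replaced by an explicit threshold
parameter plus a largest-26-connected-component rule (single concentric
lesion assumption). The raw mask is monotone in the threshold; the component
filter is applied afterwards. Reconstruction is marching cubes at the 0.5
level between inside and outside, vertices in mm, optionally Taubin-smoothed
(λ = 0.5, ν = 0.53, 10 iterations — changes enclosed volume by < 2 % on a
10 mm sphere at 1 mm voxels).

The "longest axis" is implemented as the longest surface chord. Its exact
computation uses the fact that the farthest point pair of a set lies on its
convex hull: hull vertices (scipy `ConvexHull`) followed by an all-pairs
search is exact at any mesh size and is verified against the brute-force
all-pairs oracle in the tests. Ties within 1e-9 mm resolve to the
lexicographically smallest vertex-index pair for reproducibility. A PCA
major-axis variant is available (`method="pca"`) for comparison; the chord
definition is the one the rest of the pipeline uses. `projected_max_radius`
— the quantity the margin is added to — is the maximum planar
(chest-wall-parallel) distance of any surface vertex from the centre.

## Implicit-solid guide construction

All guide solids are scalar fields on a regular grid (negative inside),
combined by pointwise min/max and meshed once by marching cubes. The choice
is deliberate: boundary-representation booleans need an exact-arithmetic
engine to stay watertight through repeated subtractions, whereas the zero
level set of a continuous field bounded away from the grid boundary is
closed by construction. The cost is a resolution floor set by the grid pitch
(default 0.5 mm): sharp edges are chamfered by up to about one cell, and
features below ~2 cells do not resolve.

The skin body is the union of the reconstructed breast mesh and the chest
half-space z ≤ 0. Its signed distance is evaluated by projecting onto vertex
normals of the k nearest mesh vertices (inverse-distance weighted, k = 6) —
smooth and accurate to well under the vertex spacing, unlike a binary-voxel
distance transform. A cheap nearest-vertex query bounds the distance
everywhere; the k-NN projection runs only in the band near the surface where
the level sets live.

The shell is the band `0 ≤ d(skin) ≤ t` (t = 3 mm), intersected with the
prism over the plan-view coverage region: the union of a disc around the
resection circle (+20 mm coverage margin), a disc around the nipple hole
(+10 mm pad) and an 18 mm-wide arm from the nipple past the manubrium. An
implicit offset cannot self-intersect, so no repair pass exists or is
needed. Numerical details that matter: the grid origin is dithered by a
fixed irrational fraction of the pitch (axis-aligned feature planes such as
z = 0 would otherwise place the level set exactly on grid nodes and produce
non-manifold marching-cubes output); the field is clamped to ±2 pitch around
the level before meshing (cells further away cannot move the level set, and
clamping prevents degenerate triangles next to sentinel values); twin
vertices within float noise are snapped.

Features are subtractions: a cylinder along the local skin normal at the
nipple (hole diameter 25 mm — not a reported constant; chosen to admit a
nipple comfortably and exposed as a parameter); a triangular prism V-notch
whose vertex sits exactly at the manubrium plan position (the notch shape is
a design choice — only the landmark's incorporation is prescribed); and
`n = 8` channel cylinders (bore 2 mm — sized for an injection needle, also
a parameter) at angles `start + k·360/n` on the resection circle, axes along
the pectoralis normal. Channel entry points are found by bisecting the body
distance along the axis to the outer offset surface. Margin semantics: the
0.5 cm extension is applied radially per side (`radius = r_proj + 5 mm`),
reading "safe margin" as per-boundary; a `margin_mode="diameter"` switch
gives the 2.5 mm-per-side alternative.

## Voronoi lightweighting and the rib guarantee

Eighty seeds are sampled uniformly (triangle-area weighted) over the shell's
outer surface with a fixed RNG seed. The through-thickness void of a cell is
the region where the distance to the second-nearest seed exceeds the
distance to the nearest by at least `w = min_rib + allowance`
(3 mm + 0.35 mm). This carving rule *is* the rib guarantee: for any points p
and q in voids of different cells, the triangle inequality gives
`‖p−q‖ ≥ w` at every depth, so the solid web between voids is at least `w`
wide in 3-D (and a fortiori geodesically). The 0.35 mm allowance absorbs
grid and measurement discretisation so the as-built rib never dips under the
3 mm design bound. The original surface-vs-volume ambiguity of "cells
distributed over the whole volume" is resolved as surface cells extruded
through the 3 mm wall: a 3 mm shell cannot host interior 3-D cells at 3 mm
rib spacing.

Cells whose void would touch an exclusion zone — the coverage rim, the
nipple-hole collar, the notch collar, the channel annulus, each padded by
`min_rib` — are dropped entirely, and cells whose void area falls below
`min_void_area` (8 mm²) are kept solid: near-coincident random seeds
otherwise produce razor-thin sliver voids that neither print nor reduce
weight and that the meshing grid cannot resolve. On the default
configuration 11 of 80 cells survive as voids.

Each void's designed boundary polygon is computed by Newton-projecting
surface samples onto the exact carving level set (residual < 0.05 mm), with
per-point surface normals retained. These polygons feed the brute-force
pairwise-distance oracle and the as-built measurement below.

## QC measurements

Every QC quantity is measured from the output mesh (in the end-to-end path,
from the STL re-read from disk), never echoed from parameters.

*Channels* are detected as plan-raster through-holes inside the resection
annulus whose wall-vertex cylinder fit has a radius within 25 % of the
design bore and an axis within 5° of the pectoralis normal — lightweighting
voids fail both. The measured margin is the Kåsa circle fit through the
detected channel centres minus the tumour's projected maximal radius.

*Wall thickness* is inward ray casting (Möller–Trumbore with a KD-tree
candidate prefilter) from ≥ 1000 surface-sampled points; rays that exit
through holes, voids or the rim are excluded by a hit-validity window and
the median is reported (3.0 ± a few hundredths on the default run).

*Minimum rib* is measured between the as-built void walls: for each retained
void, the mesh vertices at mid-wall depth (0.3–0.8 of the shell thickness
along the boundary normals) within 0.3 mm in-plane of its designed boundary,
then the minimum 3-D distance between wall vertices of different voids.
Mid-depth is measured deliberately: marching cubes chamfers the void lip by
up to a cell, and the stiffness-relevant quantity is the solid web through
the wall, not the chamfered lip. Working along local surface normals means
ribs on the steep dome flank are not foreshortened, which a plan-view
distance transform would suffer from. On the default run the measurement
agrees with the exhaustive polygon-pair oracle to 0.10 mm.

*Slicing* uses plane sections at `z_min + (k+0.5)·layer` (0.1 mm layers);
contours are closed polylines and the reported plane spacing comes from an
actual slicing run.

## Placement-error model

The failure mode of nipple-only registration is rigid rotation about the
nipple's surface-normal axis; no quantitative intraoperative data exist, so
the model is the minimal faithful formalisation and its outputs are
properties of the model, not reproductions of measured values. Single mode
draws `θ ~ Uniform(−15°, +15°)` (ignorance prior over the unconstrained
rotation); dual mode sets `θ = arctan(ε/D)` with tangential landmark noise
`ε ~ Normal(0, 2 mm)` and `D` the nipple–manubrium distance (134 mm on the
default phantom). A channel entry at planar radius `r` displaces by the
chord `2 r sin(|θ|/2)`. Both modes are driven by a common per-trial uniform
quantile, so dual dominance over single can be checked pairwise. Simulated
means are validated against the closed form
`E[d] = (4r/θmax)(1 − cos(θmax/2))` for the uniform law and a numeric
quadrature for the dual law, aggregating per trial because channels share
one rotation. Soft-tissue deformation, breathing and tracking are out of
scope.

## Problem sizes and runtime

The reference configuration is the full-size one: a 1.6M-voxel phantom at
1 mm, a design grid of ~10M cells at 0.5 mm pitch, 80 Voronoi seeds, and
10 000 Monte-Carlo trials; the whole pipeline builds and verifies in about
two minutes on one CPU. Unit tests use a 30 mm phantom on a 0.8 mm grid,
which exercises every stage in a few tens of seconds. Placement statistics
use 10 000 trials, where the 3-standard-error band against the closed form
is a fraction of a percent.

## Known limitations

- The inner surface conforms to the *smoothed reconstructed* breast; on real
  anatomy, skin texture and reconstruction noise would transfer to the fit.
- Channel axes use a single global pectoralis normal (flat chest wall); a
  curved chest wall would need the normal field evaluated per channel.
- The implicit kernel's resolution floor (0.5 mm default) chamfers sharp
  edges; printing at 0.1 mm layers will reproduce those chamfers.
- Lightweighting optimises nothing mechanical: it is patterned material
  removal with a rib constraint, not compliance-constrained topology
  optimisation.
- The embossed tab encodes a 32-bit hash of the ID, not a scannable barcode;
  full metadata lives in the JSON sidecar.
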