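# Methods

`headmodel` builds the geometric inputs of an electrical head model from
structural images: a voxel-wise tissue segmentation of T1-weighted MRI, a
CT bone segmentation, landmark-driven registrations between image spaces
and EEG sensor clouds, and a tessellated cortical surface carrying
equivalent dipoles. This note documents the models and procedures, the
parameters that matter, and the choices made where the design was open.

## Image model and relative thresholding

The observed intensity is modeled as `y_i = b_i * y'_i + rho_i`: a true
tissue intensity distorted by a multiplicative, slowly varying bias field
`b_i` (RF coil shading) and additive noise. Because the bias varies slowly,
the *ratio* of two nearby intensities is nearly bias-free. Relative
thresholding (RT) exploits this: each voxel is compared with a reference
voxel on its *gradient path* — the steepest-ascent chain through
26-neighbors of the smoothed image `z` (Gaussian sigma 1 voxel by default).
Steepness is intensity gain per unit step length, so axis steps beat
diagonal steps at equal gain; remaining ties break lexicographically.

Scheme 1 initializes a region of interest as WM, relabels a voxel GM when a
reference within path distance `d_gw` makes `z_i/z_j < t_gw`, and relabels
a GM voxel CSF when a WM voxel within `d_cw` gives `z_i/z_k < t_cw`
(`t_cw < t_gw`, `d_cw > d_gw`). The thresholds come from an exhaustive
search over a candidate grid (defaults `t_gw` in 0.50..0.95, `t_cw` in
0.20..0.50, step 0.05). The distance defaults are `d_gw = 6`, `d_cw = 12`
voxels: the reference must be reachable across the cortex, which is 5
voxels thick in the default phantom; both are configurable.

Two selection criteria are provided. `rt_objective` is the adjacent-pair
criterion `h = w_w*h_w + w_g*h_g + w_c*h_c`, each term the sum of
`|z_i - z_j|` over same-label adjacent pairs (6-adjacency, unit weights by
default). Because same-label and cross-label pair differences sum to a
constant, minimizing this `h` is algebraically a *maximization of total
boundary contrast*, and on piecewise-constant synthetic images it prefers
ragged cuts through the steepest part of the boundary blur. The default
criterion for `optimize_thresholds` is therefore the within-object
intensity scatter: each class is split into its 26-connected components
(scalp flesh and true WM may legitimately share the WM label while being
distinct objects), and every component contributes its squared deviations
from the component mean. On layered phantoms with a 20 % bias field this
criterion ranks the true labeling first (WM Dice 0.99–1.00); the pair-sum
criterion remains available as `criterion="pair_sum"`.

Scheme 2 (refinement) seeds WM by the absolute threshold maximizing
`f = f_e - f_r` (boundary contrast minus the same number of largest
within-WM contrasts) subject to a minimal seed cardinality (1 % of the
region), then dilates the seed: a frontier voxel joins WM when its
intensity is at least `t_gw` times the local WM reference. The reference is
the local WM intensity *maximum* in a radius-3 window: a mean-based
reference is dragged down by dim voxels accepted at the frontier, which
can cascade into runaway growth through GM; the maximum tracks the bias
field while being immune to that contamination.

Both schemes depend only on intensity ratios, so multiplying the volume by
a global constant leaves every labeling bitwise unchanged.

## Digital topology

Foreground connectivity is 26, background 6. A point is *simple* when its
removal preserves the topology of object and complement; the test uses the
standard topological-number characterization (one 26-component of
foreground in the punctured 26-neighborhood, one 6-component of background
in the 18-neighborhood touching a face neighbor), memoized on the packed
neighborhood configuration. A point is *thick-simple* when it is simple and
its joint removal with any single foreground neighbor leaves component and
tunnel counts non-increasing; the pair test first tries the two sequential
orders (each exact) and falls back to a component/Euler comparison on the
4x4x4 window covering both neighborhoods — a bounded-window interpretation,
since the removal of a pair has no exact local characterization. Euler
characteristics come from the standard 2x2x2-octant weight table for
26-connectivity (verified against `skimage.measure.euler_number`);
`count_topology` reports components, cavities (bounded complement
components) and tunnels = components + cavities − chi.

### Skeletonization

Thinning removes boundary points that satisfy a pass-specific predicate *at
the moment of removal* (sequential re-checking). The schedule, which the
underlying theory leaves open, is: waves gated by the original distance
transform (onion layers — prevents digging pits into the interior), six
directional subiterations per wave (at most one layer per face direction),
and for the curve pass additionally eight parity subfields whose members
are never neighbors (prevents a removal front from unraveling a 2-wide
ribbon end to end). Rejected candidates are cached per direction until a
neighbor changes.

* Thick-surface pass: erode a simple point through face direction `d` only
  where the object is thicker than two voxels along `d` (exposed face with
  two foreground voxels behind it), keeping genuine sheet points (an empty
  opposite face pair plus a contiguous in-plane arc of at least three
  foreground neighbors). Restricting the thickness test to the
  subiteration's own direction prevents shearing through layers thinned by
  other directions. The pass stops exactly at thickness two.
* Thin-surface pass: remove simple points that are neither sheet points
  nor curve ends; the result is one voxel thick.
* Curve pass: remove simple points that are not curve ends (exactly one
  foreground neighbor).

Depth (surface skeleton) and wideness (curve skeleton) are the Euclidean
distance transform of the original object at the surviving voxels — the
local half-thickness. Both skeletonizations preserve (components,
cavities, tunnels) exactly and are idempotent. A flat-capped tube loses
about one radius of length at each end: the medial segment of such a
cylinder genuinely stops a radius short of the caps.

### Topology correction

Cavities are filled. Handles are cut scale by scale: the curve skeleton of
the opening of the object (radius = scale; scale 0 means no opening) is
computed, and a small ball around the lowest-wideness skeleton voxel —
preferring voxels far from thick structure, so the cut lands mid-handle —
is removed whenever recounting confirms the tunnel count drops without
splitting components. If no skeleton cut can break a remaining tunnel
(wide or deeply embedded defects), the tunnel is plugged instead by
morphological closing at growing radius, again accepted only when the
count drops. The output always has zero tunnels and cavities.

## Cell-complex morphometry

The 3-complex of a voxel set has a point per voxel, an edge per
26-adjacent pair, a triangle per mutually adjacent triple and a
tetrahedron per mutually adjacent quadruple. Collapsing 3→2→1 accumulates
`depth(f') = depth(f) + d(f, f')` on the faces remaining from a removed
tetrahedron and `wideness(e') = max(wideness(e'), wideness(e) + d(e, e'))`,
`connectivity(e') += connectivity(e) + d(e, e')` on the edges remaining
from a removed face (`d` = centroid distance). Two scheduling choices were
forced by the structure of clique complexes:

* Free (elementary) pairs often do not exist — in a 26-adjacency clique
  complex every triangle typically lies in two or more tetrahedra. Free
  pairs are used when available (popped shallow-first; the 2→1 stage pops
  free edges by ascending current wideness, so wideness measures distance
  from the complex rim, i.e. local width); otherwise the shallowest cell is
  force-removed. Forced 2→1 removals drop the face only, never an edge, so
  the 1-skeleton's component structure is provably preserved.
* Edge metrics are seeded with the smaller endpoint depth of the *original*
  object (the skeleton's depth field) rather than zero: curve-like skeleton
  regions carry no faces, so zero-seeded metrics would stay zero there and
  bottlenecks could not be ranked against the object's bulk.

The endpoint of the maximum-connectivity edge of the final 1-complex is the
object's center. Bottleneck separation thresholds edge wideness (Otsu by
default) into *cores*; a non-center core is split off only when the widest
path connecting it to the center core pinches below 0.6 times the smaller
core's peak wideness — a false positive hangs on a *narrow* bottleneck,
whereas texture inside one structure does not. Peripheral points follow
their graph-nearest core, and the volume is restored by competitive
geodesic dilation (kept versus removed skeleton seeds), which cannot leak
back through the volume of a cut bottleneck.

## Segmentation cascade

Foreground extraction takes the lowest threshold of a four-class Otsu
split (the air/tissue cut), the largest 26-component, and fills holes.
RT scheme 1 classifies the foreground; WM extraction keeps the connected
component of greatest interior depth (scalp flesh shares the WM label but
is a thin shell), corrects its topology, and applies the cell-complex
bottleneck cut; GM extraction keeps GM-classified voxels whose gradient
path reaches WM within `d_max = 8` voxels. The refinement region
R3 = W1 ∪ G1 is re-segmented with scheme 2, re-extracted (W2), partitioned,
and G2 is extracted against W2. Hemispheres are split by an s-t minimum cut
on the 6-adjacency graph with unit capacities, seeded by the outer-x thirds
of the WM so the cut stays in the central slab; an optional cerebellar cut
uses inferior-posterior seeds. The scalp mask is the filled largest
foreground component; eyeballs are detected as compact quasi-spherical
components of near-constant intensity (sliding intensity windows, roundness
= peak depth over equivalent radius ≥ 0.6) in the anterior non-brain head.
CT segmentation thresholds at 300 / −200 HU (configurable), smooths the
bone shell, and separates the intracranial cavity from the remaining soft
tissue by minimum cut; bone keeps its Hounsfield values as a density
channel. Head-model assembly resolves overlaps with priority
WM > GM > eyeball > bone > CSF > flesh, redefines CSF as the closed brain
envelope minus WM and GM, sets unclaimed in-head voxels to flesh, and
reports whether at least one CSF voxel separates GM from bone everywhere.

## Registration

All similarities are sums of squared landmark-to-contour distances,
evaluated by interpolating the *squared* distance field (smooth across the
contour, where the distance itself has a kink). Rigid coefficients come
from a three-level exhaustive grid search (translation ±20 voxels, rotation
±20°, final steps 1 voxel / 1.5°; near-ties resolve to the smallest
motion, which matters for rotationally symmetric targets). Affine
coefficients start from the rigid optimum and descend the 12 parameters
with a normalized-coordinate numeric gradient plus step halving, finished
by Powell line searches (the numeric gradient stalls on the interpolation
lattice when a parameter mostly slides points along the contour); a second
start from the identity guards against a spurious rigid rotation. The TPS
solves `L W = M` exactly with kernel `r^2 ln r^2` (0 at r = 0); affine
target sets yield kernel weights at numerical zero.

Atlas skull fitting estimates the global thickness ratio from how the
scalp-to-brain gap scales between atlas and subject, capped at the largest
value keeping 90 % of the inner-skull mate landmarks outside the subject
brain mask, with local reductions for the rest; superior targets are scalp
intersections of brain-center rays, posterior-inferior targets use the
same construction on the brain mask (with outer-skull mates placed by the
global ratio) and anterior-inferior targets descend the brain-contour
distance field. Sensor mapping projects each sensor along the brain-center
ray to the outermost scalp crossing; head-to-sensor-space fitting aligns
the cloud (exhaustive rigid, nasion-constrained, or three-fiducial
Procrustes), refines affinely when the residual exceeds one voxel, and
finishes with a TPS taking scalp points to the aligned sensors.

## Surfaces and dipoles

Marching cubes at level 0.5 on the zero-padded mask gives closed
2-manifold meshes (Euler characteristic 2 per genus-0 component).
Inflation moves each vertex toward the area-weighted mean of its incident
triangle centroids (`alpha = 0.5`, 30 iterations by default); on an
icosphere a small residual asphericity (~1 %) remains because penta- and
hexavalent vertices contract at slightly different rates. Dipole patches
come from recursive geometric bisection of the triangle dual graph by
area-weighted median planes along the local principal axis, followed by a
connectivity repair and a bounded rebalancing pass; each patch carries one
dipole at its area-weighted centroid oriented along the normalized
area-weighted normal sum. Unoriented dipole triples are spread through
gray matter by farthest-point sampling. The Talairach transform is rigid
(AC at the origin, AC–PC along −y, mid-sagittal plane at x = 0) followed by
six-piece bounding-box scaling to the standard extents (x ±68, y +70/−102,
z +74/−42 mm).

## Synthetic phantoms

The generator emulates exactly the properties the methods assume:
concentric tissue layers (WM 20 / GM 25 / CSF 27 / skull 31 / flesh 35 mm
by default, 72³ grid at 1 mm so the head fits; the 64³ study grid clips the
outer flesh), T1 intensity ordering bone 20 < CSF 40 < GM 105 < WM 150
(flesh 80, eyeballs 60, air 5, arbitrary units), a bias field summing three
low-frequency cosines rescaled over the brain to the stated range (exactly
[0.90, 1.10] at the 20 % level, linearly scaled otherwise), Rician noise in
signal regions and Rayleigh noise in air with sigma given as a percentage
of the WM mean, optional thin WM handles (staples placed on near-flat
surface patches; every placement is verified to raise the tunnel count by
exactly one, else reverted), and quasi-uniform Fibonacci sensor clouds
(antipodally symmetrized for even counts, so sensors are exactly
equidistant from the cloud centroid) with anatomical-proxy fiducials.

What the phantom does not emulate: cortical folding (the GM shell is
smooth, so segmentation Dice here bounds the easy-geometry regime, not
gyral/sulcal accuracy), partial-volume mixing, tissue texture, ghosting or
motion artifacts, and realistic bias-field shapes (the cosine model is a
smooth stand-in). Passing tests therefore demonstrate correctness of the
mechanisms — bias cancellation, topology handling, metric accumulation,
registration algebra — not clinical-grade accuracy on real scans.

## Numerical choices and limitations

* Problem sizes used by the test suite and the acceptance script: 64³
  cascade phantoms (10 seeds), 48³ handle phantoms (30 corrections), 1e5
  random neighborhoods for the simple-point oracle, 500-landmark TPS
  systems, subdivision-4 icospheres (5120 triangles).
* Determinism: every randomized component takes an explicit seed;
  thinning, collapses and searches use fixed tie-break orders; repeated
  cascade runs are byte-identical.
* The segmentation cascade assumes a single bright, deep WM structure; it
  has no atlas priors and does not label subcortical structures.
* The eyeball detector is shape-based and tuned to quasi-spherical
  homogeneous blobs; it reports not-found rather than guessing.
* Minimum cuts use unit capacities on 6-adjacency edges, so the cut
  minimizes boundary area; anatomically weighted capacities are not
  implemented.
* TPS systems are solved densely; landmark counts are capped (300 by
  default) for conditioning and cost.
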