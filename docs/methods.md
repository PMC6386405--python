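# Methods

## The division model

A mother cell is a set of N lattice sites (voxels) obtained either from a
segmented image or by digitizing a synthetic shape (a voxel is occupied
iff its center lies inside the continuous shape). A division is an
assignment x of every site to daughter 1 or daughter 2. Candidate
divisions are sampled by Metropolis dynamics on

    H(x)/kT = H_V(x)/kT + H_A(x)/kT,

where the volume term enforces a target volume-ratio ρ*,

    H_V/kT = ([V1 − V1*]² + [V2 − V2*]²)^(1/3),   V1* = ρ*·N,  V2* = (1 − ρ*)·N,

with V1, V2 the daughter volumes in voxels, and the interface term
penalizes the area of the division interface by an unweighted facet count
over the 26-neighborhood,

    H_A/kT = α a² Σ_(i,j) 1[x_i ≠ x_j],

with a the area of one voxel facet and α = 2. Discordant pairs are
counted once each (unordered); any factor-two convention is absorbed into
α, whose default is calibrated under the once-per-pair convention. The
26-direction unweighted count is the lattice equivalent of an unweighted
Crofton area estimate; it is orientation-biased (oblique interfaces are
over-counted relative to axis-aligned ones), which is why all *reported*
interface areas are measured on an extracted triangular mesh, never from
the facet count.

Each run starts from an independent random assignment (each site to
either daughter with probability 1/2) and performs single-site toggles: a
uniformly random occupied site is proposed for reassignment, accepted
systematically when ΔH ≤ 0 and with probability exp(−ΔH/kT) otherwise.
One Monte-Carlo cycle is N attempted toggles; the default budget of 5000
cycles reaches convergence on cell-sized masks (10³–10⁵ sites). ΔH is
computed locally (the site's ≤ 26 facets plus the two volume counts) and
is exactly equal to the global energy difference; this is asserted to
1e-9 in the tests.

## Energy-scale calibration (α, a, kT)

The published form of the model fixes α = 2 but leaves two scales open:
the units of the facet area a and the temperature kT. These are not
cosmetic. The volume term is a cube root of squared *voxel counts*, so
its stiffness near the target is absolute (moving one voxel away from
the target costs about 1.26 units); the interface term scales as α·a².
Their ratios to kT determine whether the sampler works at all:

- kT of order 1 with α·a² of order 1 (lattice units): the volume term is
  far too soft. The energy of a collapsed partition (one empty daughter,
  H = H_V ≈ (2(ρ*N)²)^(1/3) ≈ 400 for N ≈ 17000) is *lower* than that of
  any divided partition (H ≈ α·a²·pairs ≈ 10⁴), so asymmetric runs
  deterministically collapse into a single daughter.
- kT ≪ 1 with α·a² ≫ kT: a deep quench; symmetric runs freeze into a
  bicontinuous sponge.

The working regime, used as the default, is

    a = 0.35² μm²  (the facet area at the 0.35 μm reference calibration),
    kT = α·a² = 0.030,

i.e. the interface term contributes one kT per discordant facet while the
volume term contributes tens of kT per voxel of deviation. The ratio
pins to the target essentially exactly, interfaces anneal to clean
near-minimal planes, and the behavior matches the published validation:
symmetric spheres divide along equatorial disks (area within a few
percent of πR², plane through the centroid) and asymmetric divisions
produce flat caps at the exact target ratio. The sampler's internal
scales are deliberately *independent of the mask calibration*: because
H_V counts voxels, tying a to the image calibration would change the
physics with magnification (verified to collapse at side 1 μm). Both a
and kT remain explicit `ModelParams` fields for sensitivity analysis.

Two further numerical choices matter:

- **Half-integer target snapping.** On the lattice, H_V has a cusp at
  V1 = V1*. When ρ*·N is an integer the two lowest states are V1* and
  V1* ± 1 with an energy gap of ≈ 1.26 ≈ 42 kT, so *every* single-site
  toggle is rejected and the initial random mixture freezes verbatim.
  The sampler therefore snaps its internal target to the nearest
  half-integer voxel count (⌊ρ*N⌋ + 0.5), an offset of at most half a
  voxel (ratio error < 1/N), which turns the cusp into a two-state
  corridor of near-zero cost: V1 oscillates between ⌊ρ*N⌋ and ⌊ρ*N⌋+1
  and the interface anneals freely, with the volume exactly conserved up
  to one voxel. The energy-reporting functions (`volume_energy` etc.)
  keep the exact ρ*·N targets; snapping is purely a sampler detail.
- **Initialization.** The default start assigns each site to either
  daughter with probability 1/2. Starting at the target ratio
  (Bernoulli(ρ*), available via `init="bernoulli_rho"`) leaves the
  minority daughter dispersed as isolated sites at asymmetric targets;
  in a few percent of such runs the minority evaporates entirely before
  compact domains form and the run collapses. From the symmetric start
  the minority always holds a percolating reservoir while the volume
  term sheds the excess, and no collapse was observed in repeated runs.

## The 2D variant

For planar (leaf epidermis) geometries the volume term is dropped
entirely: the initial configuration is drawn exactly at the target ratio
(V1 = round(ρ*N), numpy round-half-even) and every move exchanges one
site of each daughter (Kawasaki dynamics), so the ratio is conserved to
the pixel at every step. The interface term uses the 8-neighborhood, the
direct analog of the 26-neighborhood. Exchange partners are drawn
uniformly from each daughter (not necessarily adjacent).

Conserved dynamics at a fixed temperature relax poorly in elongated
shapes: about half the runs end in two or three parallel cuts (a
multi-band local minimum). The default sampler therefore anneals kT
within the same 5000-cycle budget: linearly from 2.2·α·a² down to
0.8·α·a² (slow cooling through the order–disorder region, which is what
dissolves initial bands), then geometrically to α·a²/4. With this
schedule 39–40 of 40 seeded runs reach within 15% of the minimal chord
for a disk, a 4:1 rectangle, and a 3:1 ellipse, on seed ranges disjoint
from those used during development. A fixed temperature is used when
`kT` is set explicitly.
Interface length is reported both as the discordant-pair count × pixel
side (the quantity the energy sees) and as the marching-squares polyline
length; the polyline value is used in rule evaluation because facet
counting overestimates oblique interfaces.

## Plane measurement

The division interface is the 0.5-level surface of the daughter-1
indicator, extracted by marching cubes after filling the background with
the label of the nearest occupied site (so the mother's outer wall
produces no spurious interface); triangles whose centroid falls outside
the mother mask are discarded. Per plane the package reports: total mesh
area; the area-weighted mean facet normal (oriented daughter 1 →
daughter 2; all angles are folded to [0°, 90°] so the convention cannot
affect results); the mesh centroid (closest mesh point to the
area-weighted mean of triangle centroids, i.e. the center of inertia
projected onto the mesh); the anchor distance (exact per-triangle
closest-point projection, not vertex-only, to the mother centroid or a
supplied nucleus centroid); the volume-ratio with either smallest-daughter
or region-based selection; and connected-component counts of both
daughters, used to flag fragmented solutions.

## Morphometrics

Sixteen per-cell features. Volume is the exact site count × voxel
volume. Surface area uses the Cauchy–Crofton formula over 13 lattice
line directions with solid-angle weights from the spherical Voronoi
diagram of the 26 directions; it is accurate to ~1% on digitized balls
of radius ≥ 10 voxels (the estimate of an axis-aligned box is ~10% low —
the residual anisotropy of a 13-direction estimator — while naive facet
counting would be 50% high on spheres). Mean breadth is the integral of
mean curvature of the marching-cubes surface divided by 2π (a few
percent high on balls from staircase dihedrals). The three ellipsoid
axis lengths come from the eigenvalues of the voxel-center covariance
(plus the voxel's own second moment), scaled as for a uniform solid
ellipsoid. The inscribed-ball radius is the maximum of the Euclidean
distance transform. The geodesic diameter runs Dijkstra on the voxel
graph with Euclidean step weights over a knight-augmented (5×5×5)
stencil — metrication error ~2% versus ~7% for the plain
26-neighborhood — with iterated farthest-point sweeps from the
inscribed-ball center (exact for convex shapes, a tight lower bound
otherwise). The three size-ratio shape factors are normalized so each
equals 1 for a continuous ball: 36πV²/S³, S/(πb²), and 6V/(πb³); the
three elongation factors are ratios of the sorted axis lengths;
convexity is V over the volume of the voxel-center convex hull (clipped
to 1); geodesic elongation is the geodesic diameter over the
inscribed-ball diameter.

## Relative measures and the nested rule

To pool plane measurements across cells of different sizes, a candidate
solution x is scored against a reference set S of alternative solutions
by the rank proportion Â(x) = |{x′ ∈ S : A(x′) < A(x)}| / |S| (strict
inequality; ties do not count; a midrank variant exists behind a flag).
Â is invariant under any strictly increasing transform of the measured
quantity, and if x is exchangeable with S it is uniform on
{0, 1/|S|, …, 1} — both properties are tested. Reference regimes:
alternatives at the observed ratio, alternatives at ρ* drawn uniformly
from (0.2, 0.5), and the centroid-constrained subset of the latter
(references passing at least as close to the anchor as the candidate).

The nested rule selects, among candidates whose daughters are both
single connected components and whose anchor distance is below one voxel
side, the candidate of least mesh area; ties break on smaller distance,
then smaller seed, making the choice deterministic and order-independent.
An empty admissible set raises an explicit error (the caller may widen
the ensemble) — never a silent fallback. The one-voxel threshold is the
voxel *side* (0.35 μm at the reference calibration), not the diagonal.
Orientation classes operationalize visual plane classification: the
normal is compared to the radial, axial and tangential directions of the
embryo frame at the cell position, with 30° cones (configurable).

## Embryo simulation

The embryo frame (i, j, k) originates at the centroid G1 of the first
division plane D1: i is the D1 normal, k the projection of the direction
to the suspensor centroid G2 onto D1, and j = i × k; G2 − G1 parallel to
i is a hard error. At the 8-cell stage the four cells with larger
k-projection are apical, the others central, and the label propagates to
descendants; within each 16-cell sibling pair the daughter with smaller
|i|-projection is internal. Projection ties within 1e-9 raise rather
than annotate arbitrarily.

`simulate_embryogenesis` starts from a truncated sphere (default
truncation: a planar cut removing a quarter of the diameter, mimicking
the 1C embryo proper; the exact geometry is a free parameter) and
recursively: runs an ensemble (default 50 runs) at the scheduled ratio
(0.5, 0.5, 0.45, 0.33 for 1C→16C), applies the nested rule with the
cell's mask centroid as anchor (an external nucleus centroid can be
substituted per cell), splits the mask along the chosen partition, and
recurses. There is no growth between generations. A cell with no
admissible solution gets one retry with a doubled ensemble, then the
simulation aborts naming the cell. Master-seed determinism covers the
whole tree; per-(generation, cell) seeds come from numpy SeedSequence
streams, so results are independent of traversal order.

## What the synthetic shapes do and do not show

Spheres, half-spheres, quarter-spheres and truncated spheres have
analytically known minimal bisecting sections, which makes them the
validation substrate: symmetric divisions must find the equatorial disk
(area within 10%, plane within one voxel of the centroid), and the
recursion must produce near-orthogonal successive planes. Real cells
differ in ways these shapes do not probe: wall curvature and
irregularity, segmentation noise at the wall, anisotropic original
voxels, and biological anchors (nuclei) away from the centroid. Passing
the synthetic suite therefore validates the sampler, the measurement
chain and the rule machinery — not the biological claim itself, which
requires segmented embryo images supplied by the user through
`read_label_stack`.

## Problem sizes and budgets

Defaults follow the published protocol (5000 cycles, α = 2, 40–100 runs
per ensemble, 50 runs per division in the recursion). The test suite
scales some experiments down to keep a full run in tens of minutes on
one core: ratio fidelity uses a radius-16-voxel sphere with 10 seeds;
shape validation a radius-12-voxel sphere with 20 seeds; the full 1C→16C
recursion runs once at radius 16 voxels with 10 runs per division; the
orthogonality statistic uses ten radius-10-voxel recursions to the 4C
stage. The compiled Metropolis kernel advances ~10⁷ site updates per
second per core.

## Known limitations

- The sampler is a stochastic minimizer, not an equilibrium sampler of a
  biological ensemble; run-to-run variability is exploration of local
  minima, and its spread has no calibrated biological meaning.
- The interface energy's orientation bias means the *dynamics* slightly
  prefer axis-aligned planes; measurement is unbiased (mesh-based), but
  candidate generation inherits the lattice anisotropy.
- The 13-direction Crofton surface area is ~10% low for near-cubical
  axis-aligned cells; ranking-based analyses are unaffected.
- Recursive simulations reproduce the model's behavior, not observed
  walls: at the 16C stage the internal interfaces of simulated central
  cells tend to parallel the first division plane, where real embryos
  orient them relative to the outer walls — an expected divergence of
  the geometry-only rule.
- No growth, mechanics, or cortical-array (preprophase band) dynamics:
  the model links geometry to plane selection and nothing else.
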