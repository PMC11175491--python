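# Methods

## The model

The package studies an idealized transverse slice of an abdominal aortic
aneurysm (AAA) whose cavity is partly filled by intraluminal thrombus (ILT).
The slice is a circular wall annulus (outer radius `b = 25` mm, thickness
`t = 2` mm), an annular thrombus between the wall inner circle
(`a = b − t = 23` mm) and a circular lumen of radius `r_l`, and a rigid
circular spine (radius 15 mm) tangent to the outer wall on the posterior
side.  The thrombus fraction is defined by cavity area,

    f = 1 − (r_l / a)²,

so the sweep variable `f ∈ [0.2, 0.99]` maps one-to-one to the lumen
radius.  The lumen may be offset 2.5 mm toward the spine (posterior), away
from it (anterior), or laterally (left/right), making the thrombus
eccentric in thickness.  An anterior/posterior/lateral offset of 2.5 mm is
geometrically impossible at `f = 0.20` (the lumen would touch the wall);
such sweep records are retained as failed with an explanatory error rather
than silently dropped.

Both tissues are isotropic, homogeneous and (hyper)elastic under plane
strain.  Two solution modes share one P1-triangle discretisation:

* **linear** — small-strain elasticity with dead pressure loads; used as the
  verification mode against closed forms and as the engine of the
  displacement sweeps;
* **finite strain** — total-Lagrangian St. Venant–Kirchhoff material,
  `S = λ tr(E) I + 2μ E` on the Green–Lagrange strain
  `E = ½(∇u + ∇uᵀ + ∇uᵀ∇u)`, solved by Newton with load stepping; both
  pressures follow the deformed boundary.  This is the mode of the
  wall-stiffness threshold searches, where the loss of an equilibrium
  solution (Newton collapse after automatic step halving down to 1/64 of a
  load step) is itself the measured outcome.

### Loads, support and contact

100 mmHg acts on the lumen lining and 6 mmHg (intra-abdominal pressure) on
the outer surface; 1 mmHg = 133.322 Pa.  Uniform pressure on a closed
contour has zero resultant, so the slice carries no net force.  The spine
is a fixed rigid circle; because the wall (curvature radius 25 mm) is less
curved than the spine (15 mm), contact at physiological stiffness is a
grazing point.  The tangency node is therefore pinned (the vessel rests on
the spine) and a frictionless unilateral penalty (stiffness 1e12 Pa/m on
the deformed gap, weighted by reference arc length) guards the surrounding
arc for large-deformation cases where the wall can wrap the spine.  Penalty
tractions are compressive by construction.  Weak grounding springs (1e−8 of
the largest Young's modulus, per node) regularise the remaining near-rigid
modes; they carry no net load at equilibrium because the pressure loads are
self-balanced.  A `clamp` mode (fix the near-tangent arc) exists for
regression tests, and `none` (springs only) for the axisymmetric
verification cases.

### Discretisation and solvers

The two annular regions are meshed by a transfinite blend between their
bounding circles with a shared angular discretisation, giving a bonded
wall–thrombus interface node-for-node.  The blend is provably
non-degenerate for every admissible geometry (its Jacobian condition
reduces exactly to the lumen-containment inequality).  Quads are split into
triangles with parity-alternating diagonals and the angular count is a
multiple of 16, which makes the mesh exactly symmetric under 45°
rotations (central case) and under reflection about the anterior–posterior
axis — the basis of the probe-axisymmetry and left/right-mirror tests.
Characteristic cell size defaults to 0.4 mm in both tissues (about 5
elements through the wall); the nominal spine cell size of 2 mm is accepted
for interface parity but the rigid spine needs no mesh in this formulation.

The linear mode resolves the contact active set by fixed-point iteration on
the linearized gap (terminating when the set repeats).  Newton uses a
relative residual tolerance of 1e−8 (max 25 iterations per step, 5 load
steps by default), a consistent tangent including the follower-pressure
term, and accepts a warm start; the modulus continuation warm-starts each
decrement from the previous equilibrium, which is both ~10× faster and more
robust near the limit point.  All sparse solves use SuperLU.  Displacements
are reported in metres internally (geometry in mm).

### Measured quantities

`Total deformation` is the nodal |u|; `equivalent elastic strain` is the
von-Mises combination of principal strains (out-of-plane principal strain
zero under plane strain) with effective Poisson ratio 0.5.  The 16 probes
lie on 4 cutting lines at 45° spacing anchored at the **lumen centroid**
(at high fraction with an offset lumen the vessel centre can lie outside
the lumen, so vessel-centred lines would miss the lining); each line meets
the outer wall and the lumen lining twice.  The mean wall displacement is
the arc-length-weighted average of |u| over the outer surface, which is
mesh-independent.  Sweep summaries are reported on the 0.05 fraction grid
without interpolation: the crossover fraction is the smallest grid fraction
at which the sign of (max lining − max wall displacement) differs from its
sign at the smallest converged fraction, and the peak fraction is the grid
argmax of mean wall displacement with ties broken toward smaller fractions.

### Threshold searches

The **critical modulus** search lowers the wall Young's modulus from
1.0 MPa in 0.01 MPa decrements (floor 0.1 MPa) and returns the lowest
modulus whose finite-strain solve still converges; the continuation stops
at the first collapse.  The **minimal modulus** additionally requires the
converged solution to keep the maximum equivalent strain at or below a cap
(default 0.2).  The cap definition is an explicit stand-in for a threshold
that the study's source material leaves undefined; it is configurable, and
cap-bound solutions are a subset of converged ones, so the minimal modulus
is never below the critical one.

## Parameters and defaults

| parameter | default | note |
|---|---|---|
| wall outer radius / thickness | 25 / 2 mm | slice geometry |
| lumen offset | 2.5 mm | all non-central positions |
| spine radius / gap | 15 / 0 mm | tangent posterior circle |
| wall / thrombus Young's modulus | 1.0 / 0.1 MPa | within published AAA wall and ILT ranges; the dominant sensitivity of every emergent result |
| Poisson ratio (both) | 0.45 | near-incompressible soft tissue |
| luminal / abdominal pressure | 100 / 6 mmHg | 133.322 Pa/mmHg |
| mesh size (tissue) | 0.4 mm | ~5 elements through the wall |
| modulus decrement / floor | 0.01 / 0.1 MPa | threshold grid |
| Newton tol / max iters / load steps | 1e−8 / 25 / 5 | collapse = halving below 1/64 step |

## What the sweeps show under these defaults

The solver verifies against the Lamé annulus (0.05% relative L2 at
h = 0.4 mm, convergence order 2.0) and the two-layer compound cylinder
(0.3%).  The emergent study-level behaviour is then fixed by the physics of
a soft compressible thrombus (E = 0.1 MPa, ν = 0.45) inside a stiffer wall:

* the thrombus shields the wall, so the mean wall displacement falls
  monotonically with thrombus fraction (span ≈ 93% of the f = 0.20 value
  for the central case) and every position peaks at its smallest buildable
  fraction;
* the lining displacement exceeds the wall displacement at every fraction
  on the 0.20–0.95 grid; an analytic scan of the compound-cylinder solution
  over E_thr ∈ [0.01, 1] MPa and ν_thr ∈ [0.3, 0.499] shows this ordering
  is invariant in this model family, with a flip only at f ≈ 0.995 where
  the external 6 mmHg compression overtakes the shielded luminal load;
* the finite-strain continuation at the central f = 0.20 configuration
  loses its equilibrium branch at a wall modulus of 0.39 MPa (follower
  pressure outrunning the softening ring), so the critical-threshold search
  terminates at 0.40 MPa rather than the 0.1 MPa floor.

These are faithful outcomes of the stated configuration, reported as
computed; a shielding-free (≤10% span) regime and a lining/wall crossover
inside [0.6, 0.8] would require mutually incompatible material regimes in
this model family, so no single parameter set can produce both.

## Synthetic data: what it emulates and what it does not

The generators stand in for the study's upstream clinical data and always
return their ground truth, so downstream analyses are tested by parameter
recovery:

* **label volumes** — extruded slice geometries rasterized by voxel-centre
  membership (no partial-volume effects, no scanner noise or artifacts);
  optional per-slice lumen jitter and calcification blobs.  Voxelization
  error on the recovered volumetric fraction is ≤0.02 at 0.5 mm voxels.
* **densities** — per-class constants plus a two-component thrombus
  cluster model (means 60/120, HU-like arbitrary units) mirroring a
  bimodal cohort histogram; no texture.
* **paired US/CT fractions** — additive clipped Gaussian disagreement
  (US sd 0.05, CT sd 0.02 by default).  The noise model is a plain choice,
  not an error model derived from data: passing concordance tests shows the
  rank-correlation machinery is correct, not that real US/CT disagreement
  is Gaussian.
* **boundary tracks** — rest contours displaced by a solved FEM field
  scaled with a half-sine cardiac waveform plus optional point jitter; real
  speckle-tracking drop-outs, through-plane motion and probe pressure are
  not modelled.

Consequently, green imaging tests certify the estimators against their own
generative model; they say nothing about segmentation quality or ultrasound
physics on real patients.

## Numerical choices and degenerate inputs

Fraction↔radius round trips are exact to 1e−12.  Meshing raises a quality
error below a 1° minimum-angle floor and solves refuse unconstrained
rigid-body systems.  The Spearman p-value is an exact permutation
enumeration for n ≤ 9 and a t-approximation above; ties take mid-ranks.
Fraction clusters are left-closed/right-open except the last ([0.8, 0.99]
closed); out-of-range values are flagged, not binned.  The per-volume
position index aggregates transverse slices by median (robust to end
slices).  Strain sign convention: expansion positive.

## Known limitations

Plane strain on an idealized circular slice; bonded wall–thrombus
interface; no viscoelasticity, anisotropy, residual stress, calcification
mechanics, or fluid–structure interaction; contact with a single rigid
circle only.  The absolute displacement scale depends directly on the
assumed moduli, which published sources report over wide ranges.
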