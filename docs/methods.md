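# Methods

## Model and conventions

**Joint coordinate systems.** Each articular surface carries an anatomical
coordinate system (ACS): an origin plus right-handed orthonormal axes with
X = LAR (lateral), Y = ABAD (posterior), Z = FE (ventral).  Joint rotations
are intrinsic Z→Y→X Euler angles in degrees, `R = Rz(FE)·Ry(ABAD)·Rx(LAR)`,
with positive FE = flexion, positive ABAD = abduction, positive LAR =
external rotation.  Hard limits are FE, LAR ∈ [−180, 180] and
ABAD ∈ [−90, 90]; poses beyond them are errors, not verdicts, because they
were never sampled.  ABAD = ±90 (gimbal lock) is allowed: poses are compared
as Euler triplets, never as orientations, so orientation-level duplicates at
the locked angle are retained as distinct samples.

**Null pose.** All angles zero; the femur extends laterally (+X of the
acetabular ACS) and the knee is extended so the crus continues along the
femoral axis.

**Joints.** A joint is a fixed translational spacing offset (mm, expressed in
the proximal ACS frame — the "position joint", standing in for unpreserved
cartilage) followed by the Euler rotation (the "rotation joint").  The
rotation center sits at a configurable fraction along the offset:
at the proximal ACS origin, midway between the two ACS origins (the default,
matching a point-constrained center between proximal and distal ACSs), or at
the offset distal origin.  The hip uses the midway center with a cartilage
offset (the reference model uses 10.83 mm lateral, −6.28 mm dorsal); the
hinge knee uses a pure X offset whose magnitude is one of three spacing
hypotheses (20 / 29 / 35.9 mm presets, or 26% of a reference tibial length).
The hinge's translation profile is *constant*: the published prism-based
hinge construction calibrates translations at 45° FE against articular
surface alignment, which a fixed offset reproduces at the measurable level
(stated null-pose ACS separations) but not necessarily at intermediate
flexion angles.  Rotation-dependent translation profiles and translational
DoF sampling are out of scope.

**Viability.** A pose is viable iff the posed distal mesh does not *strictly*
interpenetrate the proximal mesh: some triangle pair properly crosses, or one
watertight mesh contains the other (decided by ray parity after zero
crossings).  Exact surface tangency is viable — grid sampling makes true
tangency measure-zero, and the reference workflow marks poses viable when
"no intersection" is found.  The tolerance separating crossing from contact
is 1e-9 mm.  The original implementation's Boolean-intersection tolerance is
unpublished, so counts for poses within that tolerance of contact may differ.

**Grid.** Half-open intervals [−180, 180) × [−90, 90) × [−180, 180) at 5°
give 72·36·72 = 186 624 unique poses — the unique 5°-grid reading consistent
with that published count, with the duplicate −180°/+180° samples excluded.
FE is the outer loop, LAR the inner; results are independent of traversal
order.

**Alpha shapes.** Viable poses are points in flat ℝ³ (FE, ABAD, LAR degrees):
no cosine correction (volumes are comparative only) and no angular
wraparound (−180 and +180 are distant points, so LAR extremes of a free axis
are reported as the two half-open grid endpoints).  The alpha complex keeps
Delaunay tetrahedra with circumradius ≤ α; the boundary is the set of faces
on exactly one retained tetrahedron, oriented outward.  α is defined strictly
as the maximum circumradius, which may differ from other software's radius
parameterization of the same name.  Containment is closed (boundary counts
as inside) and answered against the tetrahedral complex; after an OBJ round
trip only the boundary survives, and containment switches to ray parity
against the surface — identical verdicts for any query not exactly on the
boundary.  `auto_radius` mirrors the manual protocol: bisect the resolution
lattice (default 0.5°) for the smallest α containing every generating point
(equivalently: every point is a vertex of a retained tetrahedron), then step
through the radii at which the complex changes until the boundary also
passes the cleanliness audit (watertight, edge-manifold, consistently wound,
no self-intersections) — the same requirement the checker's mesh import
enforces.

**Multi-joint checking.** A limb configuration (1–3 joints) is overall
viable iff every configured joint's triplet is inside its shape.  The
nearest-miss distance reported for an inviable joint is unweighted Euclidean
in Euler degrees to the closest boundary vertex — a reporting convenience in
the same uncorrected space, not a metric claim.

**Cross-taxon transfer.** A source rig is uniformly scaled so the distance
from the acetabular ACS origin to the distal crus point equals the target's,
separately per knee-spacing option.  The distal crus point is the
intersection of the crus LAR axis with the plane through the most distal
tibia/fibula vertex; the published tilt of that plane ("about 90 degrees to
the LAR axis") is qualitative, and the orthogonal-plane reading is adopted.
The manual step of posing the target limb to match the source bones is
formalized as weighted landmark least squares over the joint angles
(bounded trust-region, null-pose start, deterministic), with distal segments
weighted 10× by default to encode the stated priority on aligning distal
articular surfaces — an automation of the published manual protocol, not a
reproduction of it.  `match_pose` takes both bone-local landmark coordinates
and their world targets, since recovering a configuration requires the
correspondence, not only the target positions.

## Synthetic fixtures: the stated world

The fossil photogrammetry meshes behind the published per-joint pose counts
are not redistributable, so the test bed is a pair of parametric joints whose
collision boundary has a closed form; the closed form *is* the ground truth
the sampler is held to, exactly, at every grid point.

**Socket.**  Proximal: a spherical shell cup (inner radius 10 mm = 9.5 mm
head + 0.5 mm cartilage clearance, 2 mm thick) covering polar angles from
the rim half-angle to 180° about +X.  Distal: the femoral neck as a cylinder
(radius 0.5 mm, length 16 mm) from the joint center along +X — the head
itself is omitted because with positive clearance it can never touch the
cup.  Viability: neck-axis excursion θ = acos(cos FE · cos ABAD) ≤
rim − asin(r_neck/R_cup) (LAR-free).  Default rim 60° gives a 57.13° stop;
rims 30/60/80° are the test set.  Grid samples sit ≥ 2° from the stop while
mesh discretization (32×12 cup, 24-gon neck) perturbs the boundary by
< 0.2°, so mesh sampling and closed form agree exactly on the grid.

**Hinge.**  Distal: a rectangular bar (12 × 2·2.4 × 2·0.6 mm along X).
Proximal: a tall C-ring around Z whose opening arc is the trough (default
120°, the FE stops) and two full-disk clearance plates at |z| ≥ 2.3 mm (the
ABAD/LAR stops); ring and plates interpenetrate by design (union semantics —
the bar collides if it hits either).  Exact predicate: plate term
`L·|sin ab| + |cos ab|·(w·|sin lar| + b·|cos lar|) > gap`, ring term
`|fe| + asin((w·|cos lar| + b·|sin lar|)/R_ring) > arc/2` — the axes couple,
so per-axis "stops" (FE 36.4°, ABAD 8.2°, LAR 54.7° at default geometry) are
derived from the closed form by 1-D scans, not assumed separable.  Two
consequences a user should expect: (i) the bar is symmetric under a half
turn, so LAR near ±180° is legitimately viable again — the clearance
threshold is the edge of the contiguous band around zero, and the gap is
deliberately smaller than the bar half-width so that band stays closed
through ±90°; (ii) the viable region is a wedge whose ABAD thickness pinches
to zero as |LAR| grows, so the viable cloud is mostly planar: at a 15° step
it is exactly coplanar (rejected by design — degenerate sets are refused,
not extruded), and even at 5° its thin margins force `auto_radius` up to the
convex-hull-equivalent radius.  That is the correct answer under the
wrapping criterion, not a defect, but it means a green hinge wrapping test
establishes containment, not tightness.

**Toy limbs.**  Box pelvis plus cylinder femur/tibia/fibula with
proximodistal lengths in prescribed ratios (reference sets: 0.92/0.62/0.98
for the large-bodied taxon at 100 mm pelvis; 0.62/0.57/0.85 for the
salamander-proportioned rig at 30 mm), hip and hinge-knee joints at
geometric centers.  Deterministic; the `seed` field exists for optional
surface jitter and defaults to exact geometry.  These rigs exercise
kinematics, scaling, and landmark matching — they are not morphologically
realistic, so green tests establish the geometry/kinematics machinery, not
any anatomical claim.

What the fixtures do *not* emulate: real articular surface geometry
(concavities, incongruence), cartilage deformation, ligaments, translation
profiles, mesh noise from photogrammetry.  A green fixture suite therefore
validates the sampling/wrapping/checking machinery against exact ground
truth; it does not validate anatomical inferences for any real taxon.

## Numerical choices

- Collision tolerance 1e-9 mm; coplanar triangle pairs are tangent, never
  crossing.  Ray-parity uses fixed irrational-ish directions with up to 8
  retries on grazing hits; an unresolvable parity during sampling is treated
  conservatively as contact.
- The per-pose sweep precomputes candidate triangle pairs by
  radial-interval overlap about the rotation center (sound because rotation
  preserves every vertex's distance to the center), then AABB-rejects and
  runs an exact interval triangle test per pose in a numba kernel.  Results
  are bit-identical regardless of evaluation order; there is no parallelism.
- Delaunay triangulation of degree grids is maximally degenerate
  (cospherical 4-tuples everywhere); a deterministic symbolic perturbation
  (seeded jitter, 1e-9 of the bounding-box diagonal ≈ 4e-7 degrees) resolves
  it.  Containment queries use a 1e-6-degree closed tolerance, far below the
  grid step and far above the jitter.
- Circumradii come from the linear circumcenter system; tetrahedra with
  |det| < 1e-12 are treated as unretainable (the jitter makes them rare).
- `summarize_rom` tie-break: among poses achieving a per-axis extremum,
  report the one minimizing the sum of absolute companion angles, then the
  lexicographically smallest triplet — one printed pose per extremum
  requires *some* deterministic rule, and this one favors the least-coupled
  companion pair.
- Units: mm and degrees everywhere; loaders accept a unit flag
  (mm/cm/m) and normalize to mm.

## Design choices where the design was open

- Rotation-center placement (`midway` default) is configurable because the
  double-joint rig pattern fixes the *order* (position then rotation) but
  not the pivot; the hip's point-constrained midpoint generalizes cleanly.
- The checker evaluates the tetrahedral complex rather than the exported
  boundary mesh (the reference GUI's choice is unknowable); round-trip
  consistency between the two is guaranteed and tested.
- The interactive red/green feedback is replaced by a machine-readable
  verdict table; headless testability over interactivity.
- Mesh repair is deliberately absent: repair changes geometry and hence RoM;
  validation only reports flags.

## Known limitations

- Only fixed spacing offsets; no translational DoF sweeps, no
  rotation-dependent hinge translation profile.
- Euler-space volumes are not cosine-corrected; they are comparable between
  runs of this package, not across methods that correct.
- Alpha-radius semantics (max circumradius) may differ numerically from
  other alpha-shape implementations at the same nominal radius.
- `meshes_intersect` requires watertight, consistently wound inputs; the
  validator reports problems but never fixes them.
- On mostly-planar viable clouds the wrapping radius degenerates toward the
  convex hull (see the hinge fixture above); alpha shapes are only
  informative for fully 3D pose clouds.
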