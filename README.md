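# osteorom

Osteological range-of-motion (RoM) estimation and multi-joint limb pose
viability for articulated bone meshes.

## The problem

In virtual paleontology and comparative biomechanics, the mobility of a fossil
joint is commonly reconstructed by rigging digitized bone meshes as a
forward-kinematic chain and exhaustively posing each joint over a grid of
Euler rotations — flexion–extension (FE, about Z), abduction–adduction (ABAD,
about Y) and long-axis rotation (LAR, about X), applied intrinsically in
Z→Y→X order.  A pose is *osteologically viable* iff the articulating bone
meshes do not interpenetrate.  The viable poses of one joint form a point
cloud in Euler space (FE, ABAD, LAR in degrees); wrapping that cloud in a 3D
**alpha shape** (the tetrahedra of the Delaunay tetrahedralization with
circumradius ≤ α) yields a queryable envelope of the joint's pose space,
including its concavities and the interactions between degrees of freedom.

The step beyond single joints is the point of this package: a whole **limb
configuration** (e.g. hip *and* knee poses taken from an extant animal's
walking stride) is viable only if *every* joint's Euler triplet falls inside
that joint's envelope.  `osteorom` implements the full workflow:

1. **geometry** — OBJ/STL/PLY mesh I/O, watertight/manifold validation, and a
   strict triangle-crossing + ray-parity interpenetration test;
2. **kinematics** — anatomical coordinate systems (ACS), the Z→Y→X Euler
   convention, hip/hinge-knee joint definitions with fixed cartilage-spacing
   offsets, forward kinematics of the pelvis–femur–crus chain;
3. **rom_sampler** — exhaustive half-open grid sampling
   ([−180, 180) × [−90, 90) × [−180, 180) at 5°, i.e. 72·36·72 = 186 624
   unique poses) with per-pose collision testing and per-axis extrema
   summaries;
4. **pose_space** — alpha complexes over viable pose clouds, automatic radius
   selection ("grow α until the shape wraps every viable pose with a clean
   boundary"), closed containment queries, OBJ round trips;
5. **config_checker** — per-joint and overall verdicts for 1–3 joint limb
   configurations;
6. **transfer** — cross-taxon uniform scaling (matching the acetabulum-to-
   distal-crus length), ACS alignment, and landmark-based pose recovery;
7. **fixtures** — synthetic socket and hinge joints whose viable pose space
   has a closed form, plus toy limbs with prescribed segment proportions —
   the analytic test bed standing in for fossil photogrammetry meshes.

## Worked example

Sample a synthetic ball-and-socket joint (cup rim half-angle 60°, neck
angular half-width 2.87°, hence an analytic excursion stop of 57.13°) on the
full 5° grid, wrap the viable poses, and check reference walking
configurations:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (abridged):

```
grid: 186624 poses at 5 degree steps
socket joint: 30888 viable poses (analytic stop 57.13 deg)
hinge joint: 1058 viable poses (FE stop 36.42 deg)
hip alpha shape: radius 4.5 deg, 198854 tetrahedra, wraps all poses: True
  hip FE: max 55, min -55
  hip ABAD: max 55, min -55
  hip LAR: max 175, min -180
reference configuration verdicts (fixture joints, not fossils):
  mid_swing: hip=1 knee=1 overall=1
  mid_stance: hip=1 knee=0 overall=0
shape-vs-collision agreement (hip, n=1000): 1.000
```

Reading the numbers: the sampled viable FE/ABAD extremes (±55°) sit within
one grid step below the closed-form 57.13° stop; LAR is unconstrained for a
rotationally symmetric neck, so its extremes are the half-open grid endpoints
(175 / −180).  The mid-stance knee pose (101° flexion) exceeds the toy
hinge's 36.4° trough stop, so that configuration is flagged inviable at the
knee — exactly the per-joint feedback the multi-joint checker exists to give.

The same stages are exposed as a CLI:

```sh
osteorom make-fixtures --kind socket --rim-angle 60 --out fixtures/
osteorom sample-rom --config fixtures/rig.yaml --joint socket --step 5 --out hip_viability.csv
osteorom build-shape --viability hip_viability.csv --radius auto --out hip_shape.obj
osteorom check-pose --rig fixtures/rig.yaml --shape socket=hip_shape.obj \
    --config poses.csv --out verdicts.csv
osteorom run --kind socket --step 15 --radius auto --out runs/demo --seed 0
```

## What `scripts/acceptance.py` does

It re-runs the package's primary computation from scratch at the stated
operating conditions: builds the synthetic fixtures, samples both joints over
the full 5° grid with collision testing, auto-selects alpha radii, verifies
the wrapping property, summarizes per-axis extrema, evaluates the four
reference limb configurations through the multi-joint checker, and
cross-validates shape containment against the recorded collision flags on
seeded random poses.  The `--seed` argument drives every stochastic step.
Published joint-specific pose counts depend on fossil photogrammetry meshes
that are not redistributable, so the script reports no reference-value
targets; the test suite (`tests/test_acceptance.py`) instead holds the
pipeline to exact combinatorial and closed-form analytic ground truth.

See `docs/methods.md` for the model conventions, parameter defaults,
numerical choices, and known limitations.
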