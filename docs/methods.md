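# Methods

`hipsim` simulates the bony range of motion (ROM) of a hip joint from
triangulated femur and pelvis surface models, the way CT-based dynamic
impingement software operates in the clinic: reorient the femur along a
clinically defined motion, check the bone models for collision at every
step, allow a small corrective translation of the femoral head, and
register the angle at which impingement halts the motion.  This note
describes the model, its parameters, the synthetic phantom used to
validate every stage, and the numerical choices behind them.

## Joint model and pose parameterization

Anatomical frames follow the International Society of Biomechanics
conventions.  The pelvic frame takes Z along the inter-ASIS line (toward
the subject's right), X anteriorly in the plane of the two ASIS and a
posterior midline point, and Y = Z x X superiorly; the femoral frame
takes Y along the shaft from the epicondyle midpoint to the hip rotation
center, with Z toward the subject's right in the epicondylar plane.  The
hip rotation center comes from a least-squares sphere fit to the femoral
head surface, optionally refined so the head-to-acetabulum clearance is
as uniform as possible over the covered directions (the equidistant
criterion); the refinement minimizes the spread of cup-point distances
about the candidate center, starting from the algebraic sphere fit.

A pose is (flexion, abduction, internal rotation) in degrees: flexion
about the pelvic Z axis, abduction about the pelvic X axis, and axial
rotation about the femoral Y axis, composed in that fixed order with the
axial rotation intrinsic (about the already-reoriented femoral axis).
The composition order is a configuration field so its sensitivity can be
tested.  All rotations pivot at the hip center.  Positive angles follow
the clinical motion names on both sides (positive flexion is anterior,
positive abduction lateral, positive internal rotation turns the
anterior thigh medially); the `side` flag maps these onto right-handed
rotations about the shared axes.

## Collision checking and the corrective translation

Contact queries run on an axis-aligned bounding-box tree per mesh with
exact triangle-triangle feature distances at the leaves and an exact
crossing test for overlapping triangle pairs.  A pose is *free* when no
triangle pair crosses (and neither closed mesh contains the other).
When disjoint, the reported separation is the true minimal
surface-to-surface distance (verified against an exhaustive all-pairs
oracle on small meshes); when colliding, the reported value is the
negative of a penetration-depth estimate — the maximum distance from
penetrating vertices of either mesh to the other's surface, found by
flood-filling outward from the crossing faces with generalized-winding
inside tests.  This estimate is deliberately cheap rather than an exact
minimal-translation depth; bone-on-bone overlaps in a sweep are shallow.

When a reorientation collides, up to `max_translation` (default 3 mm) of
femoral-head translation may be applied.  The resolver operationalizes
the equidistant criterion as *maximize the minimal clearance* over the
translation ball: a deterministic line search along the
penetration-extraction direction, an axis-direction fallback, a
golden-section refinement, and a short subgradient polish.  A resolved
pose must reach a clearance of at least the contact tolerance (default
0.1 mm, which doubles as the contact-reporting band).  If no translation
within the cap achieves that, the pose is *impinged* and the sweep
halts.  The correction is re-solved independently at every candidate
pose (no warm-start coupling), so endpoints are path-independent.

Endpoint search: a coarse sweep at 2 degrees followed by bisection on a
0.1-degree grid, so the registered endpoint is the largest grid angle
that is free or resolved while one resolution step further impinges.
The 0.1-degree resolution matches the rotational resolution of the
electromagnetic tracking systems such simulations are validated against.
Sweep bounds default to 150 degrees of flexion and 90 degrees of
abduction / internal rotation; they are configuration, not anatomy.
The standard examination set is six motions: maximal flexion, maximal
abduction, and maximal internal rotation at 0, 30, 60 and 90 degrees of
flexion.

## The synthetic hip phantom

Real validation of such software used cadaveric hips with artificial cam
deformities; those CT datasets are not public.  The phantom substitutes
an analytically tractable joint with the same task structure:

- a spherical femoral head (radius 25 mm) concentric in a spherical
  acetabular cup shell with uniform clearance `c` (2 mm, a realistic
  cartilage-space figure), covered to a rim polar angle of 60 degrees;
- a cylindrical neck (radius 11 mm, along an axis 172 degrees from the
  cup pole at neutral), a coaxial shaft stub, and marker beads at the
  epicondyles, greater trochanter and pelvic landmarks;
- registration fiducials laid out like surgical K-wires, the pelvic pair
  30 mm apart;
- an optional cam: a spherical-cap bump proud of the head-neck region,
  default 5 mm footprint radius and 3.5 mm height — the geometry of the
  nylon screw heads used to induce artificial cams — placed in the
  anterosuperior 11-2 o'clock band (default 1:30, 45 degrees from the
  neck axis).  The profile is measured in geodesic arc length on the
  head sphere and applied as radial vertex displacement, which keeps the
  mesh watertight.  A `screws` mode generates two discrete cylindrical
  studs instead, at the cost of overlapping solids.

Defaults were chosen once, from the closed-form geometry, so the six
native endpoints land in a clinically plausible pattern (flexion ~114
degrees, internal rotation at 90 degrees of flexion ~47 degrees,
abduction and low-flexion rotations reaching their sweep bounds) and the
default cam restricts deep-flexion internal rotation and abduction —
mirroring how anterosuperior cams present.  With the default tessellation
the head uses icosphere subdivision 4 (one extra level under a cam, whose
clearance boundary needs finer sampling than the bare sphere).

### Closed-form ROM oracle

Because head and cup are concentric, both impingement mechanisms have
closed forms.  Let `p` be the cup pole, `tau_neck = coverage +
asin(r_neck / R_cup)`.  The neck impinges when the angle between the
(swept) neck axis and `p` falls to `tau_neck`; for a sweep about a fixed
axis `w`, `cos psi(phi) = A cos phi + B sin phi + C` (Rodrigues), so the
first crossing is solved in closed form.  The cam impinges when its
*super-clearance* disc — the region of the bump prouder than the
clearance, of geodesic half-width `gamma = s_c / r_head` with
`d(s_c) = c` — reaches the rim circle, i.e. when the cam-apex direction
comes within `coverage + gamma` of the pole; the same crossing formula
applies.  The endpoint is the earliest of the two mechanisms, capped at
the sweep bound.  For the textbook in-plane case this reduces to
`neutral_offset - coverage - asin(r_neck / R_cup)`.

The closed form is itself pre-validated against an independent dense
sampler that marches the sweep at 0.01 degrees for the neck and solves,
per densely sampled point of the displacement field (no disc geometry
involved), the angle at which that point enters the covered region;
agreement is within 0.02 degrees across randomized phantoms.

The oracle models the *uncorrected* sweep.  With a 3 mm translation cap
the engine legitimately reaches further (shifting the head within the
2 mm clearance postpones neck-on-rim contact by roughly
`(c - tolerance) / R_cup` radians), so engine-vs-oracle agreement is
always assessed at `max_translation = 0`; the cap's semantics are tested
separately (monotonicity in the cap, and a constructed pose that needs
5 mm of separation: unresolvable at 3 mm, resolvable at 6 mm).

## Synthetic CT and segmentation

The CT stage emulates the validation scan protocol: 0.265 mm in-plane
pixels, 1.0 mm slices.  Voxelization is exact scanline parity per closed
mesh with 2x supersampling and block averaging, producing true
partial-volume fractions at boundaries; intensities are relative
densities (air 0, soft tissue 1.0, nylon 1.15, bone 1.9 — nylon vs bone
as in the physical experiment; a linear density-to-HU map exists but is
off by default).  Each voxel takes the densest enclosing material, so
the bone core keeps bone intensity under the nylon cam mantle.  A
soft-tissue envelope surrounds the bones; this matters because it puts
the 50% partial-volume point of the bone boundary at the midpoint
threshold 1.45, making the reconstructed surface nearly unbiased.

Segmentation resamples the intensity volume to an isotropic 0.5 mm grid
(cubic interpolation — linear smears the rim edge noticeably), takes
bone at `threshold >= 1.45`, optionally adds a nylon intensity band to
reproduce the paired "with cam / without cam" bone models from a single
scan, splits connected components, and iso-surfaces each with marching
cubes.  The nylon band needs one guard: partial-volume averaging coats
*every* bone surface with a thin nylon-density skin that can bridge the
2 mm joint space at 1 mm slice spacing, so a one-voxel morphological
opening keeps only the thick nylon core (the actual cam mantle) before
the band joins the bone field.  Round trip fidelity on the default
phantom: endpoints re-simulated on segmented models stay within 1.0
degree of the mesh-direct endpoints, dominated by rim-edge rounding from
the 1 mm slice direction; component volumes agree within a few tenths of
a percent.

## Impingement localization and virtual resection

At a blocked pose the impinging area is every femur/pelvis face pair
within the contact tolerance; zones carry their summed femoral area and
an area-weighted centroid expressed on the radiological head-neck clock
face (12 superior, 3 anterior on a right hip, mirrored on the left,
measured about the neck axis).  Aggregation over a motion set unions the
zones at each motion's first blocked pose and tracks per-face maximum
penetration depth.

The resection estimator carves per-vertex depth along inward vertex
normals — mimicking arthroscopic burring normal to the bone — and
re-simulates until every target motion reaches its target angle.  At
each blocked station (2-degree spacing up to the target) it flood-fills
outward from the actually colliding faces while the clearance deficit
persists, so the carve covers the whole prominence but stops where the
joint space returns to normal; native contacts, such as the neck at its
own endpoint, are never burred.  The carve margin defaults to the
articular clearance of the uninvolved joint (median femur-to-pelvis gap
at neutral, floored at the contact tolerance): the prominence is burred
back to the equidistant joint space, which is what "dissolving" the
impingement means clinically, and which makes the removed volume
commensurate with the deformity itself (the default cam resects to
within ~10% of the spherical-cap volume pi h (3 a^2 + h^2) / 6).  Passing
`margin=config.contact_tolerance` instead yields the minimal un-snagging
carve (~30% of the cap volume on the default phantom).  Removed volume
is measured by watertight-mesh volume difference, with a 0.25 mm voxel
parity fallback if carving ever breaks watertightness.

## What the phantom does and does not show

The phantom shares the real task's structure — collision-limited motion,
a dose-controlled deformity, paired imaging, fiducial registration — but
its surfaces are analytic.  Passing the suites demonstrates that the
engine's geometry, search, imaging and comparison layers are correct to
stated tolerances; it does not demonstrate robustness to real anatomy
(aspherical heads, osteophytes, segmentation artifacts from real CT
noise and beam hardening), soft-tissue constraints, or in-vivo
kinematics.  Detection sensitivity on the synthetic cohort is reported,
not asserted: the published cadaveric sensitivity (12 of 13) reflects a
specimen set and tracker reference that cannot be regenerated here.

## Numerical choices, determinism and problem sizes

- All lengths are millimetres and all angles degrees at API boundaries.
- Contact tolerance 0.1 mm serves as both the contact-reporting band and
  the minimum clearance a resolved pose must achieve; whether the
  published 0.1 mm figure meant tolerance or reporting resolution is
  ambiguous, so one configurable parameter covers both uses.
- Degenerate faces are dropped at load (and at marching-cubes output),
  never silently mid-pipeline.
- Everything is deterministic: the resolver's multi-starts are fixed,
  sweeps contain no randomness, and repeated runs produce bitwise-equal
  endpoints.  Randomized suites draw phantom parameters from seeded
  generators.
- Test and validation runs scale the work to the check: reduced
  tessellation (icosphere subdivision 3) for sweep-semantics suites,
  full default resolution for oracle-agreement, imaging and resection
  suites, and a cropped scan extent (the joint region) for the CT
  roundtrip.  These sizes are recorded in the scripts that use them.

## Known limitations

- Penetration depth is a vertex-based estimate, not exact EPA depth.
- The translation resolver is a deterministic heuristic; it can in
  principle under-estimate the reachable clearance (it never
  over-estimates, and the cap is always respected).
- The analytic oracle requires a concentric sphere-in-sphere joint and a
  single-axis sweep from a collision-free start; the engine itself has
  no such assumptions.
- Clock positions are well-defined only for points off the neck axis,
  with the axis not parallel to the superior direction.
- The `screws` cam mode produces overlapping solids whose summed mesh
  volume double-counts the embedded portion; use the smooth cap profile
  when volumes matter.
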