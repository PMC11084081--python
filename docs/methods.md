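# Methods

## Model

The limb is treated as a static serial chain under gravity. One
right-handed Cartesian frame is used throughout, meters, `+z` up, gravity
`(0, 0, -g)` with `g = 9.81 m/s²` by default (configurable). Three joints
are modeled as centers of rotation:

- **coxofemoral** — center of a sphere least-squares fitted to femoral-head
  surface points. The fit is algebraic (linear in `(c, r² − |c|²)`), then
  polished by geometric least squares on the orthogonal distances; exact
  sphere data is recovered to ~1e−10 relative. Fewer than four points or a
  coplanar set raises a degenerate-input error.
- **femorotibial** — arithmetic midpoint of the lateral and medial femoral
  epicondyles (coincident epicondyles return that point with a warning).
- **femoropatellar** — in standing, the complex joint is reduced to a
  supplied patella–femur contact point; its construction is input data,
  not computed here.

Muscles and ligaments are line actuators: one force magnitude along a unit
line of action, normally the origin→insertion chord. Curved muscles whose
resultant near the insertion deviates from the chord (biceps femoris,
semitendinosus, semimembranosus) carry an explicit near-insertion
direction override. Broad insertions (tensor fasciae latae) are modeled as
one actuator whose single magnitude is split over up to three attachment
points by weight fractions summing to 1 (equal split by default — the
anatomical split is not known). Which joints an actuator spans is explicit
input data rather than inferred from geometry: span determination from
attachments and lines of action is an anatomical judgement, and silent
inference would be error-prone.

## External loading and net joint moments

Standing loads are the vertical GRF `(0, 0, +f·m·g)` at the hoof contact
(`f = 0.20` of body weight per hindlimb by default) and per-segment
gravity `(0, 0, −w_s·m·g)` at each segment's center of mass. The five
hindlimb subunits (thigh, crus, metatarsus, hind pastern, hind hoof) carry
editable default mass fractions (3.35%, 1.45%, 0.55%, 0.35%, 0.25% of body
mass), shipped as the `nauwelaerts_defaults`-style configuration; they are
order-of-magnitude equine values chosen once and exposed as configuration,
since published segmentation tables vary by breed and method.

The net moment about a joint is `Σ (p − c) × F` over all external forces
applied **distal** to that joint: the GRF and every below-stifle segment
load the hip and the stifle, while the thigh's own weight contributes only
to the hip moment — standard inverse-statics bookkeeping for a serial
chain. The femoropatellar net moment is fixed at zero (the patella has
negligible gravitational influence). The actuators must produce the
negated external moments; a cross product `τ × r̂` (lever from joint
center to attachment × unit line of action) gives each actuator's moment
per newton, and the same product order is used for external moments, so
the balance system is sign-consistent regardless of the convention chosen.

## Static optimization

Cost: `U = Σ (F_i / PCSA_i)³`, the cubic muscle-stress (efficiency)
criterion. Bounds:

| rule | floor | cap |
|---|---|---|
| muscle (tonus) | 1% of max isometric force | max isometric force |
| superficial digital flexor | max(tonus, 90% of GRF magnitude) | max isometric force |
| ligament | 0 | configured cap (`f_max`) |

Bounds keep `F ≥ 0`, where the cubic is convex and monotone — no modulus
is needed and any KKT point is the global optimum. Ligaments enter `U`
through an effective PCSA; this is a documented modeling assumption (their
transfer forces are essentially determined by the balance constraints and
the muscle costs).

Numerics: the problem is conditioned by optimizing activations
`a_i = F_i / (PCSA_i · σ₀)` with a nominal muscle stress `σ₀ = 0.3 MPa`,
keeping gradients near unit scale. The equality system is first reduced to
full row rank by SVD (a target-moment component outside the row space is
reported as linear infeasibility); box-feasibility is established by
linear programming, and an infeasible instance raises an error carrying a
minimal-residual certificate from bounded least squares. The solve runs
SLSQP from the deterministic bound-midpoint start, then an active-set
Newton polish on the KKT system (diagonal Hessian `6a`) drives the
projected gradient to machine precision; multiplier signs at active bounds
are checked and wrongly-active bounds released. Convergence is declared
only with scaled moment residual ≤ 1e−8 and relative projected-gradient
(KKT) residual ≤ 1e−6; both are reported on the results object. Duplicated
actuators (identical columns and PCSA) split force equally by strict
per-coordinate convexity plus the deterministic start.

`brute_force_oracle` is an independent reference for ≤ 4 actuators: it
parameterizes the equality-feasible affine set, grid-scans the null-space
coefficients over a box-diameter range, and refines the best candidates
with a generic local minimizer in the reduced space. It shares no code
path with the production solve beyond the matrix itself.

## Contact forces and derived reports

`F_contact = Σ F_segmental + Σ F_muscles`: the intersegmental force (sum
of external forces distal to the joint) plus each crossing actuator's
force along its global effective direction (a per-joint-side direction is
possible via attachment overrides but the global direction is the
default). Contact force is reported as the vector acting on the proximal
bone from the distal side, plus its magnitude. Because static optimization
cancels antagonistic co-contraction, contact magnitudes are systematic
underestimates; the tonus floors reduce but do not remove this bias.

Group sums are plain arithmetic over named members. Safety factors are
`|yield| / |peak stress|` rounded half-up to one decimal, matching the
conventional reporting precision; peak stresses are inputs from an
external FEA, never computed here.

## FEA load case

Entries: femur-attached actuators with force **strictly** greater than the
threshold (100 N default — about 10 kgf, below which stress distribution
and fixation stability are insensitive). Each entry carries the force
vector, a symbolic attachment-area label (the FEA consumer owns the actual
area polygons) and a uniform-distribution tag. Boundary conditions ship as
metadata: medial condyle fixed, lateral condyle constrained
proximal-distal and anterior-posterior, leaving medial-lateral strain free
to avoid static overdetermination. Hip and patellofemoral contact forces
can be attached as optional load entries; the femorotibial contact is
represented by the bearing constraints instead. JSON export is
schema-versioned and byte-deterministic; a flat CSV mirrors the entries.

## Synthetic limbs

`synthetic.generate(seed, n_actuators=20)` emulates the real inputs'
structure: a hip–stifle–patellofemoral chain, ~20 actuators with lever
arms drawn in 0.02–0.15 m, PCSA in 1e−3–2e−2 m², `f_max = σ_max · PCSA`
with `σ_max = 0.3 MPa` (forces on the 10²–10³ N scale), body mass 514 kg
and a 20% hindlimb weight fraction. Target moments are constructed as
`A · F_ref` from a reference force vector drawn strictly inside the bounds,
so every instance is feasible by construction — gravity-derived moments
can be unreachable under the tonus floors, which is why a separate
`mode="gravity"` exists for exercising the statics path. All randomness
flows through `numpy.random.default_rng(seed)`; the same seed reproduces
the instance bit-for-bit.

What passing synthetic tests show: the assembly, solver, certificates and
export behave correctly on problems with the assumed structure and scale.
What they do not show: anatomical fidelity — no wrapping surfaces, no
joint-angle dependence, no co-contraction, single-point attachments; real
attachment coordinates, PCSAs and maximum isometric forces must come from
measured geometry tables.

## Problem sizes and checks

The shipped checks run 50 oracle comparisons on 4-actuator instances and
200 full-size (20-actuator) solves, completing in seconds; the solver's
worst observed objective gap against the oracle is ~1e−13 relative and the
worst scaled moment residual ~1e−14. Desk-scale report arithmetic
(quadriceps sum 951 N; safety factors 3.1 and 5.0; the 907.7 N
superficial-digital-flexor floor vs its 905 N solved force; the
eight-muscle femoral load case) is recomputed from the shipped input
tables. Reproducing the full standing solution (net moments of 104 and
109 N·m and the per-muscle force table) additionally requires the measured
geometry and load supplements, which are not bundled; the pipeline
implements the complete path for users who have them.

## Known limitations

- Statics only: no inertial terms, valid for quiet standing.
- Single-point attachments and straight lines of action (one optional
  near-insertion override) — no wrapping or tendon-excursion moment arms.
- The patellar locking mechanism of the equine stifle is not modeled; the
  patellar muscles compensate for it in the optimization, which inflates
  some extensor forces.
- Contact magnitudes underestimate reality wherever co-contraction matters.
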