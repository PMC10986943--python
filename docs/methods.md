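# Methods

`wingkin` quantifies the extension/flexion kinematics of a raptor wing
skeleton from multi-posture bone point clouds and carries the result through
to a bionic 1-DOF mechanism with cable–spring actuation.  This note records
the models, the numerical choices, and what the synthetic data do and do not
establish.

## The skeletal model

The four main wing bones — humerus, ulna, radius and carpometacarpus
("metacarpal") — form a closed spatial chain ("drawing-parallels" four-bar):
the elbow couples the humerus and ulna (joint 1), the wrist couples the ulna
and metacarpal (joint 2), and the radius closes the loop between the
metacarpal (joint 3) and the humerus (joint 4).  Because the radius and ulna
run side by side, elbow and wrist rotation are coupled, and the whole
extension/flexion motion has effectively one degree of freedom, plus a
shoulder pitch (joint 5, limited to ±30°).

All coordinates are in a wing-fixed global frame: origin at the humeral
head, X toward the proximal metacarpal head, Z opposing gravity for the
fully extended wing, Y completing the right-handed triad.  Poses are
intrinsic ZYX Euler angles (yaw–pitch–roll), degrees at every interface,
with the rotation matrix `Rz(α) Ry(β) Rx(γ)`; at gimbal lock (|β| = 90°) the
roll is reported as zero.

## Pose fitting

For each bone `b` and posture `p` a rigid transform `(A, t)` maps the
full-extension cloud onto the posture cloud.  The fitting criterion is the
one-sided mean nearest-neighbour distance

    resid_pb = (1/n1) Σ_i min_j ‖ X_i − (A x_j + t) ‖   [mm]

over the posture cloud's points `X_i` (target) against the transformed
reference points (candidate).  Nearest neighbours are exact (k-d tree), and
the inner minimisation is evaluated by inversely transforming the target
points against a fixed tree on the reference cloud (the Euclidean norm is
rotation invariant), so the tree is built once per bone.

The pose search is multi-start local optimisation: `n_starts = 8` starts
(centroid alignment with the identity rotation plus seeded random rotations
up to 60°), each refined by an exact-1NN ICP inner loop with closed-form
Kabsch updates, and the best start polished by Nelder–Mead directly on the
mean-distance objective (`fatol` 1e-6 mm).  ICP provides fast, reliable
convergence; the Nelder–Mead polish removes the small bias of ICP's
sum-of-squares objective relative to the mean-distance criterion.  Ties
between starts break to the lower residual, then the lower start index.
Clouds larger than 2000 points are seeded-uniformly subsampled for the
search; the reported residual is always recomputed on the full clouds at the
returned transform.  On noiseless synthetic postures this recovers rotations
and translations to machine precision; with 0.3 mm point noise, pose errors
are of order 0.5° / 0.1 mm and the residual is dominated by the noise floor
(≈ sd·√(2/π) plus a sampling-density term).

## Joint-constrained fitting

A joint between bones `b` and `b'` with shared center `c` and axes
`u_b1, u_b2` (fixed in `b`) and `u_b'3` (fixed in `b'`) contributes, per
non-reference posture, the constraints of its type:

* ball — center coincidence: `A_pb c + t_pb = A_pb' c + t_pb'`;
* universal — ball, plus one preserved orthogonal pair:
  `(A_pb u_b1)·(A_pb' u_b'3) = 0` with `u_b1 ⊥ u_b'3` at reference;
* revolute — ball, plus two preserved pairs with `u_b1, u_b2 ⊥ u_b'3`
  orthonormal, i.e. the relative rotation keeps the common axis fixed.

The constrained fit minimises the mean residual over all bones × postures
subject to all active constraints.  It proceeds in three stages:

1. unconstrained multi-start fits per bone/posture (above);
2. quadratic-penalty refinement: 4 rounds with weight μ = 10, 100, 1000,
   10000 (axis terms scaled by a 50 mm characteristic length), each round
   two blockwise sweeps of Nelder–Mead over one bone's six pose parameters
   at a time, with joint centers and axes re-estimated in closed form
   between sweeps (centers: linear least squares with a minimal-norm update
   about the initial guess; revolute axes: dominant eigenvector of
   Σ(R_p + R_pᵀ); universal pairs: alternating smallest-eigenvector updates
   with a Gauss–Newton polish);
3. feasibility polish: Gauss–Newton least squares on the violation
   residuals over all transforms, centers and axis angles (axes
   parameterised by spherical angles so unit norm is exact), driving
   coincidence below 1e-4 mm and axis dot products below 1e-6.

Joint centers are initialised at the midpoint of the adjacent bones'
nearest centerline endpoints.  Reported axes are sign-normalised to a
non-negative Z component (ties: non-negative X).  The reference posture is
the gauge: its transforms are the identity.

Model comparison fits the unrestrained baseline and the candidate joint-type
assignments (all-ball, all-universal, all-revolute, and the 1-DOF
revolute–revolute–universal–ball model), reporting each model's mean
residual and its relative deviation `100·(m − m₀)/m₀` from the unrestrained
mean `m₀`.  Because the constraint sets nest (revolute ⊂ universal ⊂ ball ⊂
unrestrained, per joint), fits cascade — each tighter model warm-starts from
the best containing model — and a consistency pass lets a looser model adopt
a tighter model's solution if that solution scores better, which makes the
reported means non-decreasing with constraint strictness by construction.
The comparison mean averages exactly the cells the optimiser minimises (all
four bones × non-reference postures); a three-bone view (ulna, humerus,
metacarpal — the conventional reporting set) is available on the results
object.

### Identifiability

Two facts about what three postures can determine, verified empirically on
the synthetic data:

* A revolute joint's center is identifiable only transverse to its axis
  (any point of the axis satisfies coincidence).  The estimator anchors the
  axial component at the initialisation via a minimal-norm update; recovery
  is therefore assessed as distance to the true axis line.
* A universal joint's axis pair is identifiable only up to a one-parameter
  family from two relative rotations (four unknowns, three orthogonality
  equations).  The estimator returns an exactly consistent member of that
  family; it need not be the generating pair, and recovery is assessed as
  consistency with the true motion.  Revolute axes, by contrast, are point
  identifiable and recovered to < 0.01° on noiseless data.

## The 1-DOF mechanism

The best-supported joint types (joints 1–2 revolute, 3 universal, 4 ball)
define a 1-DOF mechanism: the ulna is the driving bar with elbow angle θ1;
the wrist angle follows the monotone coupling law interpolating linearly
through the measured posture anchors (0, 0), (15.54, 22.84),
(37.18, 55.65) degrees; the metacarpal rides the ulna; and the radius is
the closing link.

The default geometry places the ball-joint center on the elbow axis and the
universal-joint center on the wrist axis.  This is a deliberate design
property: the radius chord then has invariant length under any (θ1, θ2)
pair, so the loop closes exactly along the entire stroke for the anchored
coupling law (an arbitrary geometry closes only at the anchors themselves).
The radius spin about its chord is fixed by the universal joint's preserved
axis pair and solved by damped Gauss–Newton on the rotation vector
(4 residuals, 3 unknowns, warm-started along the stroke); closure residuals
are at machine precision, and every returned state is checked to
coincidence ≤ 1e-6 mm and axis dot ≤ 1e-9.  A consequence worth noting: in
this geometry the radius transmits no kinematic coupling — the coupling law
is imposed, and the radius follows.

Posture reproduction finds, per measured posture, the drive angle
minimising the mean residual between mechanism-posed reference clouds and
the posture clouds (bounded scalar minimisation, 1e-4° tolerance).

## Cable–spring actuation

Two antagonistic ropes drive the stroke: rope 1 (biceps analogue) from a
linear motor on the humerus (site BH) to the proximal ulna (BU); rope 2
(triceps analogue) from the ulnar olecranon (TU) to a spring on the humerus
(TH).  Ropes are straight segments through their endpoints — no wrapping or
pulleys — which keeps the quasi-static analysis well defined; consequently
the hardware-specific stroke numbers of a wrapped-rope implementation are
not reproduced here, only the structure of the analysis.  The spring is
linear with stiffness k = 0.187 N/mm and preload F₀ = 4.5 N; the motor
force bound is 0–5 N; inertia and friction are neglected.  The motor force
follows from virtual work,

    F_motor(θ1) = F_spring(θ1) · |dL2/dθ1| / |dL1/dθ1| ,

with rope-length derivatives by central differences (step 0.01°); a
configuration with |dL1/dθ1| < 1e-9 mm/deg is reported as singular.  On toy
linkages with analytic moment arms this matches the closed-form torque
balance to 1e-6 N, and motor work equals the spring energy change within 1%
over a discretised stroke.

Each site has three candidates (spacings 10 mm at BU, 30 mm at BH, 3 mm at
TU, 5 mm at TH), giving 3⁴ = 81 combinations.  The sweep samples θ1 in 101
uniform steps, records the maxima of motor stretch, spring stretch, spring
force and motor force per combination, marks feasibility against the motor
bound, and selects the feasible combination with the smallest maximum motor
force, ties broken by the smallest maximum spring stretch.  The selection
rule is configurable; on the default geometry, moving the ulna-side biceps
endpoint distally strictly increases the maximum motor stretch.

## Sensor streams

Four inertial sensors ride the steering gear (S1), humerus (S2), ulna (S3)
and metacarpal (S4).  Quaternions are scalar-first with Hamilton-convention
multiplication (this must be pinned for the relative-rotation algebra to be
reproducible).  For a pair (a, b), the joint motion is

    p'_ab(t) = (p_a(t)⁻¹ ⊗ p_b(t)) ⊗ (p_a(0)⁻¹ ⊗ p_b(0))⁻¹ ,

identity at the reference time, invariant under a common rotation of both
sensors, and — because a constant mounting offset enters only by
conjugation — the total relative angle is mount independent.  Signs are
canonicalised (scalar ≥ 0) before the intrinsic ZYX Euler extraction; joint
angles are reported in the parent-bone (relative) convention.  Streams are
aligned by nearest timestamp within 20 ms with no interpolation; gaps over
0.5 s are flagged.  On streams synthesised from the mechanism's forward
kinematics, the extracted elbow angle reproduces the commanded θ1 exactly
(the relative humerus→ulna rotation is the drive rotation itself).

## Synthetic data: what it emulates, and what it does not

Real inputs would be segmented CT clouds of the four bones in three scanned
postures.  The generator stands in for them: each bone is a bent-tube
surface (parabolic bow, interpolated radius profile) with hemispherical end
caps and 2–3 hemispheric bumps, which guarantees no rotational symmetry so
the rigid pose is uniquely recoverable.  Chord lengths follow the wing-scale
geometry (humerus ≈ 59 mm, ulna ≈ 63 mm, radius ≈ 63 mm, metacarpal ≈
34 mm); the joint centers span ≈ 90 mm as in the real wing.  No anatomical
accuracy is claimed.  Postures are generated by the mechanism itself at the
coupling anchors, so joint coincidence holds to 1e-9 mm by construction,
and isotropic Gaussian point noise (default 0.3 mm) is applied after
posing as a segmentation-error surrogate.  Everything is deterministic
under a fixed seed.

Passing tests on these data therefore establish correctness of the
estimators under the modelled conditions — rigid bones, exactly consistent
joints, isotropic noise, complete clouds.  They do not establish robustness
to segmentation artefacts, partial overlap, cartilage compliance,
non-rigid deformation, or outliers, none of which the generator emulates.
Real CT residuals (a few tenths of a millimetre per bone) are matched in
structure, not in value.

## Default study conditions and problem sizes

2000 points per bone cloud (searches subsample at 2000); three postures at
the coupling anchors; noise sd 0.3 mm where noise is used.  The recovery
study runs 20 generator seeds noiseless at full density; the model-nesting
study uses 800-point clouds at 0.3 mm noise (two seeds), where the
constraint hierarchy is exercised away from the trivial noiseless optimum.
The endpoint sweep and closure checks use the full 101-step stroke.  These
sizes are the package's reference configuration; all are arguments.

## Known limitations

* Straight-segment ropes: no wrapping, slack (negative spring stretch) is
  rejected rather than modelled.
* No dynamics: inertia, friction, gravity and aerodynamic loads are out of
  scope, as is any motor or sensor hardware model (drift, bias, fusion).
* The constrained fit is a local method; it is reliable warm-started from
  the unconstrained fits under study conditions but carries no global
  optimality guarantee.
* Universal-joint axis pairs (and hinge centers along their axes) are
  reported as one member of their identifiable family, as discussed above.
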