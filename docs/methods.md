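# Methods

## The balanced region and its boundary

A standing biped is *balanced* at a COM state `(x, ẋ)` if some admissible
motion brings it to an upright rest state without changing the foot
contact. The set of such states is the balanced region; its boundary (the
boundary of balance, BoB) is traced point by point: at each sampled COM
position `x_i` — taken at the standing COM height `ȳ` — the initial COM
horizontal velocity is extremized (separately toward anterior and
posterior) subject to a dynamically feasible recovery. The two extremal
velocities at each position are one point of the upper and lower BoB
branch respectively.

Coordinates are sagittal-plane with X anterior, Y up, and the origin at
the heel edge of the base of support, so the support interval is
`[0, fl]` with `fl` the foot length. Nondimensionalization divides
positions by `fl` and velocities by `fl·ω`, `ω = √(g/ȳ)`.

Three model families are implemented:

* **LIP** — point mass at fixed height, COP-only control. The balanced
  region is known in closed form: `−ωx ≤ ẋ ≤ −ωx + fl·ω`, i.e. the
  extrapolated COM `XCoM = x + ẋ/ω` must lie in the support. The
  reachable boundary margins are exactly zero and the bounds put no limit
  on COM position, so the viable margins are *undefined* — represented by
  an explicit sentinel, never as zero or infinity.
* **4-DOF** — ankle, knee, hip and upper-body joints on a rigid foot in
  permanent flat contact. Joints are relative; a link's absolute
  orientation is measured from the vertical, positive anterior; `q = 0`
  is upright.
* **5-DOF** — the same chain plus one foot coordinate realizing a
  two-segment foot: in `HEEL_PIVOT` the rigid foot rocks about the heel
  (toe lifts), in `TOE_PIVOT` the rearfoot rotates about the metatarsal
  contact point while the toe segment stays flat (heel lifts). "Locking
  the metatarsal" means restricting contact to `FLAT` with the foot
  coordinate pinned at zero, which reduces the model exactly to the
  4-DOF problem.

Contact is handled mode-wise with per-mode constraint sets rather than
complementarity conditions. Rocker contacts are passive: the actuation on
the pivot coordinate is constrained to zero, and the COP is by definition
at the pivot point. In flat contact the COP must stay inside the support;
the constraint is imposed multiplicatively (`lo·F_y ≤ M_O ≤ hi·F_y`, with
`M_O` the ground moment about the origin), which stays smooth when the
vertical reaction `F_y` becomes small. Unilaterality is enforced as
`F_y ≥ f_min·W` (default 2 % of body weight): recoveries that rely on a
near-flight phase are excluded as non-physiological.

## Transcription of the extremization problem

Decision variables are the initial configuration `q₀`, initial velocity
`q̇₀`, and the joint accelerations at `n_nodes` uniform time nodes over a
fixed horizon `T` (default 2 s, 24 nodes). Velocities are the exact
trapezoidal integral of the piecewise-linear acceleration; positions are
the exact double integral (`Δq = h q̇_k + h²(a_k/3 + a_{k+1}/6)`). Because
the reconstruction is exact for this acceleration class, forward
integration of the stored acceleration profile reproduces the node states
to integrator precision — this is what the certificate check exploits.
Torques, ground reaction and COP are recovered from the prescribed motion
by inverse dynamics (d'Alembert virtual work on the planar chain), so the
dynamics never appear as defect constraints.

Path constraints (torque limits, COP window, unilaterality, joint-angle
windows) are imposed at the nodes *and* at three interior points per
interval (quarter points). Torque and COP are quartic in time within an
interval; node-only enforcement admits chatter policies whose inter-node
excursions are unbounded, which the interior samples rule out.
Accelerations and velocities carry physiological box bounds (60 rad/s²,
8 rad/s).

The rest state at `T` requires every joint speed below
`rest_velocity_tol` (0.05 rad/s; scaled by `fl·ω` for the LIP), a
statically sustainable final posture (static torques within limits with
slack `equilibrium_residual_tol` = 1 N·m, static COP in the support) and
the final COM ground projection over the support. The final posture is
any static equilibrium, not a pinned configuration.

The initial COM position is an equality; the initial COM *height* is held
in a ±1 cm band around `ȳ` rather than an equality: `ȳ` is the upright
COM height, which is the chain's global maximum, so exact equality is
geometrically unattainable at any other COM position. The band is what
makes the feasible position range — and hence the viable margins — finite
and contact-mode-dependent.

Problems are solved with SLSQP on normalized variables (velocities /5,
accelerations /50) with an analytic-accuracy batched finite-difference
Jacobian, from `n_multistarts` seeded perturbed static postures. A point
is infeasible only when every start ends with normalized constraint
residual above `solver_tol`.

`solver_tol` (default 5·10⁻³ on the normalized constraint scale — about
0.4 N·m of torque or 1 mm of COP) represents the transcription's
between-node path-constraint accuracy at the default node count, not the
inner SLSQP residual (which is ~10⁻¹²). The certificate re-checks every
constraint along the forward-integrated motion within 10× this tolerance
and applies the rest-state test to the integrated final state.

For the two-link foot, a small library of contact-mode schedules is
enumerated per solve — `FLAT`; `HEEL_PIVOT→FLAT`; `TOE_PIVOT→FLAT`, with
the pivot phase occupying the first 40 % of the horizon — and the
feasible velocity ranges are united. At the touchdown node the foot
coordinate must land at zero with zero velocity (no impact). Since the
all-`FLAT` schedule is always in the library and pinned coordinates are
eliminated from the decision vector, the locked five-link problem is
structurally the rigid-foot problem, and unlocking can only enlarge the
velocity ranges.

Position limits (for viable margins) are located by outward bisection
from the support edges to a prescribed bracket tolerance; the LIP returns
an explicit *unbounded* sentinel. A BoB without an explicitly computed
domain reports *undefined* viable margins — the sampled grid extremes are
not evidence of a position limit.

## Margins and classification

Boundary margins are measured on the nondimensional raw point set, not on
the fitted lines: the reachable margins from the zero-velocity crossings
of the lower (posterior) and upper (anterior) boundaries, located by
linear interpolation between adjacent points (end segments extrapolated
when the crossing falls outside the grid); the viable margins from the
position-domain extremes. Margins are positive outward from the support
edge; a crossing inside the support is a negative margin. Straight lines
fitted by ordinary least squares to the two branches serve visualization
and the eMOS computation.

The eMOS of a state against line bounds is the signed position distance
to each bound at the state's velocity; the critical margin is the smaller
in *magnitude* (the nearer boundary is the threatening one), with ties
resolved to the lower bound. States outside the fitted domain are still
evaluated but flagged extrapolated. On LIP bounds the eMOS reduces
exactly to the XCoM margin of stability.

Classification is hierarchical and exhaustive: outside the BoB →
unbalanced; COM over the support → static; within the reachable margins →
reachable; else viable.

## Synthetic data

The generator stands in for recorded human push-recovery exercises; it
produces the structure the estimators consume, not biofidelic motion.

* `simulate_lip_recovery` integrates `ẍ = ω²(x − u)` with a fixed-step
  RK4 at 1 kHz (resampled to 100 Hz for output) under either a
  capture-point policy (`u = x_t + 1.5·(XCoM − x_t)`, clipped to the
  support; the gain > 1 makes the XCoM converge to the target) or a PD
  policy realizing an acceleration demand through the COP (kp = 4 s⁻²,
  kd = 3 s⁻¹). `stance_intact` turns false from the first instant the
  commanded COP saturates while the XCoM is outside the support (with a
  10⁻⁴·fl slack so boundary-riding states do not trip on integrator
  drift) — from there a stance change is inevitable for the LIP.
* `sample_states` draws uniform COM states in a requested balance
  partition by rejection against the classifier; deterministic per seed.
  It emulates the role of perturbed initial states in push-recovery
  experiments (graded posterior perturbations); the reference study's
  extracted states are figure-derived data and are not shipped.
* `add_noise` resamples to a measurement rate and adds independent
  Gaussian noise per channel.

What passing tests on these data do **not** show: human recoveries are
not LIP trajectories under simple COP policies, real COM estimates carry
correlated (not white) noise, and real perturbation experiments sample
initial states far from uniformly. The synthetic pipeline validates the
estimators' correctness, not their field performance.

## Verification scales

The default test suite builds all regions at reduced sizes chosen as the
package's own verification conditions: the COP-only model on an 11-point
nondimensional grid (30 nodes, 4 s horizon); the pendulum+flywheel
benchmark on a 7-point grid with every solution certificate re-checked
and a 3-position comparison against an exhaustive switching-time
bang-bang search (0.05 s switch grid, 0.05 m/s velocity grid — the
search's velocity resolution is the grid step plus the velocity cost of
one switch quantum at full torque authority, ≈0.15 m/s); and the
4-DOF/5-DOF nesting comparison on a 3-position grid at 16 nodes with a
single multistart. The shipped anthropometric fixture uses Winter-style
mass and length fractions scaled so the upright COM height is exactly
1.12 m with fl = 0.23 m; published joint-level subject parameters are not
available, so quantitative margin values are fixture-specific while the
structural properties (nesting, ordering, certificates) are
parameter-independent.

## Known limitations

* Sagittal plane only; symmetric double stance with leg segments lumped
  pairwise; no friction cone beyond COP + unilaterality; no stepping
  (stance change is the failure event, not a recovery strategy).
* Mode schedules are drawn from a fixed library with a fixed pivot
  fraction; a recovery needing, e.g., a mid-motion pivot would be scored
  conservatively (the union can only under-approximate the true region).
* SLSQP is a local method: multistart reduces but does not eliminate the
  chance of under-approximating an extremal velocity. All reported
  regions are inner approximations certified point-wise.
* The ±1 cm COM-height band is a modeling choice; tightening it shrinks
  the feasible position range and the viable margins.
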