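# bobkit

Quantitative balance assessment for standing posture: **bobkit** builds
the *balanced region* of planar biped models in COM state space, measures
its *boundary margins*, and evaluates instantaneous *state margins* along
COM trajectories. It is aimed at balance-rehabilitation research — the
margins serve both as targets for perturbation exercises and as outcome
measures computed from recorded (or simulated) COM motion.

## The model

A COM state `(x, ẋ)` of a standing biped is *balanced* if the body can
reach an upright rest state without changing its foot contact. The
boundary of the balanced region (the **boundary of balance**, BoB) is
constructed point by point: at each sampled COM position `x_i` (at the
standing COM height `ȳ`), a constrained trajectory optimization finds the
extremal feasible initial COM velocities

```
(x_i, ȳ, ẋ_lim^{ANT/POS}, ẏ_i),   i = 1…N
```

subject to the rigid-body dynamics, joint angle and torque limits, the
center of pressure staying inside the base of support `[0, fl]`, a
non-negative vertical ground reaction, and a final rest state.

Three sagittal-plane models are included: a linear inverted pendulum
(LIP, closed form: `−ωx ≤ ẋ ≤ −ωx + fl·ω` with `ω = √(g/ȳ)`, equivalent
to the extrapolated COM `XCoM = x + ẋ/ω` staying inside the support), a
4-DOF chain (ankle–knee–hip–upper body) on a rigid foot, and a 5-DOF
model whose two-segment foot may rock about the heel or the metatarsal.

From the (nondimensionalized) BoB the package derives:

* **reachable margins ΔR** — zero-velocity crossings of the boundary
  relative to the support edges: how far the COM can sway beyond the
  footprint and still return by internal dynamics alone;
* **viable margins ΔV** — the extreme COM positions admitting any
  balanced velocity: the limit of externally imposed perturbations
  (undefined for the LIP, whose bounds put no limit on position);
* **eMOS** — the signed position distance from any COM state to the
  boundary lines; positive inside, negative outside; equal to the
  classical XCoM margin of stability for the LIP;
* **exercise targets** — graded target states approaching the reachable
  (category A) or viable (category B) margins, or via-points at
  prescribed eMOS values (category C), plus estimators that recover the
  experimental counterparts of the margins from recorded trajectories and
  perturbation trials.

## Worked example

Reference model files ship with the package (`lip`, `dof4`, `dof5`). The
LIP pipeline, end to end:

```sh
LIP=$(python -c "import bobkit.io; print(bobkit.io.fixture_path('lip'))")

bobkit build-bob $LIP --x-min 0 --x-max 0.23 --n-positions 11 --out lip_run
bobkit margins lip_run/bob.csv --out margins.json
cat margins.json
```

prints

```json
{
 "reachable_post": 0.0,
 "reachable_ant": 0.0,
 "viable_post": "undefined",
 "viable_ant": "undefined"
}
```

— the LIP can never let its COM leave the footprint (zero reachable
margins) and its analytic bounds place no limit on COM position (viable
margins undefined). Simulating a balance recovery and scoring it against
the region:

```sh
bobkit simulate $LIP --x0 0.10 --xdot0 0.3 --duration 3 --out recovery.csv
bobkit emos recovery.csv lip_run/bob.csv --out emos.csv
```

```
wrote emos.csv (min critical 0.1245)
```

The recovery from `x = 0.10 m, ẋ = 0.3 m/s` stays balanced throughout;
its closest approach to the boundary is a nondimensional eMOS of 0.124
(12.4 % of foot length), on the anterior side — the XCoM of the initial
state is at `0.10 + 0.3/ω ≈ 0.20 m`, 3 cm short of the toe edge.

The same operations are available as library calls (`bobkit.build_bob`,
`bobkit.boundary_margins`, `bobkit.emos_series`, …); the multi-link
models go through the same `build-bob` interface with trajectory
optimization under the hood, e.g.

```python
import numpy as np
from bobkit import (OptimizationSettings, StanceSpec, ContactMode,
                    dof5_model, build_bob, nondimensionalize,
                    boundary_margins)

m5 = dof5_model()
stance = StanceSpec((0.0, m5.fl), frozenset(
    {ContactMode.FLAT, ContactMode.HEEL_PIVOT, ContactMode.TOE_PIVOT}))
bob = build_bob(m5, stance, np.linspace(-0.06, 0.14, 3),
                OptimizationSettings(n_nodes=16, seed=1, n_multistarts=1))
print(boundary_margins(nondimensionalize(bob, m5.fl, m5.omega)))
```

Every feasible BoB point carries its certifying recovery trajectory;
`bobkit.verify_solution` re-integrates it and re-checks every constraint
independently of the optimizer.

Note on the shipped multi-link fixtures: segment masses and lengths are
standard proportional (Winter-style) values scaled to a 1.12 m standing
COM height with a 0.23 m foot; subject-specific joint parameters from the
primary literature are not public, so margin *values* are
fixture-specific while the structural results (model nesting, margin
ordering, certificate validity) are parameter-independent.

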