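"""Synthetic balance-recovery data.

Generates every input the analysis pipeline consumes, without any external
recording: simulated LIP balance-recovery trajectories under simple COP
control policies, perturbed initial-state sets emulating push-recovery
experiments (posterior perturbations of graded severity), and measurement
noise.

The simulated controllers are deliberately simple stand-ins for human
recovery control: a capture-point style policy that commands the COP
beyond the extrapolated COM (saturated at the support edges) and a
PD policy on COM position.  They produce the qualitative structure the
margin estimators need — recoveries that settle, boundary states that
linger, unbalanced states that diverge at the pendulum rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .bob import BoB
from .geometry import BalanceCategory, BoundaryMargins, classify_state, _feasible_arrays
from .lip import LipParams, xcom
from .margins import Trajectory
from .models import COMState

__all__ = [
    "CopPolicy",
    "LipController",
    "NoiseSpec",
    "simulate_lip_recovery",
    "sample_states",
    "add_noise",
]


class CopPolicy(str, enum.Enum):
    SATURATED_COP = "SATURATED_COP"
    PD_COP = "PD_COP"


@dataclass(frozen=True)
class LipController:
    """COP command policy for the LIP plant.

    ``SATURATED_COP`` commands ``u = x_t + gain_capture*(XCoM - x_t)``
    (``gain_capture > 1`` makes the XCoM converge to the target), clipped
    to the support.  ``PD_COP`` realizes an acceleration demand
    ``-kp*(x - x_t) - kd*xdot`` through the COP; ``kp`` (1/s^2) and ``kd``
    (1/s) are the proportional and derivative gains.
    """

    policy: CopPolicy = CopPolicy.SATURATED_COP
    kp: float = 4.0
    kd: float = 3.0
    gain_capture: float = 1.5
    target: float | None = None  # defaults to mid-support

    def command(self, x, xdot, params: LipParams):
        x_t = self.target if self.target is not None else params.fl / 2.0
        if CopPolicy(self.policy) is CopPolicy.SATURATED_COP:
            xc = xcom(x, xdot, params.omega)
            return x_t + self.gain_capture * (xc - x_t)
        acc_des = -self.kp * (x - x_t) - self.kd * xdot
        return x - acc_des / params.omega**2


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: resampling rate and per-channel sigmas."""

    sigma_pos: float = 0.0
    sigma_vel: float = 0.0
    rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_pos < 0 or self.sigma_vel < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")


def simulate_lip_recovery(init: COMState, params: LipParams,
                          controller: LipController | None = None,
                          duration: float = 3.0, seed: int = 0,
                          output_rate: float = 100.0,
                          internal_rate: float = 1000.0) -> Trajectory:
    """Forward-simulate ``xdd = omega^2 (x - u)`` under a COP policy.

    Fixed-step 4th-order integration at ``internal_rate``, resampled to
    ``output_rate`` for output.  ``stance_intact`` turns (and stays) False
    from the first instant the commanded COP saturates at a support edge
    while the XCoM lies outside the support — from there a stance change is
    inevitable for the LIP.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    controller = controller or LipController()
    w2 = params.omega**2
    fl = params.fl
    h = 1.0 / internal_rate
    n = int(round(duration * internal_rate)) + 1
    ts = np.arange(n) * h
    x = np.empty(n)
    xd = np.empty(n)
    intact = np.ones(n, dtype=bool)
    x[0], xd[0] = init.x, init.xdot

    def deriv(xk, xdk):
        u = np.clip(controller.command(xk, xdk, params), 0.0, fl)
        return xdk, w2 * (xk - u)

    # detection slack: a state held exactly on the boundary accumulates
    # integrator-level XCoM drift that must not trip the flag
    xc_tol = 1e-4 * fl
    broken = False
    for k in range(n - 1):
        u_cmd = controller.command(x[k], xd[k], params)
        xc = xcom(x[k], xd[k], params.omega)
        if (u_cmd <= 0.0 or u_cmd >= fl) and not (-xc_tol <= xc <= fl + xc_tol):
            broken = True
        intact[k] = not broken
        # classic RK4 on the controlled dynamics
        k1 = deriv(x[k], xd[k])
        k2 = deriv(x[k] + h / 2 * k1[0], xd[k] + h / 2 * k1[1])
        k3 = deriv(x[k] + h / 2 * k2[0], xd[k] + h / 2 * k2[1])
        k4 = deriv(x[k] + h * k3[0], xd[k] + h * k3[1])
        x[k + 1] = x[k] + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        xd[k + 1] = xd[k] + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    u_cmd = controller.command(x[-1], xd[-1], params)
    xc = xcom(x[-1], xd[-1], params.omega)
    if (u_cmd <= 0.0 or u_cmd >= fl) and not (-xc_tol <= xc <= fl + xc_tol):
        broken = True
    intact[-1] = not broken

    m = int(round(duration * output_rate)) + 1
    to = np.linspace(0.0, ts[-1], m)
    xo = np.interp(to, ts, x)
    xdo = np.interp(to, ts, xd)
    io = np.interp(to, ts, intact.astype(float)) >= 1.0 - 1e-12
    return Trajectory(t=to, x=xo, y=np.full(m, params.ybar),
                      xdot=xdo, ydot=np.zeros(m), stance_intact=io)


def sample_states(bob: BoB, margins: BoundaryMargins, category, n: int,
                  seed: int = 0) -> list[COMState]:
    """Uniform rejection sampling of COM states within one balance partition.

    Every returned state re-classifies (via :func:`classify_state`) into
    the requested category; deterministic for a fixed seed.
    """
    from .margins import UnsupportedCategoryError

    category = BalanceCategory(category)
    if category is BalanceCategory.UNBALANCED:
        raise UnsupportedCategoryError("sampling targets balanced partitions only")
    if not bob.nondimensional:
        raise ValueError("sample_states expects a nondimensional BoB")
    xs, lo, hi = _feasible_arrays(bob.points)
    x_lo, x_hi = float(xs.min()), float(xs.max())
    if isinstance(bob.domain, tuple):
        x_lo, x_hi = min(x_lo, bob.domain[0]), max(x_hi, bob.domain[1])
    v_lo, v_hi = float(lo.min()), float(hi.max())
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    max_attempts = max(20000, 2000 * n)
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(x_lo, x_hi)
        xd = rng.uniform(v_lo, v_hi)
        state = COMState(x, 1.0, xd, 0.0)
        if classify_state(state, bob, margins) is category:
            out.append(state)
    if len(out) < n:
        raise UnsupportedCategoryError(
            f"partition {category.value} appears empty for this balanced region")
    return out


def add_noise(traj: Trajectory, noise: NoiseSpec) -> Trajectory:
    """Resample a trajectory to ``noise.rate`` and add Gaussian noise.

    Position channels receive ``sigma_pos``, velocity channels
    ``sigma_vel``; independent draws per channel, seeded.
    """
    duration = traj.t[-1] - traj.t[0]
    m = int(round(duration * noise.rate)) + 1
    to = np.linspace(traj.t[0], traj.t[-1], m)
    rng = np.random.default_rng(noise.seed)

    def res(v):
        return np.interp(to, traj.t, v)

    x = res(traj.x) + rng.normal(0.0, noise.sigma_pos, m) if noise.sigma_pos else res(traj.x)
    y = res(traj.y) + rng.normal(0.0, noise.sigma_pos, m) if noise.sigma_pos else res(traj.y)
    xd = res(traj.xdot) + rng.normal(0.0, noise.sigma_vel, m) if noise.sigma_vel else res(traj.xdot)
    yd = res(traj.ydot) + rng.normal(0.0, noise.sigma_vel, m) if noise.sigma_vel else res(traj.ydot)
    intact = np.interp(to, traj.t, traj.stance_intact.astype(float)) >= 1.0 - 1e-12
    return Trajectory(t=to, x=x, y=y, xdot=xd, ydot=yd, stance_intact=intact,
                      nondimensional=traj.nondimensional)
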