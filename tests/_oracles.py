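"""Independent oracles used by the test suite.

Everything here is deliberately coded from first principles, without the
package's chain/inverse-dynamics machinery, so the tests compare two
independent routes to the same physics.
"""

from __future__ import annotations

import numpy as np


def per_link_com(base, offsets, attach_d, com_d, masses, q, qd):
    """Brute-force mass-weighted COM of a planar chain, one link at a time."""
    n = len(masses)
    th = np.asarray(offsets) + np.cumsum(q)
    w = np.cumsum(qd)
    p = np.asarray(base, dtype=float)
    pv = np.zeros(2)
    num = np.zeros(2)
    vnum = np.zeros(2)
    for i in range(n):
        d = np.array([np.sin(th[i]), np.cos(th[i])])
        dp = np.array([np.cos(th[i]), -np.sin(th[i])])
        r = p + com_d[i] * d
        rv = pv + com_d[i] * dp * w[i]
        num += masses[i] * r
        vnum += masses[i] * rv
        p = p + attach_d[i] * d
        pv = pv + attach_d[i] * dp * w[i]
    return num, vnum


class ToyDynamics:
    """Closed-form pendulum+flywheel dynamics (Lagrangian, by hand).

    phi: pendulum angle from vertical; q2: flywheel angle relative to the
    pendulum.  tau1 acts at the ankle, tau2 on the flywheel.
    """

    def __init__(self, mass, length, flywheel_inertia, g=9.81):
        self.m = mass
        self.l = length
        self.If = flywheel_inertia
        self.g = g

    def accel(self, phi, tau1, tau2):
        phidd = (tau1 - tau2 + self.m * self.g * self.l * np.sin(phi)) / (self.m * self.l**2)
        q2dd = tau2 / self.If - phidd
        return phidd, q2dd

    def step(self, state, tau1, tau2, h):
        """One RK4 step; state = (phi, q2, phid, q2d), vectorized."""
        def f(s):
            phidd, q2dd = self.accel(s[0], tau1, tau2)
            return np.stack([s[2], s[3], phidd, q2dd])

        k1 = f(state)
        k2 = f(state + h / 2 * k1)
        k3 = f(state + h / 2 * k2)
        k4 = f(state + h * k3)
        return state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def bang_bang_extremal_velocity(toy, x_i, sense="MAX", horizon=2.5,
                                switch_grid=0.05, v_max_scan=None, dv=0.05,
                                h=0.005, rest_tol=0.08):
    """Exhaustive discretized bang-bang policy search for the extremal
    initial COM velocity of the pendulum+flywheel benchmark.

    The policy class is bang-bang with switching times enumerated on a grid
    of ``switch_grid`` seconds: the ankle brakes at full torque for a
    duration ``t_a`` and then hands over to a saturated stabilizing PD law;
    the flywheel spins up at full torque for ``t_b`` and unwinds at full
    reverse torque for ``t_c``, then spins down under feedback.  All
    ``(sign, t_a, t_b, t_c)`` combinations are simulated simultaneously.
    A candidate initial velocity (scanned outward-in at resolution ``dv``
    m/s) succeeds when some policy ends at rest in a statically holdable
    posture within the horizon; every success is a certified recovery, so
    the returned value is a lower bound on the true extremum with
    resolution ``dv``.
    """
    dyn = ToyDynamics(toy.chain.masses[0], toy.ybar, toy.chain.inertias[1], toy.g)
    t1 = toy.torque_limits[0, 1]
    t2 = toy.torque_limits[1, 1]
    phi_i = np.arcsin(np.clip((x_i - toy.chain.base[0]) / toy.ybar, -1, 1))
    phi_max = toy.angle_limits[0, 1]
    sgn = 1.0 if sense == "MAX" else -1.0
    if v_max_scan is None:
        v_max_scan = 2.0 * toy.fl * np.sqrt(toy.g / toy.ybar)

    t_brake = np.arange(0.0, 1.2 + switch_grid / 2, switch_grid)
    t_spin = np.arange(0.0, 0.8 + switch_grid / 2, switch_grid)
    ta, tb, tc = np.meshgrid(t_brake, t_spin, t_spin, indexing="ij")
    ta, tb, tc = ta.ravel(), tb.ravel(), tc.ravel()
    signs = np.array([1.0, -1.0])
    ta = np.concatenate([ta, ta])
    tb = np.concatenate([tb, tb])
    tc = np.concatenate([tc, tc])
    s_fly = np.repeat(signs, ta.size // 2)
    n_pol = ta.size
    kp, kd, kf = 400.0, 150.0, 30.0

    # candidate velocities: a window below the a priori capture bound given
    # by the total torque authority (effective support extension)
    omega = np.sqrt(toy.g / toy.ybar)
    x_eff = (t1 + t2) / (toy.chain.masses[0] * toy.g)
    if sense == "MAX":
        v_ub = omega * (toy.chain.base[0] + x_eff - x_i) + 3 * dv
    else:
        v_ub = omega * (x_i - (toy.chain.base[0] - x_eff)) + 3 * dv
    v_ub = min(v_ub, v_max_scan)
    full_grid = np.arange(dv, v_ub + dv / 2, dv)

    def run(vs):
        phid0 = vs / (toy.ybar * np.cos(phi_i))
        n_v = vs.size
        state = np.zeros((4, n_pol, n_v))
        state[0] = phi_i
        state[2] = phid0[None, :]
        alive = np.ones((n_pol, n_v), dtype=bool)
        brake = np.where(phid0 != 0, -np.sign(phid0), -1.0) * t1
        ta_c, tb_c, tc_c, s_c = ta[:, None], tb[:, None], tc[:, None], s_fly[:, None]
        for k in range(int(round(horizon / h))):
            t = k * h
            pd1 = np.clip(-kp * state[0] - kd * state[2]
                          + dyn.m * dyn.g * dyn.l * np.sin(state[0]), -t1, t1)
            tau1 = np.where(t < ta_c, brake[None, :], pd1)
            spin_down = np.clip(-kf * state[3], -t2, t2)
            tau2 = np.where(t < tb_c, s_c * t2,
                            np.where(t < tb_c + tc_c, -s_c * t2, spin_down))
            state = dyn.step(state, tau1, tau2, h)
            alive &= np.abs(state[0]) <= phi_max
        static_ok = np.abs(dyn.m * dyn.g * dyn.l * np.sin(state[0])) <= t1
        rest = (np.abs(state[2]) <= rest_tol) & (np.abs(state[3]) <= rest_tol)
        return np.any(alive & static_ok & rest, axis=0)

    window = full_grid[full_grid > v_ub - 0.8]
    success = run(sgn * window)
    if np.any(success):
        return float(sgn * window[np.nonzero(success)[0].max()])
    rest_grid = full_grid[full_grid <= v_ub - 0.8]
    if rest_grid.size:
        success = run(sgn * rest_grid)
        if np.any(success):
            return float(sgn * rest_grid[np.nonzero(success)[0].max()])
    return None


def bang_bang_resolution(toy, switch_grid=0.075, dv=0.05):
    """Velocity resolution of the switching-time search: the velocity grid
    step plus the velocity cost of one switch-time quantum at the maximum
    torque-driven acceleration."""
    t1 = toy.torque_limits[0, 1]
    t2 = toy.torque_limits[1, 1]
    m = toy.chain.masses[0]
    accel = (t1 + t2) / (m * toy.ybar**2) * toy.ybar  # COM-velocity rate
    return dv + accel * switch_grid
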