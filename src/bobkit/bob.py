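"""Numerical construction of the boundary of balance (BoB).

The balanced region of a biped in a given stance is the set of COM states
from which an upright rest state can be reached without changing the foot
contact.  Its boundary is built point by point: at each sampled COM
position ``x_i`` (at the standing COM height ``ybar``) a constrained
trajectory optimization extremizes the initial COM horizontal velocity
subject to

1. the rigid-body dynamics of the model under the active contact mode(s),
2. joint angle and torque limits, COP-within-support and a non-negative
   vertical ground reaction,
3. a final rest state (near-zero joint velocities in a statically
   sustainable posture with the COM over the support), and
4. preservation of the stance (no new contacts; rocking about the heel or
   metatarsal is permitted for the two-link-foot model).

Transcription.  The decision variables are the initial configuration and
velocity plus the joint accelerations at ``n_nodes`` uniformly spaced time
nodes; velocities and positions are reconstructed by exact trapezoidal
integration of the piecewise-linear acceleration profile, and torques,
ground reaction and COP are recovered from the prescribed motion by
inverse dynamics, so the dynamics never appear as separate defect
constraints.  Because trapezoidal sums integrate a piecewise-linear
function exactly, forward integration of the acceleration profile
reproduces the node states to integrator precision, which is what the
certificate check in :func:`verify_solution` exploits.

Problems are solved with SLSQP from seeded multistarts; for the two-link
foot a small library of contact-mode schedules is enumerated and the
feasible velocity ranges are united.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .models import (
    BipedModel,
    ContactMode,
    ModelKind,
    PlanarChain,
    StanceSpec,
    ToyModel,
)

__all__ = [
    "OptimizationSettings",
    "BoBPoint",
    "ExtremalSolution",
    "BoB",
    "Sense",
    "UNBOUNDED",
    "extremize_initial_velocity",
    "build_bob",
    "find_position_limits",
    "verify_solution",
]


UNBOUNDED = "unbounded"


class Sense:
    MIN = "MIN"
    MAX = "MAX"


@dataclass(frozen=True)
class OptimizationSettings:
    """Transcription and solver settings for the BoB optimizer.

    ``horizon`` is the recovery-motion duration in seconds; ``n_nodes`` the
    collocation node count.  The rest state at the final node requires every
    joint speed below ``rest_velocity_tol`` (rad/s; scaled by ``fl*omega``
    for the LIP) and a statically sustainable posture with torque slack
    ``equilibrium_residual_tol`` (N*m).  ``n_multistarts`` seeded initial
    guesses are tried per problem; a point is declared infeasible only when
    every start ends with a normalized constraint residual above
    ``solver_tol``.
    """

    horizon: float = 2.0
    n_nodes: int = 24
    rest_velocity_tol: float = 0.05
    equilibrium_residual_tol: float = 1.0
    n_multistarts: int = 3
    seed: int = 0
    solver_tol: float = 5e-3
    max_iter: int = 250
    pivot_fraction: float = 0.4
    grf_min_fraction: float = 0.02
    acc_max: float = 60.0
    vel_max: float = 8.0
    # initial COM height is held within this band around ybar (m): exact
    # equality is geometrically unattainable away from the upright COM
    # position, where ybar is the chain's maximum height
    com_height_tol: float = 0.01

    def __post_init__(self):
        if self.horizon <= 0 or self.n_nodes < 5:
            raise ValueError("horizon must be positive and n_nodes >= 5")
        for name in ("rest_velocity_tol", "equilibrium_residual_tol", "solver_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_multistarts < 1:
            raise ValueError("n_multistarts must be >= 1")


@dataclass(frozen=True)
class SolverDiagnostics:
    status: str
    iterations: int
    residual: float
    schedule: tuple = ()
    starts_tried: int = 0


@dataclass(frozen=True)
class ExtremalSolution:
    """One limiting recovery motion certifying a BoB point."""

    x_i: float
    sense: str
    xdot: float
    ydot: float
    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    qddot: np.ndarray
    torques: np.ndarray
    cop: np.ndarray
    grf: np.ndarray
    mode_schedule: tuple  # ((mode, first_node), ...)
    diagnostics: SolverDiagnostics


@dataclass(frozen=True)
class BoBPoint:
    """Extremal feasible initial COM velocities at one sampled position."""

    x: float
    ybar: float
    feasible: bool
    xdot_min: float | None = None
    xdot_max: float | None = None
    ydot_at_min: float | None = None
    ydot_at_max: float | None = None
    solutions: tuple = ()  # (min_solution, max_solution) when feasible
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.feasible and self.xdot_min is not None and self.xdot_max is not None:
            if self.xdot_min > self.xdot_max + 1e-12:
                raise ValueError("xdot_min must not exceed xdot_max")


@dataclass
class BoB:
    """A built boundary of balance: point set plus shared normalization."""

    points: list
    fl: float
    ybar: float
    omega: float
    nondimensional: bool = False
    settings: OptimizationSettings | None = None
    domain: tuple | str | None = None  # (x_min, x_max), UNBOUNDED, or None

    @property
    def feasible_points(self):
        return [p for p in self.points if p.feasible]


# ---------------------------------------------------------------------------
# Trapezoidal reconstruction machinery
# ---------------------------------------------------------------------------


def _trap_matrix(n: int, h: float) -> np.ndarray:
    """Cumulative trapezoid matrix: (S @ f)[k] = integral of f up to node k."""
    S = np.zeros((n, n))
    for k in range(1, n):
        S[k, : k + 1] = h
        S[k, 0] = h / 2
        S[k, k] = h / 2
    return S


@dataclass
class _Phase:
    mode: ContactMode
    nodes: np.ndarray       # node indices
    chain: PlanarChain
    coords: np.ndarray      # model-coordinate indices driving the chain
    pivot: bool


class _Adapter:
    """Uniform view of BipedModel / ToyModel for the transcription."""

    def __init__(self, model, stance: StanceSpec | None):
        self.model = model
        if isinstance(model, ToyModel):
            self.nc = 2
            self.angle_limits = model.angle_limits
            self.torque_limits = model.torque_limits
            self.contact_constraints = False
            self.foot_idx = None
            self.enforce_height = False
            self.weight = float(np.sum(model.chain.masses)) * model.g
        elif isinstance(model, BipedModel):
            if model.kind is ModelKind.LIP:
                raise TypeError("the LIP is handled by the dedicated transcription")
            self.nc = model.dof_count
            self.angle_limits = model.params.joint_angle_limits
            self.torque_limits = model.params.joint_torque_limits
            self.contact_constraints = True
            self.foot_idx = 0 if model.kind is ModelKind.DOF5 else None
            self.enforce_height = True
            self.weight = model.params.total_mass * model.g
        else:
            raise TypeError(f"unsupported model type {type(model)!r}")
        self.fl = model.fl
        self.g = model.g
        self.omega = model.omega
        self.ybar = model.ybar
        self.stance = stance or StanceSpec((0.0, model.fl))
        self.vscale = self.fl * self.omega
        self.tscale = max(np.max(np.abs(self.torque_limits)), 1.0)

    def chain_for(self, mode: ContactMode):
        if isinstance(self.model, ToyModel):
            return self.model.chain, np.arange(2)
        return self.model.chain(mode), self.model.chain_coords(mode)

    def pivot_x(self, mode):
        return self.model.pivot_x(mode)

    def schedules(self, settings: OptimizationSettings):
        """Contact-mode schedules to enumerate, as ((mode, node_frac), ...)."""
        out = [((ContactMode.FLAT, 0.0),)]
        if self.foot_idx is None:
            return out
        allowed = self.stance.allowed_contact_modes
        pf = settings.pivot_fraction
        if ContactMode.HEEL_PIVOT in allowed:
            out.append(((ContactMode.HEEL_PIVOT, 0.0), (ContactMode.FLAT, pf)))
        if ContactMode.TOE_PIVOT in allowed:
            out.append(((ContactMode.TOE_PIVOT, 0.0), (ContactMode.FLAT, pf)))
        return out

    def phases(self, schedule, n_nodes) -> list[_Phase]:
        # fractions are of the time horizon; node k sits at frac k/(n-1)
        starts = [int(round(frac * (n_nodes - 1))) for _, frac in schedule] + [n_nodes]
        out = []
        for (mode, _), a, b in zip(schedule, starts[:-1], starts[1:]):
            if b <= a:
                continue
            chain, coords = self.chain_for(mode)
            out.append(_Phase(mode=ContactMode(mode), nodes=np.arange(a, b),
                              chain=chain, coords=coords,
                              pivot=ContactMode(mode) is not ContactMode.FLAT))
        return out


class _CollocationProblem:
    """Single extremization problem at one COM position for one schedule.

    Decision vector: ``[q0 (nc), qd0 (nc), qdd at nodes (N*nc)]``; states
    are reconstructed by exact trapezoidal integration.
    """

    def __init__(self, adapter: _Adapter, x_i: float, sense: str,
                 settings: OptimizationSettings, schedule):
        self.ad = adapter
        self.x_i = float(x_i)
        self.sign = 1.0 if sense == Sense.MAX else -1.0
        self.sense = sense
        self.st = settings
        self.schedule = schedule
        self.N = settings.n_nodes
        self.nc = adapter.nc
        self.h = settings.horizon / (self.N - 1)
        self.t = np.linspace(0.0, settings.horizon, self.N)
        self.S = _trap_matrix(self.N, self.h)
        self.phases = adapter.phases(schedule, self.N)
        self.mode0 = self.phases[0].mode
        self.interior_offsets = (0.25, 0.5, 0.75)
        self._last = None
        # coordinates pinned to zero for the whole schedule (the foot
        # coordinate of a two-link-foot model in an all-FLAT schedule) are
        # eliminated from the decision vector, which makes the locked
        # problem structurally identical to the rigid-foot one
        if (adapter.foot_idx is not None
                and all(ph.mode is ContactMode.FLAT for ph in self.phases)):
            self.free = np.array([j for j in range(self.nc) if j != adapter.foot_idx])
        else:
            self.free = np.arange(self.nc)
        self.ncf = len(self.free)
        self.nvar = self.ncf * (self.N + 2)

        # variable bounds: q0 within (mode-restricted) angle limits, qd0 and
        # qdd within generous boxes; the foot coordinate's acceleration is
        # frozen during FLAT phases (it is pinned at zero there).
        lo0 = adapter.angle_limits[:, 0].copy()
        hi0 = adapter.angle_limits[:, 1].copy()
        alo = np.full((self.N, self.nc), -settings.acc_max)
        ahi = np.full((self.N, self.nc), settings.acc_max)
        fi = adapter.foot_idx
        self.switch_nodes = []
        if fi is not None:
            for ph in self.phases:
                if ph.mode is ContactMode.FLAT:
                    alo[ph.nodes, fi] = 0.0
                    ahi[ph.nodes, fi] = 0.0
                elif ph.mode is ContactMode.HEEL_PIVOT:
                    hi0[fi] = min(hi0[fi], 0.0) if ph.nodes[0] == 0 else hi0[fi]
                else:
                    lo0[fi] = max(lo0[fi], 0.0) if ph.nodes[0] == 0 else lo0[fi]
            if self.mode0 is ContactMode.FLAT:
                lo0[fi] = hi0[fi] = 0.0
            for ph in self.phases[1:]:
                self.switch_nodes.append(int(ph.nodes[0]))
        vlo = np.full(self.nc, -settings.vel_max)
        vhi = np.full(self.nc, settings.vel_max)
        if fi is not None and self.mode0 is ContactMode.FLAT:
            vlo[fi] = vhi[fi] = 0.0
        fr = self.free
        self.bounds = np.stack([
            np.concatenate([lo0[fr], vlo[fr] / self._VS, alo[:, fr].ravel() / self._AS]),
            np.concatenate([hi0[fr], vhi[fr] / self._VS, ahi[:, fr].ravel() / self._AS]),
        ], axis=1)
        # per-node angle windows (pivot-phase sign restrictions included)
        qlo = np.tile(adapter.angle_limits[:, 0], (self.N, 1))
        qhi = np.tile(adapter.angle_limits[:, 1], (self.N, 1))
        if fi is not None:
            for ph in self.phases:
                if ph.mode is ContactMode.HEEL_PIVOT:
                    qhi[ph.nodes, fi] = 0.0   # toe must stay above ground
                elif ph.mode is ContactMode.TOE_PIVOT:
                    qlo[ph.nodes, fi] = 0.0   # heel must stay above ground
        self.qlo, self.qhi = qlo, qhi

    # -- state reconstruction ----------------------------------------------

    # decision variables are held in normalized units: joint velocities are
    # divided by _VS (rad/s) and accelerations by _AS (rad/s^2), so SLSQP
    # works on O(1) quantities throughout.
    _VS = 5.0
    _AS = 50.0

    def _states(self, Z):
        B = Z.shape[0]
        nf = self.ncf
        q0 = Z[:, :nf]
        qd0 = Z[:, nf: 2 * nf] * self._VS
        A = Z[:, 2 * nf:].reshape(B, self.N, nf) * self._AS
        Qd = qd0[:, None, :] + np.einsum("kl,blc->bkc", self.S, A)
        # positions by exact double integration of the piecewise-linear
        # acceleration: dq_k = h*qd_k + h^2*(a_k/3 + a_{k+1}/6)
        h = self.h
        dq = h * Qd[:, :-1] + h**2 * (A[:, :-1] / 3.0 + A[:, 1:] / 6.0)
        Q = q0[:, None, :] + np.concatenate(
            [np.zeros((B, 1, nf)), np.cumsum(dq, axis=1)], axis=1)
        if nf != self.nc:  # re-insert pinned coordinates as zeros
            full = np.zeros((3, B, self.N, self.nc))
            for arr, out in zip((Q, Qd, A), full):
                out[:, :, self.free] = arr
            Q, Qd, A = full
        return Q, Qd, A

    # -- batched evaluation -------------------------------------------------

    def _eval_batch(self, Z):
        """Z: (B, nvar) -> (eq (B, ne), ineq (B, ni), obj (B,))."""
        ad, st = self.ad, self.st
        B = Z.shape[0]
        Q, Qd, A = self._states(Z)

        # interval-interior states (closed form for piecewise-linear
        # acceleration) are constrained alongside the nodes, which rules out
        # node-feasible chatter policies with wild inter-node excursions;
        # torque and COP are quartic in time within an interval, so several
        # interior samples per interval are used
        h = self.h
        Qm_list, Qdm_list, Am_list = [], [], []
        for s in self.interior_offsets:
            sh = s * h
            ak, da = A[:, :-1], A[:, 1:] - A[:, :-1]
            Qds = Qd[:, :-1] + ak * sh + da * sh**2 / (2 * h)
            Qs = Q[:, :-1] + Qd[:, :-1] * sh + ak * sh**2 / 2 + da * sh**3 / (6 * h)
            Qm_list.append(Qs)
            Qdm_list.append(Qds)
            Am_list.append(ak + da * s)
        Qm = np.concatenate(Qm_list, axis=1)
        Qdm = np.concatenate(Qdm_list, axis=1)
        Am = np.concatenate(Am_list, axis=1)

        eq, ineq = [], []
        # initial COM state (phase containing node 0)
        ph0 = self.phases[0]
        pos0, vel0 = ph0.chain.com(Q[:, 0, ph0.coords], Qd[:, 0, ph0.coords])
        eq.append((pos0[:, 0] - self.x_i)[:, None] / ad.fl)
        if ad.enforce_height:
            htol = st.com_height_tol
            ineq.append(((pos0[:, 1] - (ad.ybar - htol)) / ad.fl)[:, None])
            ineq.append((((ad.ybar + htol) - pos0[:, 1]) / ad.fl)[:, None])
        obj = -self.sign * vel0[:, 0] / ad.vscale

        n_int = self.N - 1
        for ph in self.phases:
            iv = ph.nodes[ph.nodes < self.N - 1]  # interval k spans [k, k+1]
            mids = np.concatenate([iv + j * n_int
                                   for j in range(len(self.interior_offsets))])
            nn = len(ph.nodes) + len(mids)
            q = np.concatenate([Q[:, ph.nodes], Qm[:, mids]], axis=1)[:, :, ph.coords].reshape(B * nn, -1)
            qd = np.concatenate([Qd[:, ph.nodes], Qdm[:, mids]], axis=1)[:, :, ph.coords].reshape(B * nn, -1)
            qdd = np.concatenate([A[:, ph.nodes], Am[:, mids]], axis=1)[:, :, ph.coords].reshape(B * nn, -1)
            tau, grf, cop, mom = ph.chain.inverse_dynamics_full(q, qd, qdd, g=ad.g)
            tau = tau.reshape(B, nn, -1)
            grf = grf.reshape(B, nn, 2)
            mom = mom.reshape(B, nn)
            tl = ad.torque_limits[ph.coords]
            if ph.pivot:
                # passive rocker: zero actuation on the pivot coordinate
                eq.append(tau[:, :, 0].reshape(B, -1) / ad.tscale)
                body = np.arange(1, tau.shape[2])
            else:
                body = np.arange(tau.shape[2])
            ineq.append(((tau[:, :, body] - tl[None, None, body, 0]) / ad.tscale).reshape(B, -1))
            ineq.append(((tl[None, None, body, 1] - tau[:, :, body]) / ad.tscale).reshape(B, -1))
            if ad.contact_constraints:
                ineq.append((grf[:, :, 1] / ad.weight - st.grf_min_fraction).reshape(B, -1))
                if not ph.pivot:
                    # COP-in-support, multiplied through by grf_v to stay
                    # smooth: lo*grf_v <= mom <= hi*grf_v
                    lo_s, hi_s = ad.stance.bos_interval
                    scale = ad.weight * ad.fl
                    ineq.append(((mom - lo_s * grf[:, :, 1]) / scale).reshape(B, -1))
                    ineq.append(((hi_s * grf[:, :, 1] - mom) / scale).reshape(B, -1))

        # joint-angle windows along the motion (free coordinates only;
        # pinned coordinates are identically zero), midpoints included
        fr = self.free
        ineq.append(((Q[:, :, fr] - self.qlo[None][:, :, fr]) / np.pi).reshape(B, -1))
        ineq.append(((self.qhi[None][:, :, fr] - Q[:, :, fr]) / np.pi).reshape(B, -1))
        n_off = len(self.interior_offsets)
        qlo_m = np.tile(self.qlo[:-1], (n_off, 1))
        qhi_m = np.tile(self.qhi[:-1], (n_off, 1))
        ineq.append(((Qm[:, :, fr] - qlo_m[None][:, :, fr]) / np.pi).reshape(B, -1))
        ineq.append(((qhi_m[None][:, :, fr] - Qm[:, :, fr]) / np.pi).reshape(B, -1))

        # pivot-phase touchdown: foot coordinate lands at zero with zero speed
        fi = self.ad.foot_idx
        for k in self.switch_nodes:
            eq.append(Q[:, k, fi][:, None])
            eq.append(Qd[:, k, fi][:, None])

        # rest state at the final node
        vel_tol = st.rest_velocity_tol
        ineq.append(vel_tol - np.abs(Qd[:, -1, :]))
        ineq.append(vel_tol - np.abs(Qd[:, -2, :]))  # settle, not fly-through
        phT = self.phases[-1]
        qT = Q[:, -1, phT.coords]
        zeros = np.zeros_like(qT)
        tauS, grfS, copS = phT.chain.inverse_dynamics(qT, zeros, zeros, g=ad.g)
        tlT = ad.torque_limits[phT.coords]
        slack = st.equilibrium_residual_tol
        ineq.append((tauS - tlT[None, :, 0] + slack) / ad.tscale)
        ineq.append((tlT[None, :, 1] - tauS + slack) / ad.tscale)
        posT, _ = phT.chain.com(qT, zeros)
        lo_s, hi_s = ad.stance.bos_interval
        ineq.append(((posT[:, 0] - lo_s) / ad.fl)[:, None])
        ineq.append(((hi_s - posT[:, 0]) / ad.fl)[:, None])
        if ad.contact_constraints and not phT.pivot:
            ineq.append(((copS - lo_s) / ad.fl)[:, None])
            ineq.append(((hi_s - copS) / ad.fl)[:, None])

        eq = np.concatenate([e.reshape(B, -1) for e in eq], axis=1)
        ineq = np.concatenate([i.reshape(B, -1) for i in ineq], axis=1)
        return eq, ineq, obj

    def _ensure(self, z):
        z = np.asarray(z, dtype=float)
        if self._last is not None and np.array_equal(self._last[0], z):
            return self._last[1]
        n = z.size
        hstep = 1e-6
        Z = np.tile(z, (n + 1, 1))
        Z[1:] += np.eye(n) * hstep
        eq, ineq, obj = self._eval_batch(Z)
        vals = {
            "eq": eq[0], "ineq": ineq[0], "obj": obj[0],
            "eq_jac": (eq[1:] - eq[0]).T / hstep,
            "ineq_jac": (ineq[1:] - ineq[0]).T / hstep,
            "obj_jac": (obj[1:] - obj[0]) / hstep,
        }
        self._last = (z.copy(), vals)
        return vals

    def residual(self, z):
        v = self._ensure(z)
        r_eq = float(np.max(np.abs(v["eq"]))) if v["eq"].size else 0.0
        r_in = float(np.max(np.maximum(0.0, -v["ineq"]))) if v["ineq"].size else 0.0
        return max(r_eq, r_in)

    def solve(self, z0):
        cons = [
            {"type": "eq", "fun": lambda z: self._ensure(z)["eq"],
             "jac": lambda z: self._ensure(z)["eq_jac"]},
            {"type": "ineq", "fun": lambda z: self._ensure(z)["ineq"],
             "jac": lambda z: self._ensure(z)["ineq_jac"]},
        ]
        res = optimize.minimize(
            lambda z: self._ensure(z)["obj"],
            z0, jac=lambda z: self._ensure(z)["obj_jac"],
            bounds=self.bounds, constraints=cons, method="SLSQP",
            options={"maxiter": self.st.max_iter, "ftol": 1e-9},
        )
        return res

    # -- initial guesses ----------------------------------------------------

    def initial_guesses(self, rng: np.random.Generator):
        q0 = _static_posture(self.ad, self.x_i, self.mode0)[self.free]
        base = np.concatenate([q0, np.zeros(self.ncf), np.zeros(self.N * self.ncf)])
        guesses = [base]
        for _ in range(self.st.n_multistarts - 1):
            pert = np.concatenate([
                rng.normal(0.0, 0.08, self.ncf),
                rng.normal(0.0, 0.05, self.ncf),
                rng.normal(0.0, 0.03, self.N * self.ncf),
            ])
            guesses.append(np.clip(base + pert, self.bounds[:, 0], self.bounds[:, 1]))
        return guesses

    def package(self, z, res) -> ExtremalSolution:
        Q, Qd, A = self._states(np.asarray(z)[None, :])
        Q, Qd, A = Q[0], Qd[0], A[0]
        tau = np.zeros((self.N, self.nc))
        cop = np.zeros(self.N)
        grf = np.zeros((self.N, 2))
        for ph in self.phases:
            t_, g_, c_ = ph.chain.inverse_dynamics(Q[ph.nodes][:, ph.coords],
                                                   Qd[ph.nodes][:, ph.coords],
                                                   A[ph.nodes][:, ph.coords], g=self.ad.g)
            tau[np.ix_(ph.nodes, ph.coords)] = t_
            grf[ph.nodes] = g_
            cop[ph.nodes] = self.ad.pivot_x(ph.mode) if ph.pivot else c_
        ph0 = self.phases[0]
        _, vel0 = ph0.chain.com(Q[0, ph0.coords][None, :], Qd[0, ph0.coords][None, :])
        sched = tuple((ph.mode, int(ph.nodes[0])) for ph in self.phases)
        return ExtremalSolution(
            x_i=self.x_i, sense=self.sense,
            xdot=float(vel0[0, 0]), ydot=float(vel0[0, 1]),
            t=self.t, q=Q, qdot=Qd, qddot=A, torques=tau, cop=cop, grf=grf,
            mode_schedule=sched,
            diagnostics=SolverDiagnostics(status=str(res.message),
                                          iterations=int(res.nit),
                                          residual=float(self.residual(z)),
                                          schedule=sched),
        )


def _static_posture(ad: _Adapter, x_i: float, mode: ContactMode) -> np.ndarray:
    """A configuration placing the COM near (x_i, ybar), used as seed posture."""
    chain, coords = ad.chain_for(mode)
    nfull = ad.nc

    def pack(qc):
        q = np.zeros(nfull)
        q[coords] = qc
        return q

    lims = ad.angle_limits[coords]

    def resid(qc):
        pos, _ = chain.com(qc[None, :], np.zeros((1, len(coords))))
        r = [(pos[0, 0] - x_i) / ad.fl]
        if ad.enforce_height:
            r.append((pos[0, 1] - ad.ybar) / ad.fl)
        r.extend(0.05 * qc)
        return np.array(r)

    sol = optimize.least_squares(resid, np.zeros(len(coords)),
                                 bounds=(lims[:, 0], lims[:, 1]),
                                 xtol=1e-12, ftol=1e-12, max_nfev=200)
    return pack(sol.x)


# ---------------------------------------------------------------------------
# LIP transcription (COP-only control)
# ---------------------------------------------------------------------------


class _LipProblem:
    """Collocation on the point-mass dynamics xdd = omega^2 (x - u).

    Decision vector ``[x0, xd0, xdd at nodes]``; the COP command is
    recovered from the dynamics and constrained to the support.  Serves as
    the numerical counterpart of the closed-form balance bounds.
    """

    def __init__(self, model: BipedModel, stance: StanceSpec | None,
                 x_i: float, sense: str, settings: OptimizationSettings):
        self.m = model
        self.st = settings
        self.x_i = float(x_i)
        self.sense = sense
        self.sign = 1.0 if sense == Sense.MAX else -1.0
        self.N = settings.n_nodes
        self.h = settings.horizon / (self.N - 1)
        self.t = np.linspace(0.0, settings.horizon, self.N)
        self.S = _trap_matrix(self.N, self.h)
        self.stance = stance or StanceSpec((0.0, model.fl))
        self.vscale = model.fl * model.omega

    def _parts(self, z):
        x0, xd0 = z[0], z[1]
        a = np.asarray(z[2:])
        xd = xd0 + self.S @ a
        dx = self.h * xd[:-1] + self.h**2 * (a[:-1] / 3.0 + a[1:] / 6.0)
        x = x0 + np.concatenate([[0.0], np.cumsum(dx)])
        u = x - a / self.m.omega**2
        return x, xd, u

    def solve(self, z0):
        fl = self.m.fl
        lo, hi = self.stance.bos_interval
        vtol = self.st.rest_velocity_tol * self.vscale

        def eq(z):
            return np.array([z[0] - self.x_i]) / fl

        def ineq(z):
            x, xd, u = self._parts(z)
            return np.concatenate([
                (u - lo) / fl, (hi - u) / fl,
                [(vtol - abs(xd[-1])) / self.vscale, (vtol - abs(xd[-2])) / self.vscale],
                [(x[-1] - lo) / fl, (hi - x[-1]) / fl],
            ])

        def obj(z):
            return -self.sign * z[1] / self.vscale

        amax = 4.0 * fl * self.m.omega**2
        bounds = ([(None, None), (None, None)] + [(-amax, amax)] * self.N)
        res = optimize.minimize(
            obj, z0, method="SLSQP", bounds=bounds,
            constraints=[{"type": "eq", "fun": eq}, {"type": "ineq", "fun": ineq}],
            options={"maxiter": self.st.max_iter, "ftol": 1e-10})
        return res

    def residual(self, z):
        x, xd, u = self._parts(z)
        lo, hi = self.stance.bos_interval
        fl = self.m.fl
        vtol = self.st.rest_velocity_tol * self.vscale
        r = [abs(z[0] - self.x_i) / fl,
             max(0.0, float(np.max(u - hi)) / fl), max(0.0, float(np.max(lo - u)) / fl),
             max(0.0, (abs(xd[-1]) - vtol) / self.vscale),
             max(0.0, (lo - x[-1]) / fl), max(0.0, (x[-1] - hi) / fl)]
        return float(max(r))

    def package(self, z, res) -> ExtremalSolution:
        x, xd, u = self._parts(z)
        a = np.asarray(z[2:])
        return ExtremalSolution(
            x_i=self.x_i, sense=self.sense, xdot=float(xd[0]), ydot=0.0,
            t=self.t, q=x[:, None], qdot=xd[:, None], qddot=a[:, None],
            torques=np.zeros((self.N, 1)), cop=u,
            grf=np.column_stack([np.zeros(self.N), np.full(self.N, self.m.g)]),
            mode_schedule=((ContactMode.FLAT, 0),),
            diagnostics=SolverDiagnostics(status=str(res.message),
                                          iterations=int(res.nit),
                                          residual=float(self.residual(z))),
        )

    def initial_guesses(self, rng):
        base = np.zeros(self.N + 2)
        base[0] = self.x_i
        out = [base]
        for _ in range(self.st.n_multistarts - 1):
            p = base.copy()
            p[1] += rng.normal(0, 0.2 * self.vscale)
            p[2:] += rng.normal(0, 0.1 * self.m.fl * self.m.omega**2, self.N)
            out.append(p)
        return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _solve_problem(prob, settings, seed_seq):
    rng = np.random.default_rng(seed_seq)
    best = None
    tried = 0
    for z0 in prob.initial_guesses(rng):
        tried += 1
        res = prob.solve(z0)
        r = prob.residual(res.x)
        if r < settings.solver_tol:
            cand = prob.package(res.x, res)
            if best is None or prob.sign * cand.xdot > prob.sign * best.xdot:
                best = cand
    if best is not None:
        best = dataclasses.replace(
            best, diagnostics=dataclasses.replace(best.diagnostics, starts_tried=tried))
    return best


def extremize_initial_velocity(model, stance: StanceSpec | None, x_i: float,
                               sense: str, settings: OptimizationSettings | None = None):
    """Extremal feasible initial COM X velocity at position ``x_i``.

    Returns the best :class:`ExtremalSolution` over the contact-mode
    schedule library and seeded multistarts, or ``None`` when every attempt
    fails to reach a feasible recovery (the position is then outside the
    balanced region).
    """
    settings = settings or OptimizationSettings()
    if sense not in (Sense.MIN, Sense.MAX):
        raise ValueError("sense must be MIN or MAX")
    if not np.isfinite(x_i):
        raise ValueError("x_i must be finite")
    if isinstance(model, BipedModel) and model.kind is ModelKind.LIP:
        prob = _LipProblem(model, stance, x_i, sense, settings)
        seed = np.random.SeedSequence([settings.seed, _pos_key(x_i), 0, sense == Sense.MAX])
        return _solve_problem(prob, settings, seed)
    ad = _Adapter(model, stance)
    best = None
    sign = 1.0 if sense == Sense.MAX else -1.0
    for si, schedule in enumerate(ad.schedules(settings)):
        prob = _CollocationProblem(ad, x_i, sense, settings, schedule)
        seed = np.random.SeedSequence([settings.seed, _pos_key(x_i), si, sense == Sense.MAX])
        sol = _solve_problem(prob, settings, seed)
        if sol is not None and (best is None or sign * sol.xdot > sign * best.xdot):
            best = sol
    return best


def _pos_key(x):
    # stable non-negative integer key for a float position (< 2**31)
    return int(abs(hash(round(float(x), 12)))) % (2**31 - 1)


def build_bob(model, stance: StanceSpec | None, positions, settings=None) -> BoB:
    """Construct the BoB point by point over a grid of COM positions.

    MIN and MAX problems are solved independently at every position.
    Infeasible positions are retained as infeasible points.  Deterministic
    for a fixed ``settings.seed``.
    """
    settings = settings or OptimizationSettings()
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0 or np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be a nonempty strictly increasing grid")
    points = []
    for x_i in positions:
        lo = extremize_initial_velocity(model, stance, x_i, Sense.MIN, settings)
        hi = extremize_initial_velocity(model, stance, x_i, Sense.MAX, settings)
        if lo is None or hi is None:
            points.append(BoBPoint(x=float(x_i), ybar=model.ybar, feasible=False,
                                   diagnostics={"min_found": lo is not None,
                                                "max_found": hi is not None}))
            continue
        xdmin, xdmax = lo.xdot, hi.xdot
        if xdmin > xdmax:  # solver noise on a degenerate (single-velocity) point
            xdmin = xdmax = 0.5 * (xdmin + xdmax)
        points.append(BoBPoint(
            x=float(x_i), ybar=model.ybar, feasible=True,
            xdot_min=xdmin, xdot_max=xdmax,
            ydot_at_min=lo.ydot, ydot_at_max=hi.ydot,
            solutions=(lo, hi),
            diagnostics={"min": dataclasses.asdict(lo.diagnostics),
                         "max": dataclasses.asdict(hi.diagnostics)},
        ))
    return BoB(points=points, fl=model.fl, ybar=model.ybar, omega=model.omega,
               nondimensional=False, settings=settings)


def find_position_limits(model, stance: StanceSpec | None = None,
                         settings: OptimizationSettings | None = None,
                         bracket_tol: float = 0.01, max_extent: float = 3.0):
    """Extreme COM positions where the balanced region vanishes.

    Outward bisection from the support edges: expand until an infeasible
    position is found, then bisect to within ``bracket_tol`` (in units of
    the support length).  Returns ``(x_min, x_max)`` or the :data:`UNBOUNDED`
    sentinel for the LIP, whose analytic bounds impose no position limit.
    """
    if bracket_tol <= 0:
        raise ValueError("bracket_tol must be positive")
    if isinstance(model, BipedModel) and model.kind is ModelKind.LIP:
        return UNBOUNDED
    settings = settings or OptimizationSettings()
    stance = stance or StanceSpec((0.0, model.fl))
    lo_s, hi_s = stance.bos_interval
    fl = model.fl

    def feasible(x):
        return extremize_initial_velocity(model, stance, x, Sense.MAX, settings) is not None

    def search(edge, direction):
        step = 0.25 * fl
        inner = edge
        if not feasible(inner):
            return edge
        outer = None
        x = inner
        while abs(x - edge) < max_extent * fl:
            x = x + direction * step
            if feasible(x):
                inner = x
            else:
                outer = x
                break
        if outer is None:
            return x  # no loss of feasibility within the search extent
        while abs(outer - inner) > bracket_tol * fl:
            mid = 0.5 * (inner + outer)
            if feasible(mid):
                inner = mid
            else:
                outer = mid
        return 0.5 * (inner + outer)

    return (float(search(lo_s, -1.0)), float(search(hi_s, +1.0)))


# ---------------------------------------------------------------------------
# Certificate verification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CertificateReport:
    ok: bool
    max_violation: float
    rest_ok: bool
    details: dict


def verify_solution(model, stance: StanceSpec | None, sol: ExtremalSolution,
                    settings: OptimizationSettings | None = None,
                    factor: float = 10.0, n_check: int = 240) -> CertificateReport:
    """Independently re-check an extremal recovery motion.

    The solution's piecewise-linear acceleration profile is forward
    integrated from its initial state; torques, ground reaction and COP are
    recomputed by inverse dynamics along the integrated motion and every
    path constraint is checked within ``factor`` times the solver tolerance;
    the final state must pass the rest-state test.
    """
    settings = settings or OptimizationSettings()
    if isinstance(model, BipedModel) and model.kind is ModelKind.LIP:
        return _verify_lip(model, stance, sol, settings, factor, n_check)
    ad = _Adapter(model, stance)
    acc = interp1d(sol.t, sol.qddot, axis=0, assume_sorted=True)

    def f(t, y):
        nc = ad.nc
        return np.concatenate([y[nc:], acc(t)])

    y0 = np.concatenate([sol.q[0], sol.qdot[0]])
    ivp = solve_ivp(f, (sol.t[0], sol.t[-1]), y0, dense_output=True,
                    rtol=1e-10, atol=1e-12, max_step=sol.t[1] - sol.t[0])
    ts = np.linspace(sol.t[0], sol.t[-1], n_check)
    Y = ivp.sol(ts)
    q, qd = Y[: ad.nc].T, Y[ad.nc:].T
    tol = factor * settings.solver_tol
    worst = 0.0
    details = {}

    def track(name, margin):
        nonlocal worst
        v = float(np.max(np.maximum(0.0, -np.asarray(margin)))) if np.size(margin) else 0.0
        details[name] = max(details.get(name, 0.0), v)
        worst = max(worst, v)

    phases = ad.phases(_sched_fracs(sol, len(sol.t)), n_check)
    for ph in phases:
        idx = ph.nodes
        tau, grf, cop, mom = ph.chain.inverse_dynamics_full(
            q[idx][:, ph.coords], qd[idx][:, ph.coords],
            acc(ts[idx])[:, ph.coords], g=ad.g)
        tl = ad.torque_limits[ph.coords]
        if ph.pivot:
            track("pivot_torque", tol - np.abs(tau[:, 0]) / ad.tscale)
            body = np.arange(1, tau.shape[1])
        else:
            body = np.arange(tau.shape[1])
        track(f"torque_{ph.mode.value}",
              np.minimum(tau[:, body] - tl[None, body, 0],
                         tl[None, body, 1] - tau[:, body]) / ad.tscale)
        if ad.contact_constraints:
            track(f"grf_{ph.mode.value}",
                  grf[:, 1] / ad.weight - settings.grf_min_fraction / 2)
            if not ph.pivot:
                lo_s, hi_s = ad.stance.bos_interval
                scale = ad.weight * ad.fl
                track("cop", np.minimum(mom - lo_s * grf[:, 1],
                                        hi_s * grf[:, 1] - mom) / scale)
    track("angles", np.minimum(q - ad.angle_limits[None, :, 0],
                               ad.angle_limits[None, :, 1] - q) / np.pi)
    # rest-state test at the end
    rest_ok = bool(np.all(np.abs(qd[-1]) <= settings.rest_velocity_tol + tol))
    phT = phases[-1]
    zeros = np.zeros((1, len(phT.coords)))
    tauS, _, copS = phT.chain.inverse_dynamics(q[-1, phT.coords][None, :], zeros, zeros, g=ad.g)
    tlT = ad.torque_limits[phT.coords]
    slack = settings.equilibrium_residual_tol
    rest_ok &= bool(np.all(tauS[0] >= tlT[:, 0] - slack - tol * ad.tscale)
                    and np.all(tauS[0] <= tlT[:, 1] + slack + tol * ad.tscale))
    posT, _ = phT.chain.com(q[-1, phT.coords][None, :], zeros)
    lo_s, hi_s = ad.stance.bos_interval
    rest_ok &= bool(lo_s - tol * ad.fl <= posT[0, 0] <= hi_s + tol * ad.fl)
    ok = worst <= tol and rest_ok
    return CertificateReport(ok=bool(ok), max_violation=worst, rest_ok=rest_ok, details=details)


def _sched_fracs(sol: ExtremalSolution, n_nodes: int):
    return tuple((mode, start / (n_nodes - 1)) for mode, start in sol.mode_schedule)


def _verify_lip(model, stance, sol, settings, factor, n_check):
    stance = stance or StanceSpec((0.0, model.fl))
    lo, hi = stance.bos_interval
    acc = interp1d(sol.t, sol.qddot[:, 0], assume_sorted=True)

    def f(t, s):
        return [s[1], acc(t)]

    ivp = solve_ivp(f, (sol.t[0], sol.t[-1]), [sol.q[0, 0], sol.qdot[0, 0]],
                    dense_output=True, rtol=1e-10, atol=1e-12,
                    max_step=sol.t[1] - sol.t[0])
    ts = np.linspace(sol.t[0], sol.t[-1], n_check)
    x, xd = ivp.sol(ts)
    u = x - acc(ts) / model.omega**2
    tol = factor * settings.solver_tol
    worst = float(max(0.0, np.max(np.maximum(u - hi, lo - u)) / model.fl))
    vtol = settings.rest_velocity_tol * model.fl * model.omega
    rest_ok = bool(abs(xd[-1]) <= vtol + tol * model.fl * model.omega
                   and lo - tol * model.fl <= x[-1] <= hi + tol * model.fl)
    return CertificateReport(ok=worst <= tol and rest_ok, max_violation=worst,
                             rest_ok=rest_ok, details={"cop": worst})
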