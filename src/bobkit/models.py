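"""Planar biped models for sagittal-plane balance analysis.

Three model families are supported, in increasing order of complexity:

* ``LIP`` — a point mass at constant height ``ybar`` controlled only through
  the center of pressure (COP); it has closed-form balance bounds (see
  :mod:`bobkit.lip`).
* ``DOF4`` — a four-joint chain (ankle, knee, hip, upper-body) standing on a
  rigid foot that keeps flat ground contact at all times.
* ``DOF5`` — the same chain plus a foot coordinate realizing a two-segment
  foot: the foot may rock about its heel (``HEEL_PIVOT``) or about the
  metatarsal contact point with the toe segment flat (``TOE_PIVOT``).

All mechanics are expressed in the sagittal plane with X positive anterior,
Y up, and the ground-frame origin at the heel edge of the base of support,
so the support interval is ``[0, fl]``.

Joint angles are relative; a link's absolute orientation is measured from
the vertical (+Y), positive tilting anterior.  The upright reference posture
is ``q = 0``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ContactMode",
    "ModelKind",
    "AnthropometricSet",
    "BipedModel",
    "StanceSpec",
    "BodyConfiguration",
    "COMState",
    "ContactWrenchResult",
    "Violation",
    "ViolationReport",
    "ConfigurationError",
    "UnsupportedModelError",
    "reference_anthropometrics",
    "lip_model",
    "dof4_model",
    "dof5_model",
    "toy_pendulum_flywheel",
]

G_DEFAULT = 9.81


class ConfigurationError(ValueError):
    """Raised when a configuration does not match the model."""


class UnsupportedModelError(TypeError):
    """Raised when an operation does not apply to the model kind."""


class ContactMode(str, enum.Enum):
    FLAT = "FLAT"
    HEEL_PIVOT = "HEEL_PIVOT"
    TOE_PIVOT = "TOE_PIVOT"


class ModelKind(str, enum.Enum):
    LIP = "LIP"
    DOF4 = "DOF4"
    DOF5 = "DOF5"


@dataclass(frozen=True)
class COMState:
    """Sagittal-plane center-of-mass state (position and velocity)."""

    x: float
    y: float
    xdot: float
    ydot: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.xdot, self.ydot])


@dataclass(frozen=True)
class AnthropometricSet:
    """Subject segment parameters in SI units.

    ``segment_lengths`` etc. run bottom-up over the body links
    (shank, thigh, pelvis, upper body); the foot is described separately by
    ``foot_length`` and ``foot_geometry`` (heel→ankle, ankle→metatarsal,
    metatarsal→toe distances) plus ``foot_mass``.  Joint limit arrays cover
    the model coordinates in model order (DOF5 prepends the foot pivot).
    """

    segment_lengths: np.ndarray
    segment_masses: np.ndarray
    com_offsets: np.ndarray
    inertias: np.ndarray
    joint_angle_limits: np.ndarray  # (n_joints, 2)
    joint_torque_limits: np.ndarray  # (n_joints, 2)
    foot_length: float
    foot_geometry: tuple[float, float, float]
    foot_mass: float
    standing_com_height: float

    def __post_init__(self):
        for name in ("segment_lengths", "segment_masses", "com_offsets", "inertias"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(arr < 0) or (name in ("segment_lengths", "segment_masses") and np.any(arr <= 0)):
                raise ValueError(f"{name} must be positive")
        for name in ("joint_angle_limits", "joint_torque_limits"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 2)
            object.__setattr__(self, name, arr)
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"{name}: min must be < max for every joint")
        if self.foot_length <= 0:
            raise ValueError("foot_length must be positive")
        if abs(sum(self.foot_geometry) - self.foot_length) > 1e-9:
            raise ValueError("foot_geometry distances must sum to foot_length")
        if self.foot_mass <= 0:
            raise ValueError("foot_mass must be positive")
        if self.standing_com_height <= 0:
            raise ValueError("standing_com_height must be positive")

    @property
    def heel_to_ankle(self) -> float:
        return self.foot_geometry[0]

    @property
    def heel_to_metatarsal(self) -> float:
        return self.foot_geometry[0] + self.foot_geometry[1]

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.segment_masses) + self.foot_mass)


@dataclass(frozen=True)
class StanceSpec:
    """Base of support and permitted foot contact modes."""

    bos_interval: tuple[float, float]
    allowed_contact_modes: frozenset = frozenset({ContactMode.FLAT})

    def __post_init__(self):
        lo, hi = self.bos_interval
        if not hi > lo:
            raise ValueError("bos_interval must be a nonempty interval")
        modes = frozenset(ContactMode(m) for m in self.allowed_contact_modes)
        if ContactMode.FLAT not in modes:
            raise ValueError("FLAT contact must always be allowed")
        object.__setattr__(self, "allowed_contact_modes", modes)


@dataclass(frozen=True)
class BodyConfiguration:
    """Joint angles and velocities, in model coordinate order."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        q = np.atleast_1d(np.asarray(self.q, dtype=float))
        qd = np.atleast_1d(np.asarray(self.qdot, dtype=float))
        if q.shape != qd.shape:
            raise ConfigurationError("q and qdot must have the same shape")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "qdot", qd)


@dataclass(frozen=True)
class ContactWrenchResult:
    torques: np.ndarray
    grf_vertical: float
    grf_horizontal: float
    cop_x: float
    mode: ContactMode
    contact_separation: bool = False


@dataclass(frozen=True)
class Violation:
    name: str
    magnitude: float


@dataclass(frozen=True)
class ViolationReport:
    violations: tuple = ()

    @property
    def ok(self) -> bool:
        return len(self.violations) == 0

    def __iter__(self):
        return iter(self.violations)


# ---------------------------------------------------------------------------
# Planar chain mechanics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanarChain:
    """A serial chain of planar links pivoting above a fixed base point.

    Link ``i`` has absolute orientation ``offset[i] + cumsum(q)[i]`` measured
    from vertical; the next joint sits ``attach_d[i]`` along the link and the
    link COM at ``com_d[i]``.  ``static_masses`` are (mass, x, y) points that
    rest on the ground (foot segments in flat contact).
    """

    base: tuple[float, float]
    offsets: np.ndarray
    attach_d: np.ndarray
    com_d: np.ndarray
    masses: np.ndarray
    inertias: np.ndarray
    static_masses: tuple = ()

    @property
    def n(self) -> int:
        return len(self.offsets)

    def _kin(self, q, qd, qdd):
        """Batched link-COM kinematics.  q, qd, qdd: (B, n)."""
        th = self.offsets[None, :] + np.cumsum(q, axis=1)
        w = np.cumsum(qd, axis=1)
        al = np.cumsum(qdd, axis=1)
        s, c = np.sin(th), np.cos(th)
        d = np.stack([s, c], axis=-1)          # link direction
        dp = np.stack([c, -s], axis=-1)        # d(direction)/d(theta)
        # joint positions (B, n, 2): p_i = base + sum_{k<i} attach_k d_k
        seg = self.attach_d[None, :, None] * d
        p = np.cumsum(seg, axis=1) - seg + np.asarray(self.base)[None, None, :]
        r = p + self.com_d[None, :, None] * d
        # velocities / accelerations of joint positions then COMs
        segv = self.attach_d[None, :, None] * dp * w[..., None]
        sega = self.attach_d[None, :, None] * (dp * al[..., None] - d * w[..., None] ** 2)
        pv = np.cumsum(segv, axis=1) - segv
        pa = np.cumsum(sega, axis=1) - sega
        rv = pv + self.com_d[None, :, None] * dp * w[..., None]
        ra = pa + self.com_d[None, :, None] * (dp * al[..., None] - d * w[..., None] ** 2)
        return th, w, al, d, dp, p, r, rv, ra

    def com(self, q, qd):
        """Whole-body COM position and velocity, (B, 2) each."""
        q = np.atleast_2d(q)
        qd = np.atleast_2d(qd)
        *_, r, rv, _ = self._kin(q, qd, np.zeros_like(q))
        m = self.masses[None, :, None]
        num = np.sum(m * r, axis=1)
        vnum = np.sum(m * rv, axis=1)
        mtot = float(np.sum(self.masses))
        for ms, xs, ys in self.static_masses:
            num = num + ms * np.array([xs, ys])[None, :]
            mtot += ms
        return num / mtot, vnum / mtot

    def inverse_dynamics_full(self, q, qd, qdd, g=G_DEFAULT):
        """Like :meth:`inverse_dynamics`, additionally returning the ground
        moment about the origin (``mom = cop_x * grf_vertical``), which is
        polynomial in the states and safe to constrain when the vertical
        reaction may vanish."""
        q = np.atleast_2d(q)
        qd = np.atleast_2d(qd)
        qdd = np.atleast_2d(qdd)
        th, w, al, d, dp, p, r, rv, ra = self._kin(q, qd, qdd)
        m = self.masses[None, :, None]
        gvec = np.array([0.0, g])[None, None, :]
        F = m * (ra + gvec)                      # inertial + gravity load per link
        # tau_j = sum_{i>=j} (F_i . E_i + I_i al_i) + sum_{k>=j} G_k . (sum_{i>k} F_i)
        E = self.com_d[None, :, None] * dp
        S = np.sum(F * E, axis=-1) + self.inertias[None, :] * al
        Fsuf = np.cumsum(F[:, ::-1, :], axis=1)[:, ::-1, :]  # sum_{i>=k} F_i
        Fabove = Fsuf - F                                     # sum_{i>k}
        Gk = self.attach_d[None, :, None] * dp
        W = np.sum(Gk * Fabove, axis=-1)
        tau = np.cumsum((S + W)[:, ::-1], axis=1)[:, ::-1]
        # ground reaction: total wrench balance including static foot masses
        grf = np.sum(F, axis=1)
        mom = np.sum(F[..., 1] * r[..., 0] - F[..., 0] * r[..., 1]
                     + self.inertias[None, :] * al, axis=1)
        for ms, xs, ys in self.static_masses:
            grf = grf + np.array([0.0, ms * g])[None, :]
            mom = mom + ms * g * xs
        with np.errstate(divide="ignore", invalid="ignore"):
            cop = mom / grf[:, 1]
        return tau, grf, cop, mom

    def inverse_dynamics(self, q, qd, qdd, g=G_DEFAULT):
        """Joint torques, ground reaction and COP for prescribed motion.

        Batched over the leading axis.  Returns (tau (B,n), grf (B,2),
        cop_x (B,)).  COP may be non-finite where the vertical reaction
        vanishes.
        """
        tau, grf, cop, _ = self.inverse_dynamics_full(q, qd, qdd, g=g)
        return tau, grf, cop

    def mass_matrix(self, q, g=G_DEFAULT):
        """Joint-space inertia matrix at configuration q (n,)."""
        q = np.asarray(q, dtype=float)
        n = self.n
        z = np.zeros((1, n))
        h0, *_ = self.inverse_dynamics(q[None, :], z, z, g=0.0)
        M = np.empty((n, n))
        for j in range(n):
            e = np.zeros((1, n))
            e[0, j] = 1.0
            col, *_ = self.inverse_dynamics(q[None, :], z, e, g=0.0)
            M[:, j] = col[0] - h0[0]
        return M

    def bias(self, q, qd, g=G_DEFAULT):
        """Coriolis + gravity generalized forces h(q, qd)."""
        tau, *_ = self.inverse_dynamics(q[None, :], np.asarray(qd)[None, :],
                                        np.zeros((1, self.n)), g=g)
        return tau[0]

    def forward_dynamics(self, q, qd, tau, g=G_DEFAULT):
        M = self.mass_matrix(q)
        h = self.bias(q, qd, g=g)
        return np.linalg.solve(M, np.asarray(tau, dtype=float) - h)


# ---------------------------------------------------------------------------
# Biped model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BipedModel:
    """A planar biped, one of the LIP / 4-DOF / 5-DOF families."""

    kind: ModelKind
    params: AnthropometricSet | None
    dof_count: int
    g: float = G_DEFAULT
    fl: float = 0.23
    ybar: float = 1.12

    def __post_init__(self):
        expected = {ModelKind.LIP: 1, ModelKind.DOF4: 4, ModelKind.DOF5: 5}
        if self.dof_count != expected[ModelKind(self.kind)]:
            raise ValueError(f"dof_count {self.dof_count} inconsistent with kind {self.kind}")
        if self.kind is not ModelKind.LIP and self.params is None:
            raise ValueError("multi-link models require an AnthropometricSet")
        if self.params is not None:
            object.__setattr__(self, "fl", float(self.params.foot_length))
            object.__setattr__(self, "ybar", float(self.params.standing_com_height))

    @property
    def omega(self) -> float:
        return float(np.sqrt(self.g / self.ybar))

    # -- mode-wise chains ---------------------------------------------------

    def chain(self, mode: ContactMode = ContactMode.FLAT) -> PlanarChain:
        """Kinematic chain active in the given contact mode.

        Chain coordinates coincide with the model coordinates in FLAT mode
        for DOF4 and with all five model coordinates in the pivot modes of
        DOF5 (foot pivot first).  FLAT-mode DOF5 uses the four body
        coordinates; the foot coordinate is pinned at zero.
        """
        if self.kind is ModelKind.LIP:
            raise UnsupportedModelError("the LIP has no joint-space chain")
        p = self.params
        mode = ContactMode(mode)
        L = p.segment_lengths
        mlink = p.segment_masses
        cd = p.com_offsets
        In = p.inertias
        d_ha, d_am, d_mt = p.foot_geometry
        d_hm = d_ha + d_am
        body = dict(
            offsets=np.zeros(4), attach_d=L.copy(), com_d=cd.copy(),
            masses=mlink.copy(), inertias=In.copy(),
        )
        m_rear = p.foot_mass * d_hm / p.foot_length
        m_toe = p.foot_mass - m_rear
        if mode is ContactMode.FLAT:
            static = ((m_rear, d_hm / 2.0, 0.0), (m_toe, d_hm + d_mt / 2.0, 0.0))
            return PlanarChain(base=(d_ha, 0.0), static_masses=static, **body)
        if self.kind is not ModelKind.DOF5:
            raise UnsupportedModelError(f"{self.kind} does not support {mode}")
        if mode is ContactMode.HEEL_PIVOT:
            # whole (rigid) foot rotates about the heel; ankle is interior
            foot_com = (m_rear * d_hm / 2 + m_toe * (d_hm + d_mt / 2)) / p.foot_mass
            I_foot = (m_rear * d_hm**2 / 12 + m_rear * (d_hm / 2 - foot_com) ** 2
                      + m_toe * d_mt**2 / 12 + m_toe * (d_hm + d_mt / 2 - foot_com) ** 2)
            return PlanarChain(
                base=(0.0, 0.0),
                offsets=np.concatenate([[np.pi / 2], body["offsets"]]),
                attach_d=np.concatenate([[d_ha], body["attach_d"]]),
                com_d=np.concatenate([[foot_com], body["com_d"]]),
                masses=np.concatenate([[p.foot_mass], body["masses"]]),
                inertias=np.concatenate([[I_foot], body["inertias"]]),
            )
        # TOE_PIVOT: rearfoot rotates about the metatarsal point, toe flat
        return PlanarChain(
            base=(d_hm, 0.0),
            offsets=np.concatenate([[-np.pi / 2], body["offsets"]]),
            attach_d=np.concatenate([[d_am], body["attach_d"]]),
            com_d=np.concatenate([[d_hm / 2.0], body["com_d"]]),
            masses=np.concatenate([[m_rear], body["masses"]]),
            inertias=np.concatenate([[m_rear * d_hm**2 / 12], body["inertias"]]),
            static_masses=((m_toe, d_hm + d_mt / 2.0, 0.0),),
        )

    def chain_coords(self, mode: ContactMode = ContactMode.FLAT) -> np.ndarray:
        """Indices of model coordinates driving the chain of ``mode``."""
        if self.kind is ModelKind.DOF4:
            return np.arange(4)
        if ContactMode(mode) is ContactMode.FLAT:
            return np.arange(1, 5)  # foot coordinate pinned at 0
        return np.arange(5)

    def pivot_x(self, mode: ContactMode) -> float:
        mode = ContactMode(mode)
        if mode is ContactMode.HEEL_PIVOT:
            return 0.0
        if mode is ContactMode.TOE_PIVOT:
            return float(self.params.heel_to_metatarsal)
        raise ValueError("FLAT mode has no single pivot point")

    def _check_config(self, config: BodyConfiguration):
        if config.q.shape[0] != self.dof_count:
            raise ConfigurationError(
                f"configuration has {config.q.shape[0]} coordinates, model needs {self.dof_count}")

    def _chain_state(self, config: BodyConfiguration, mode: ContactMode):
        idx = self.chain_coords(mode)
        if self.kind is ModelKind.DOF5 and ContactMode(mode) is ContactMode.FLAT:
            if abs(config.q[0]) > 1e-9 or abs(config.qdot[0]) > 1e-9:
                raise ConfigurationError("FLAT contact requires the foot coordinate pinned at 0")
        return config.q[idx], config.qdot[idx], idx


def com_state(model: BipedModel, config: BodyConfiguration,
              mode: ContactMode = ContactMode.FLAT) -> COMState:
    """Whole-body COM position and velocity for a joint configuration.

    The COM is the mass-weighted aggregate of all link COMs (including foot
    segments resting on the ground).  For the LIP the configuration is the
    COM x coordinate itself and the height is fixed at ``ybar``.
    """
    if model.kind is ModelKind.LIP:
        if config.q.shape[0] != 1:
            raise ConfigurationError("LIP configuration is the scalar COM position")
        return COMState(float(config.q[0]), model.ybar, float(config.qdot[0]), 0.0)
    model._check_config(config)
    qc, qdc, _ = model._chain_state(config, mode)
    pos, vel = model.chain(mode).com(qc[None, :], qdc[None, :])
    return COMState(float(pos[0, 0]), float(pos[0, 1]), float(vel[0, 0]), float(vel[0, 1]))


def inverse_dynamics_contact(model: BipedModel, config: BodyConfiguration,
                             qddot: np.ndarray, mode: ContactMode) -> ContactWrenchResult:
    """Joint torques and contact wrench for a prescribed acceleration.

    In the pivot modes the contact is a passive rocker: the returned torque
    on the foot coordinate is the actuation that the contact would have to
    supply and must vanish for a physically consistent motion; the COP is
    reported at the pivot point.  A non-positive vertical reaction is
    reported through ``contact_separation``, not raised.
    """
    if model.kind is ModelKind.LIP:
        raise UnsupportedModelError("inverse dynamics is undefined for the LIP point mass")
    model._check_config(config)
    mode = ContactMode(mode)
    qdd = np.atleast_1d(np.asarray(qddot, dtype=float))
    if qdd.shape[0] != model.dof_count:
        raise ConfigurationError("qddot dimension mismatch")
    qc, qdc, idx = model._chain_state(config, mode)
    chain = model.chain(mode)
    tau_c, grf, cop = chain.inverse_dynamics(qc[None, :], qdc[None, :], qdd[idx][None, :], g=model.g)
    tau = np.zeros(model.dof_count)
    tau[idx] = tau_c[0]
    grf_v, grf_h = float(grf[0, 1]), float(grf[0, 0])
    cop_x = float(cop[0]) if grf_v > 0 else float("nan")
    if mode is not ContactMode.FLAT:
        cop_x = model.pivot_x(mode)
    return ContactWrenchResult(torques=tau, grf_vertical=grf_v, grf_horizontal=grf_h,
                               cop_x=cop_x, mode=mode, contact_separation=grf_v <= 0)


def constraint_violations(model: BipedModel, stance: StanceSpec, config: BodyConfiguration,
                          wrench: ContactWrenchResult, tol: float = 1e-9) -> ViolationReport:
    """Signed magnitudes of joint-angle, torque, COP and unilaterality violations.

    Report-only: an empty report means every constraint holds within ``tol``.
    In pivot modes the COP constraint is replaced by the passive-pivot
    condition (zero actuation on the foot coordinate).
    """
    model._check_config(config)
    out = []
    limits = model.params.joint_angle_limits
    tlimits = model.params.joint_torque_limits
    names = joint_names(model)
    for j in range(model.dof_count):
        lo, hi = limits[j]
        if config.q[j] < lo - tol:
            out.append(Violation(f"angle_{names[j]}_min", float(lo - config.q[j])))
        if config.q[j] > hi + tol:
            out.append(Violation(f"angle_{names[j]}_max", float(config.q[j] - hi)))
        lo, hi = tlimits[j]
        if wrench.torques[j] < lo - tol:
            out.append(Violation(f"torque_{names[j]}_min", float(lo - wrench.torques[j])))
        if wrench.torques[j] > hi + tol:
            out.append(Violation(f"torque_{names[j]}_max", float(wrench.torques[j] - hi)))
    if wrench.grf_vertical < -tol:
        out.append(Violation("grf_unilateral", float(-wrench.grf_vertical)))
    if wrench.mode is ContactMode.FLAT:
        lo, hi = stance.bos_interval
        if np.isfinite(wrench.cop_x):
            if wrench.cop_x < lo - tol:
                out.append(Violation("cop_out_of_support", float(lo - wrench.cop_x)))
            elif wrench.cop_x > hi + tol:
                out.append(Violation("cop_out_of_support", float(wrench.cop_x - hi)))
    else:
        pivot_tau = float(wrench.torques[0])
        if abs(pivot_tau) > tol:
            out.append(Violation("pivot_torque", abs(pivot_tau)))
    return ViolationReport(tuple(out))


def joint_names(model: BipedModel) -> list[str]:
    if model.kind is ModelKind.DOF4:
        return ["ankle", "knee", "hip", "upper"]
    if model.kind is ModelKind.DOF5:
        return ["foot", "ankle", "knee", "hip", "upper"]
    return ["com_x"]


# ---------------------------------------------------------------------------
# Reference parameter construction
# ---------------------------------------------------------------------------

# Winter-style segment fractions for a symmetric double stance (leg segments
# lumped pairwise): mass fractions of body mass, length fractions of an
# initial stature guess, COM offsets as fractions of segment length measured
# from the distal (lower) end.
_MASS_FRAC = {"foot": 0.029, "shank": 0.093, "thigh": 0.200, "pelvis": 0.281, "upper": 0.397}
_LEN0 = {"shank": 0.43, "thigh": 0.43, "pelvis": 0.25, "upper": 0.52}
_COM_FRAC = {"shank": 0.567, "thigh": 0.567, "pelvis": 0.50, "upper": 0.45}


def reference_anthropometrics(total_mass: float = 80.0, ybar: float = 1.12,
                              fl: float = 0.23) -> AnthropometricSet:
    """Proportional adult parameter set scaled to a prescribed COM height.

    Segment masses follow standard cadaver-table fractions; segment lengths
    start from stature-proportional values and are rescaled uniformly so the
    upright whole-body COM height equals ``ybar`` exactly (the foot rests on
    the ground and contributes at height zero).
    """
    names = ["shank", "thigh", "pelvis", "upper"]
    m = np.array([_MASS_FRAC[n] * total_mass for n in names])
    m_foot = _MASS_FRAC["foot"] * total_mass
    L = np.array([_LEN0[n] for n in names])
    cfrac = np.array([_COM_FRAC[n] for n in names])
    base = np.concatenate([[0.0], np.cumsum(L)[:-1]])
    com_y = base + cfrac * L
    scale = ybar * (np.sum(m) + m_foot) / np.sum(m * com_y)
    L *= scale
    inertias = m * L**2 / 12.0
    angle_limits = np.array([
        [-0.45, 0.45],   # foot pivot (restricted further per contact mode)
        [-0.70, 0.70],   # ankle
        [-2.20, 0.05],   # knee (flexion negative, small hyperextension)
        [-0.70, 2.10],   # hip
        [-1.00, 1.00],   # upper-body joint
    ])
    torque_limits = np.array([
        [-1e-6, 1e-6],   # foot pivot is a passive contact (zero-actuation band)
        [-220.0, 220.0],
        [-280.0, 280.0],
        [-360.0, 360.0],
        [-200.0, 200.0],
    ])
    return AnthropometricSet(
        segment_lengths=L, segment_masses=m, com_offsets=cfrac * L,
        inertias=inertias, joint_angle_limits=angle_limits,
        joint_torque_limits=torque_limits, foot_length=fl,
        foot_geometry=(0.25 * fl, 0.50 * fl, 0.25 * fl), foot_mass=m_foot,
        standing_com_height=ybar,
    )


def _trim_limits(params: AnthropometricSet, dof: int) -> AnthropometricSet:
    if params.joint_angle_limits.shape[0] == dof:
        return params
    # full 5-row tables drop the foot-pivot row for the 4-DOF model
    return replace(params,
                   joint_angle_limits=params.joint_angle_limits[-dof:],
                   joint_torque_limits=params.joint_torque_limits[-dof:])


def lip_model(fl: float = 0.23, ybar: float = 1.12, g: float = G_DEFAULT) -> BipedModel:
    return BipedModel(kind=ModelKind.LIP, params=None, dof_count=1, g=g, fl=fl, ybar=ybar)


def dof4_model(params: AnthropometricSet | None = None, g: float = G_DEFAULT) -> BipedModel:
    params = params or reference_anthropometrics()
    return BipedModel(kind=ModelKind.DOF4, params=_trim_limits(params, 4), dof_count=4, g=g)


def dof5_model(params: AnthropometricSet | None = None, g: float = G_DEFAULT) -> BipedModel:
    params = params or reference_anthropometrics()
    if params.joint_angle_limits.shape[0] != 5:
        raise ValueError("5-DOF model needs limits for the foot pivot coordinate")
    return BipedModel(kind=ModelKind.DOF5, params=params, dof_count=5, g=g)


# ---------------------------------------------------------------------------
# Toy benchmark mechanism
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyModel:
    """Pendulum + flywheel benchmark on a COP-limited ankle.

    A point mass on a massless leg hinged at the ankle, with a reaction
    flywheel at the top: the minimal mechanism exhibiting both COP control
    and the angular-momentum balance strategy.  Small enough for exhaustive
    policy-search cross-checks of the trajectory optimizer.
    """

    chain: PlanarChain
    fl: float
    ybar: float
    g: float
    torque_limits: np.ndarray  # (2, 2); row 0 = ankle, row 1 = flywheel
    angle_limits: np.ndarray
    kind: str = "TOY"
    dof_count: int = 2

    @property
    def omega(self) -> float:
        return float(np.sqrt(self.g / self.ybar))


def toy_pendulum_flywheel(mass: float = 70.0, ybar: float = 1.0, fl: float = 0.25,
                          flywheel_inertia: float = 4.0, flywheel_torque: float = 60.0,
                          ankle_x: float | None = None, g: float = G_DEFAULT) -> ToyModel:
    """Build the 2-link benchmark; ankle placed mid-support by default."""
    ankle_x = fl / 2.0 if ankle_x is None else ankle_x
    chain = PlanarChain(
        base=(ankle_x, 0.0),
        offsets=np.array([0.0, 0.0]),
        attach_d=np.array([ybar, 0.0]),
        com_d=np.array([ybar, 0.0]),
        masses=np.array([mass, 1e-6]),
        inertias=np.array([0.0, flywheel_inertia]),
    )
    # ankle torque bounded by what the COP can supply at rest: |tau| <= W * fl/2
    w = mass * g
    tau_ankle = w * min(ankle_x, fl - ankle_x)
    return ToyModel(
        chain=chain, fl=fl, ybar=ybar, g=g,
        torque_limits=np.array([[-tau_ankle, tau_ankle],
                                [-flywheel_torque, flywheel_torque]]),
        angle_limits=np.array([[-0.9, 0.9], [-50.0, 50.0]]),
    )
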