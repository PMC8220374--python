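"""Instantaneous state margins, experimental margin estimators and targets.

The extended margin of stability (eMOS) measures, along the position axis
of the COM state space, the signed distance from a state to the upper and
lower balance bounds: for a state ``(x, xdot)`` and a bound line
``xdot = a*x + b``, the bound position at the state's velocity is
``x_b = (xdot - b) / a`` and the margin is ``x_b - x`` (upper) or
``x - x_b`` (lower).  Positive margins mean the state is inside the bound;
the critical margin is the smaller in magnitude of the two, since it is
the nearer boundary that threatens balance.  For the LIP bounds the eMOS
reduces exactly to the classical XCoM margin of stability.

Experimental counterparts of the boundary margins are estimated from
recorded motions: the reachable margin from the extreme COM excursion at a
motion inversion, the viable margin from the most extreme initial state of
successful recovery trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .bob import BoB
from .geometry import BalanceCategory, BoundaryMargins, classify_state, _interp_bounds
from .lip import UNDEFINED, LinearBounds
from .models import COMState

__all__ = [
    "Trajectory",
    "EMOSResult",
    "EmosSeries",
    "TargetSpec",
    "TargetCategory",
    "BoundSide",
    "emos",
    "emos_series",
    "experimental_reachable_margin",
    "experimental_viable_margin",
    "make_targets",
    "UnsupportedCategoryError",
]


class BoundSide(str, enum.Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"


class TargetCategory(str, enum.Enum):
    A_REACHABLE = "A_REACHABLE"
    B_VIABLE = "B_VIABLE"
    C_VIAPOINT = "C_VIAPOINT"


class UnsupportedCategoryError(ValueError):
    """Requested target/sampling category is empty for this balanced region."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped COM states in the sagittal plane.

    ``stance_intact`` flags, per sample, whether the foot stance was
    preserved up to that instant.  Times must be strictly increasing; at
    least two samples are required.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    xdot: np.ndarray
    ydot: np.ndarray
    stance_intact: np.ndarray
    nondimensional: bool = False

    def __post_init__(self):
        for name in ("t", "x", "y", "xdot", "ydot"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "stance_intact",
                           np.asarray(self.stance_intact, dtype=bool))
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        n = self.t.size
        for name in ("x", "y", "xdot", "ydot", "stance_intact"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have the same length as t")

    def __len__(self):
        return self.t.size

    def state(self, k: int) -> COMState:
        return COMState(self.x[k], self.y[k], self.xdot[k], self.ydot[k])


@dataclass(frozen=True)
class EMOSResult:
    """Signed position distances from a COM state to the two bounds."""

    e_upper: float
    e_lower: float
    critical: float
    critical_side: BoundSide
    extrapolated: bool = False


@dataclass(frozen=True)
class EmosSeries:
    results: tuple
    frac_lower: float
    frac_upper: float
    min_critical: float

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    @property
    def critical(self) -> np.ndarray:
        return np.array([r.critical for r in self.results])


@dataclass(frozen=True)
class TargetSpec:
    category: TargetCategory
    target_state: COMState
    tolerance: float
    progression_index: int
    intended_emos: float | None = None


def emos(state: COMState, bounds: LinearBounds) -> EMOSResult:
    """eMOS of a single state against straight-line balance bounds.

    Both line slopes must be nonzero (the bound position at a given
    velocity is otherwise undefined).  Ties between equal-magnitude upper
    and lower margins resolve to LOWER.
    """
    a_u, b_u = bounds.upper
    a_l, b_l = bounds.lower
    if a_u == 0 or a_l == 0:
        raise ValueError("degenerate bounds: line slopes must be nonzero")
    x_u = (state.xdot - b_u) / a_u
    x_l = (state.xdot - b_l) / a_l
    e_upper = x_u - state.x
    e_lower = state.x - x_l
    if abs(e_lower) <= abs(e_upper):
        critical, side = e_lower, BoundSide.LOWER
    else:
        critical, side = e_upper, BoundSide.UPPER
    extrapolated = False
    if bounds.domain is not None:
        extrapolated = not (bounds.domain[0] <= state.x <= bounds.domain[1])
    return EMOSResult(e_upper=float(e_upper), e_lower=float(e_lower),
                      critical=float(critical), critical_side=side,
                      extrapolated=extrapolated)


def emos_series(traj: Trajectory, bounds: LinearBounds) -> EmosSeries:
    """Per-sample eMOS along a trajectory, with side fractions and minimum.

    The trajectory and bounds must share the same normalization.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if traj.nondimensional != bounds.nondimensional:
        raise ValueError("trajectory and bounds use different normalizations")
    results = tuple(emos(traj.state(k), bounds) for k in range(len(traj)))
    sides = np.array([r.critical_side is BoundSide.LOWER for r in results])
    crit = np.array([r.critical for r in results])
    return EmosSeries(results=results,
                      frac_lower=float(np.mean(sides)),
                      frac_upper=float(np.mean(~sides)),
                      min_critical=float(crit.min()))


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    pad = window // 2
    vp = np.pad(v, pad, mode="edge")
    out = np.convolve(vp, kernel, mode="same")[pad: pad + len(v)]
    return out


def experimental_reachable_margin(traj: Trajectory, direction: str,
                                  smooth_window: int = 5):
    """Extreme COM excursion beyond the support edge at a motion inversion.

    The COM velocity is smoothed with a centered moving average before the
    sign-change test.  Positive values lie outside the support (beyond the
    anterior edge for ``"ANT"``, the posterior edge for ``"POS"``);
    negative values mean the motion inverted inside the support.  Returns
    ``UNDEFINED`` when no inversion in the requested direction is found.
    """
    direction = direction.upper()
    if direction not in ("ANT", "POS"):
        raise ValueError("direction must be 'ANT' or 'POS'")
    v = _smooth(traj.xdot, smooth_window)
    s = np.sign(v)
    edge = 1.0 if traj.nondimensional else None
    if edge is None:
        raise ValueError("experimental margins are defined on nondimensional "
                         "trajectories (support [0, 1])")
    inversions = []
    for k in range(len(v) - 1):
        if direction == "ANT" and s[k] > 0 and s[k + 1] <= 0:
            inversions.append(k)
        if direction == "POS" and s[k] < 0 and s[k + 1] >= 0:
            inversions.append(k)
    if not inversions:
        return UNDEFINED
    if direction == "ANT":
        x_ext = max(np.max(traj.x[k: k + 2]) for k in inversions)
        return float(x_ext - 1.0)
    x_ext = min(np.min(traj.x[k: k + 2]) for k in inversions)
    return float(0.0 - x_ext)


def experimental_viable_margin(trials, direction: str):
    """Extreme successful initial COM position beyond the support edge.

    ``trials`` is an iterable of ``(COMState, success_flag)`` pairs in
    nondimensional units; a trial succeeds when rest was reached with the
    stance preserved.  Returns ``UNDEFINED`` when no trial succeeded.
    """
    direction = direction.upper()
    if direction not in ("ANT", "POS"):
        raise ValueError("direction must be 'ANT' or 'POS'")
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial set")
    xs = [s.x for s, ok in trials if ok]
    if not xs:
        return UNDEFINED
    if direction == "ANT":
        return float(max(xs) - 1.0)
    return float(0.0 - min(xs))


def make_targets(bob: BoB, margins: BoundaryMargins, category, n_levels: int,
                 direction: str = "POS", emos_levels=None,
                 tolerance: float = 0.05) -> list[TargetSpec]:
    """Exercise target states approaching a boundary margin.

    Category A targets approach the reachable margin from inside, B targets
    approach the viable margin (between the reachable and viable edges) and
    C targets are via-points at prescribed signed eMOS distances from the
    balanced-region boundary.  Every A/B target re-classifies into its
    intended partition.
    """
    category = TargetCategory(category)
    direction = direction.upper()
    if direction not in ("ANT", "POS"):
        raise ValueError("direction must be 'ANT' or 'POS'")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not bob.nondimensional:
        raise ValueError("make_targets expects a nondimensional BoB")
    sign = -1.0 if direction == "POS" else 1.0
    edge = 0.0 if direction == "POS" else 1.0

    if category is TargetCategory.A_REACHABLE:
        dr = margins.reachable_post if direction == "POS" else margins.reachable_ant
        if dr <= 0:
            raise UnsupportedCategoryError(
                f"the reachable partition is empty in the {direction} direction")
        out = []
        for i in range(1, n_levels + 1):
            frac = 0.9 * i / n_levels
            x = edge + sign * frac * dr
            lo, hi = _interp_bounds(bob, x)
            state = COMState(x, 1.0, 0.5 * (lo + hi), 0.0)
            out.append(TargetSpec(category=category, target_state=state,
                                  tolerance=tolerance, progression_index=i))
        _check_partition(out, bob, margins, BalanceCategory.REACHABLE)
        return out

    if category is TargetCategory.B_VIABLE:
        dr = margins.reachable_post if direction == "POS" else margins.reachable_ant
        dv = margins.viable_post if direction == "POS" else margins.viable_ant
        if dv is UNDEFINED:
            raise UnsupportedCategoryError(
                "the viable partition is undefined for this balanced region "
                "(the LIP bounds put no limit on COM position)")
        if dv <= max(dr, 0):
            raise UnsupportedCategoryError(
                f"the viable partition is empty in the {direction} direction")
        lo_m = max(dr, 0)
        out = []
        for i in range(1, n_levels + 1):
            frac = i / (n_levels + 1)
            d = lo_m + (0.95 * dv - lo_m) * frac if n_levels > 1 else 0.5 * (lo_m + 0.95 * dv)
            d = max(d, lo_m + 0.02 * (dv - lo_m))
            x = edge + sign * d
            lo, hi = _interp_bounds(bob, x)
            state = COMState(x, 1.0, 0.5 * (lo + hi), 0.0)
            out.append(TargetSpec(category=category, target_state=state,
                                  tolerance=tolerance, progression_index=i))
        _check_partition(out, bob, margins, BalanceCategory.VIABLE)
        return out

    # C: via-points at prescribed signed eMOS values
    from .geometry import fit_bounds

    bounds = fit_bounds(bob)
    if emos_levels is None:
        emos_levels = np.linspace(0.2, -0.2, n_levels)
    emos_levels = np.atleast_1d(np.asarray(emos_levels, dtype=float))
    out = []
    x_mid = 0.5 * sum(bounds.domain)
    for i, e in enumerate(emos_levels, start=1):
        # place the state on a horizontal offset e inward from the relevant
        # boundary line at the mid-domain velocity level
        if direction == "POS":
            a, b = bounds.lower
            xdot = a * x_mid + b
            x = (xdot - b) / a + e
        else:
            a, b = bounds.upper
            xdot = a * x_mid + b
            x = (xdot - b) / a - e
        state = COMState(float(x), 1.0, float(xdot), 0.0)
        out.append(TargetSpec(category=category, target_state=state,
                              tolerance=tolerance, progression_index=i,
                              intended_emos=float(e)))
    return out


def _check_partition(targets, bob, margins, expected: BalanceCategory):
    for t in targets:
        got = classify_state(t.target_state, bob, margins)
        if got is not expected:
            raise UnsupportedCategoryError(
                f"target at x={t.target_state.x:.3f} classifies as {got.value}, "
                f"expected {expected.value}")
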