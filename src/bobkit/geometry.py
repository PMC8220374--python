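"""Geometry of the balanced region: normalization, fitted bounds, margins.

COM states are nondimensionalized with position divided by the foot length
``fl`` and velocity by ``fl*omega``; in these units the base of support is
``[0, 1]``.  Straight lines are fitted to the upper and lower BoB point
sets, boundary margins are measured from the raw points (linear
interpolation between adjacent samples), and any COM state is classified
into one of the four balance categories.

Margins are reported as positive distances outward from the corresponding
support edge; a boundary crossing inside the support yields a negative
margin.
"""

from __future__ import annotations

import enum
from dataclasses import replace

import numpy as np

from .bob import BoB, UNBOUNDED
from .lip import UNDEFINED, BoundaryMargins, LinearBounds
from .models import COMState

__all__ = [
    "BalanceCategory",
    "BoundaryMargins",
    "InsufficientDataError",
    "nondimensionalize",
    "dimensionalize",
    "fit_bounds",
    "boundary_margins",
    "classify_state",
    "plot_bob",
]


class InsufficientDataError(ValueError):
    """Raised when too few feasible BoB points exist for an operation."""


class BalanceCategory(str, enum.Enum):
    STATIC = "STATIC"
    REACHABLE = "REACHABLE"
    VIABLE = "VIABLE"
    UNBALANCED = "UNBALANCED"


def _check_scales(fl: float, omega: float):
    if fl <= 0 or omega <= 0:
        raise ValueError("fl and omega must be positive")


def nondimensionalize(obj, fl: float, omega: float):
    """Map positions to x/fl and velocities to xdot/(fl*omega).

    Accepts a :class:`~bobkit.bob.BoB`, a :class:`~bobkit.models.COMState`
    or an ``(x, xdot)`` array pair and returns the nondimensional
    counterpart; :func:`dimensionalize` is its exact inverse.
    """
    _check_scales(fl, omega)
    vs = fl * omega
    if isinstance(obj, BoB):
        if obj.nondimensional:
            return obj
        pts = []
        for p in obj.points:
            if p.feasible:
                pts.append(replace(p, x=p.x / fl, ybar=p.ybar / fl,
                                   xdot_min=p.xdot_min / vs, xdot_max=p.xdot_max / vs,
                                   ydot_at_min=p.ydot_at_min / vs,
                                   ydot_at_max=p.ydot_at_max / vs))
            else:
                pts.append(replace(p, x=p.x / fl, ybar=p.ybar / fl))
        domain = obj.domain
        if isinstance(domain, tuple):
            domain = (domain[0] / fl, domain[1] / fl)
        return BoB(points=pts, fl=obj.fl, ybar=obj.ybar, omega=obj.omega,
                   nondimensional=True, settings=obj.settings, domain=domain)
    if isinstance(obj, COMState):
        return COMState(obj.x / fl, obj.y / fl, obj.xdot / vs, obj.ydot / vs)
    x, xdot = obj
    return np.asarray(x) / fl, np.asarray(xdot) / vs


def dimensionalize(obj, fl: float, omega: float):
    """Inverse of :func:`nondimensionalize`."""
    _check_scales(fl, omega)
    vs = fl * omega
    if isinstance(obj, BoB):
        if not obj.nondimensional:
            return obj
        pts = []
        for p in obj.points:
            if p.feasible:
                pts.append(replace(p, x=p.x * fl, ybar=p.ybar * fl,
                                   xdot_min=p.xdot_min * vs, xdot_max=p.xdot_max * vs,
                                   ydot_at_min=p.ydot_at_min * vs,
                                   ydot_at_max=p.ydot_at_max * vs))
            else:
                pts.append(replace(p, x=p.x * fl, ybar=p.ybar * fl))
        domain = obj.domain
        if isinstance(domain, tuple):
            domain = (domain[0] * fl, domain[1] * fl)
        return BoB(points=pts, fl=obj.fl, ybar=obj.ybar, omega=obj.omega,
                   nondimensional=False, settings=obj.settings, domain=domain)
    if isinstance(obj, COMState):
        return COMState(obj.x * fl, obj.y * fl, obj.xdot * vs, obj.ydot * vs)
    x, xdot = obj
    return np.asarray(x) * fl, np.asarray(xdot) * vs


def _feasible_arrays(points):
    pts = [p for p in points if p.feasible]
    x = np.array([p.x for p in pts])
    lo = np.array([p.xdot_min for p in pts])
    hi = np.array([p.xdot_max for p in pts])
    order = np.argsort(x)
    return x[order], lo[order], hi[order]


def _ols_line(x, y):
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return (float(coef[0]), float(coef[1])), float(r2)


def fit_bounds(points, nondimensional: bool = True) -> LinearBounds:
    """Least-squares lines through the upper and lower BoB point sets.

    Upper fits ``(x, xdot_max)`` and lower ``(x, xdot_min)`` separately;
    the domain is the position span of the feasible points.
    """
    if isinstance(points, BoB):
        nondimensional = points.nondimensional
        points = points.points
    x, lo, hi = _feasible_arrays(points)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 feasible BoB points to fit bounds")
    lower, r2_lo = _ols_line(x, lo)
    upper, r2_hi = _ols_line(x, hi)
    return LinearBounds(lower=lower, upper=upper, r2_lower=r2_lo, r2_upper=r2_hi,
                        domain=(float(x.min()), float(x.max())),
                        nondimensional=nondimensional)


def _zero_crossing(x, y, prefer: str):
    """Linear-interpolation zero crossing of a sampled boundary curve.

    ``prefer`` picks the crossing closest to the posterior ('post') or
    anterior ('ant') end when several exist; if no sign change occurs, the
    nearest end segment is extrapolated.
    """
    crossings = []
    for k in range(len(x) - 1):
        y0, y1 = y[k], y[k + 1]
        if y0 == y1:
            if y0 == 0.0:
                crossings.append(x[k])
            continue
        t = -y0 / (y1 - y0)
        if 0.0 <= t <= 1.0:
            crossings.append(x[k] + t * (x[k + 1] - x[k]))
    if crossings:
        return min(crossings) if prefer == "post" else max(crossings)
    # extrapolate from the outermost segment on the relevant side
    if prefer == "post":
        (x0, x1), (y0, y1) = x[:2], y[:2]
    else:
        (x0, x1), (y0, y1) = x[-2:], y[-2:]
    if y1 == y0:
        return np.nan
    return x0 - y0 * (x1 - x0) / (y1 - y0)


def boundary_margins(bob: BoB) -> BoundaryMargins:
    """Reachable and viable boundary margins of a nondimensional BoB.

    Reachable margins come from the zero-velocity crossings of the raw
    lower (posterior) and upper (anterior) boundary point sets, located by
    linear interpolation; viable margins come from the position-domain
    extremes (``UNDEFINED`` when the domain is unbounded, as for the LIP).
    """
    if not bob.nondimensional:
        raise ValueError("boundary_margins expects a nondimensional BoB "
                         "(see nondimensionalize)")
    x, lo, hi = _feasible_arrays(bob.points)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 feasible BoB points")
    x_post = _zero_crossing(x, lo, "post")
    x_ant = _zero_crossing(x, hi, "ant")
    if isinstance(bob.domain, tuple):
        v_post = -bob.domain[0]
        v_ant = bob.domain[1] - 1.0
    else:
        # UNBOUNDED (the LIP) or not computed: the sampled grid extremes are
        # not evidence of a position limit, so no viable margin is reported
        v_post = v_ant = UNDEFINED
    return BoundaryMargins(
        reachable_post=float(0.0 - x_post),
        reachable_ant=float(x_ant - 1.0),
        viable_post=v_post,
        viable_ant=v_ant,
    )


def _interp_bounds(bob: BoB, x):
    """Lower/upper boundary velocities at position x from the raw points
    (linear interpolation, end segments extrapolated)."""
    xs, lo, hi = _feasible_arrays(bob.points)

    def interp(y, xq):
        if len(xs) == 1:
            return y[0]
        k = np.clip(np.searchsorted(xs, xq) - 1, 0, len(xs) - 2)
        t = (xq - xs[k]) / (xs[k + 1] - xs[k])
        return y[k] + t * (y[k + 1] - y[k])

    return interp(lo, x), interp(hi, x)


def classify_state(state: COMState, bob: BoB,
                   margins: BoundaryMargins | None = None,
                   tol: float = 1e-9) -> BalanceCategory:
    """Balance category of a nondimensional COM state.

    UNBALANCED outside the BoB; otherwise STATIC when the COM ground
    projection lies over the support, REACHABLE within the reachable
    margins, VIABLE in the remainder of the balanced region.
    """
    if not bob.nondimensional:
        raise ValueError("classify_state expects a nondimensional BoB")
    if margins is None:
        margins = boundary_margins(bob)
    x, xdot = state.x, state.xdot
    if bob.domain != UNBOUNDED:
        domain = bob.domain if isinstance(bob.domain, tuple) else None
        if domain is None:
            xs, *_ = _feasible_arrays(bob.points)
            domain = (float(xs.min()), float(xs.max()))
        if x < domain[0] - tol or x > domain[1] + tol:
            return BalanceCategory.UNBALANCED
    lo, hi = _interp_bounds(bob, x)
    if xdot < lo - tol or xdot > hi + tol:
        return BalanceCategory.UNBALANCED
    if -tol <= x <= 1.0 + tol:
        return BalanceCategory.STATIC
    within_reach = (-margins.reachable_post - tol <= x <= 1.0 + margins.reachable_ant + tol)
    if within_reach:
        return BalanceCategory.REACHABLE
    return BalanceCategory.VIABLE


def plot_bob(bob: BoB, bounds: LinearBounds | None = None,
             margins: BoundaryMargins | None = None, ax=None, path=None):
    """State-space figure of the BoB points, fitted lines and partitions.

    Returns the matplotlib axes; saves to ``path`` (SVG/PNG by extension)
    when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    x, lo, hi = _feasible_arrays(bob.points)
    ax.plot(x, hi, "o-", color="tab:red", label="upper BoB")
    ax.plot(x, lo, "s-", color="tab:blue", label="lower BoB")
    if bounds is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, bounds.upper_at(xs), "--", color="tab:red", alpha=0.6)
        ax.plot(xs, bounds.lower_at(xs), "--", color="tab:blue", alpha=0.6)
    for edge in (0.0, 1.0) if bob.nondimensional else (0.0, bob.fl):
        ax.axvline(edge, color="k", lw=0.8, alpha=0.5)
    if margins is not None and bob.nondimensional:
        ax.axvline(-margins.reachable_post, color="tab:green", ls=":", label="reachable margin")
        ax.axvline(1.0 + margins.reachable_ant, color="tab:green", ls=":")
    unit = "(nondimensional)" if bob.nondimensional else "(m, m/s)"
    ax.set_xlabel(f"COM position {unit}")
    ax.set_ylabel(f"COM velocity {unit}")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
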