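"""Closed-form balance analytics for the linear inverted pendulum (LIP).

The LIP keeps a point mass at constant height ``ybar`` and is controlled
only through the center of pressure ``u`` within the base of support
``[0, fl]``; its dynamics are ``xdd = omega**2 * (x - u)`` with natural
frequency ``omega = sqrt(g / ybar)``.

Balance of a LIP state is governed by the extrapolated center of mass,
``XCoM = x + xdot / omega``: a state can be brought to rest without moving
the feet iff the XCoM lies inside the base of support.  Written as bounds
on the velocity this is ``-omega*x <= xdot <= -omega*x + fl*omega``, a pair
of parallel lines in the (x, xdot) plane; in nondimensional coordinates
(x/fl, xdot/(fl*omega)) the bounds are ``-x <= xdot <= -x + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LipParams",
    "LinearBounds",
    "UNDEFINED",
    "xcom",
    "lip_bounds",
    "lip_boundary_margins",
]


class _Undefined:
    """Sentinel for margins the model does not define (not zero, not inf)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNDEFINED"

    def __bool__(self):
        return False


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class LipParams:
    fl: float
    ybar: float
    g: float = 9.81

    def __post_init__(self):
        if self.fl <= 0 or self.ybar <= 0 or self.g <= 0:
            raise ValueError("fl, ybar and g must all be positive")

    @property
    def omega(self) -> float:
        return math.sqrt(self.g / self.ybar)


@dataclass(frozen=True)
class LinearBounds:
    """Upper and lower straight-line bounds on COM velocity vs position.

    Each line is (slope, intercept) in the (x, xdot) plane.  ``domain`` is
    the position interval on which the bounds are valid; ``None`` flags an
    unbounded domain (the LIP case).  ``r2_*`` report fit quality and equal
    1 for analytic bounds.
    """

    lower: tuple[float, float]
    upper: tuple[float, float]
    r2_lower: float = 1.0
    r2_upper: float = 1.0
    domain: tuple[float, float] | None = None
    nondimensional: bool = True

    def __post_init__(self):
        if self.domain is not None:
            a, b = self.domain
            if not b >= a:
                raise ValueError("domain must be a nonempty interval")
            for x in (a, b):
                lo = self.lower[0] * x + self.lower[1]
                hi = self.upper[0] * x + self.upper[1]
                if hi < lo - 1e-9:
                    raise ValueError("upper bound must dominate lower bound on the domain")

    def lower_at(self, x):
        return self.lower[0] * np.asarray(x) + self.lower[1]

    def upper_at(self, x):
        return self.upper[0] * np.asarray(x) + self.upper[1]

    def contains(self, x, xdot, tol: float = 0.0):
        x = np.asarray(x)
        xdot = np.asarray(xdot)
        inside = (xdot >= self.lower_at(x) - tol) & (xdot <= self.upper_at(x) + tol)
        if self.domain is not None:
            inside &= (x >= self.domain[0] - tol) & (x <= self.domain[1] + tol)
        return inside


@dataclass(frozen=True)
class BoundaryMargins:
    """Reachable and viable boundary margins, as fractions of foot length.

    Positive values measure outward from the base-of-support edge (0 for the
    posterior edge, 1 anterior, nondimensionally); negative values flag a
    boundary crossing inside the support.  Viable margins are ``UNDEFINED``
    for the LIP, whose analytic bounds put no limit on COM position.
    """

    reachable_post: float
    reachable_ant: float
    viable_post: float | _Undefined
    viable_ant: float | _Undefined

    def __post_init__(self):
        for r, v in ((self.reachable_post, self.viable_post),
                     (self.reachable_ant, self.viable_ant)):
            if not isinstance(v, _Undefined) and v < r - 1e-9:
                raise ValueError("viable margin cannot be smaller than reachable margin")


def xcom(x, xdot, omega: float):
    """Extrapolated center of mass, ``x + xdot / omega``."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return np.asarray(x) + np.asarray(xdot) / omega


def lip_bounds(params: LipParams, nondimensional: bool = True) -> LinearBounds:
    """Analytic LIP balance bounds.

    Nondimensional: ``-x <= xdot <= -x + 1``.  Dimensional:
    ``-omega*x <= xdot <= -omega*x + fl*omega``.  The position domain is
    unbounded (``domain=None``): any COM position admits a balanced velocity.
    """
    if nondimensional:
        return LinearBounds(lower=(-1.0, 0.0), upper=(-1.0, 1.0),
                            domain=None, nondimensional=True)
    w = params.omega
    return LinearBounds(lower=(-w, 0.0), upper=(-w, params.fl * w),
                        domain=None, nondimensional=False)


def lip_boundary_margins(params: LipParams) -> BoundaryMargins:
    """Boundary margins of the analytic LIP balanced region.

    The zero-velocity crossings of the bounds sit exactly at the support
    edges, so both reachable margins are zero; the bounds put no limit on
    position, so the viable margins are undefined.
    """
    bounds = lip_bounds(params, nondimensional=False)
    # zero-velocity crossings: xdot = a x + b = 0  =>  x = -b / a
    x_post = -bounds.lower[1] / bounds.lower[0]
    x_ant = -bounds.upper[1] / bounds.upper[0]
    post = (0.0 - x_post) / params.fl
    ant = (x_ant - params.fl) / params.fl
    # the crossings sit analytically on the edges; drop float residue
    if abs(post) < 1e-12:
        post = 0.0
    if abs(ant) < 1e-12:
        ant = 0.0
    return BoundaryMargins(
        reachable_post=float(post),
        reachable_ant=float(ant),
        viable_post=UNDEFINED,
        viable_ant=UNDEFINED,
    )
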