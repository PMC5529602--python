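"""Shape constants, plunger forces and impulse-height relations.

Integrating the chamber pressure over the plunger yields a force with two
parts: a Stefan squeeze-film term, inversely proportional to the cube of the
gap height (the viscous adhesion of two closely spaced plates), and a
proboscis-column term from the liquid column the pump drags through the food
canal.  The chamber geometry enters the Stefan term only through a shape
constant -- the integral of the harmonic correction P~ over the footprint:

    C_r(W/L, g)   = int P~_r dX dY        (rectangle)
    C_c(theta)    = int P~_c r dr dphi    (disk)

Both constants are negative for any partial opening and vanish only in the
all-opening disk limit theta = pi.  Because the force scales as h^(-3), the
quantity a muscle controls is not the force but its time integral, the
impulse Pi = -int F dt, which depends only on the gap-height endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .chamber_bvp import (
    ConvergenceRecord,
    ScalarField,
    integrate_field,
    refine_until_converged,
)
from .morphometrics import (
    ChamberGeometry,
    FluidProperties,
    PlungerKinematics,
    ProboscisGeometry,
    Shape,
)


@dataclass
class ShapeConstants:
    """A computed shape constant with its refinement provenance."""

    shape: Shape
    C: float
    aspect: Optional[float] = None
    g: Optional[float] = None
    theta: Optional[float] = None
    convergence: Optional[ConvergenceRecord] = None

    @property
    def converged(self) -> bool:
        return self.convergence is None or self.convergence.converged


def shape_constant(field: ScalarField,
                   convergence: Optional[ConvergenceRecord] = None) -> ShapeConstants:
    """Shape constant by vertex-average quadrature: the sum over triangles of
    the area times the mean of the three vertex values of P~.

    A non-converged refinement record does not abort the quadrature; the
    result is merely flagged through ``convergence``.
    """
    mesh = field.mesh
    return ShapeConstants(
        shape=mesh.shape,
        C=integrate_field(field),
        aspect=mesh.aspect,
        g=mesh.g,
        theta=mesh.theta,
        convergence=convergence,
    )


def compute_shape_constant(
    chamber: ChamberGeometry,
    tol: float = 0.005,
    max_refinements: int = 30,
    base_level: int = 0,
) -> ShapeConstants:
    """Solve the P~ problem for ``chamber`` adaptively and integrate it."""
    _, field, record = refine_until_converged(
        chamber, tol=tol, max_refinements=max_refinements, base_level=base_level)
    return shape_constant(field, record)


def _bracket_term(C: float, chamber: ChamberGeometry) -> float:
    """The Stefan bracket: ``C_r - W/(12 L)`` or ``C_c - pi/8`` (both < 0)."""
    if chamber.shape is Shape.RECTANGULAR:
        return C - chamber.aspect / 12.0
    return C - math.pi / 8.0


@dataclass
class ForceResult:
    """Force exerted by the fluid on the plunger (N); the muscle supplies
    the opposite.  Both terms resist the stroke: total * dh/dt <= 0."""

    total: float
    stefan_term: float
    column_term: float


def plunger_force(
    C: ShapeConstants | float,
    chamber: ChamberGeometry,
    proboscis: ProboscisGeometry,
    fluid: FluidProperties,
    kin: PlungerKinematics,
) -> ForceResult:
    """Total plunger force and its Stefan / proboscis-column decomposition.

    Rectangular: ``F = (12 eta/h^3)(dh/dt) L^4 [C_r - W/(12L)]
    - (dh/dt) (128 eta l_p/(pi d_p^4)) (LW)^2``; circular with ``R^4`` and
    ``[C_c - pi/8]``, column factor ``128 eta pi l_p R^4 / d_p^4``.
    """
    Cval = C.C if isinstance(C, ShapeConstants) else float(C)
    if not kin.h > 0:
        raise ValueError("h must be > 0")
    eta, h, dhdt = fluid.eta, kin.h, kin.dhdt
    l4 = chamber.yardstick**4
    stefan = (12.0 * eta / h**3) * dhdt * l4 * _bracket_term(Cval, chamber)
    if chamber.shape is Shape.RECTANGULAR:
        column = -dhdt * (128.0 * eta * proboscis.l_p /
                          (math.pi * proboscis.d_p**4)) * chamber.area**2
    else:
        column = -dhdt * (128.0 * eta * math.pi * proboscis.l_p /
                          proboscis.d_p**4) * chamber.R**4
    return ForceResult(total=stefan + column, stefan_term=stefan, column_term=column)


@dataclass
class ImpulseResult:
    """Normalised impulse ``Pi d_p^2 / (6 eta l_i^4)`` between two
    dimensionless gap heights ``H0 -> H`` (``H = h/d_p``)."""

    value: float
    H: float
    H0: float


def impulse_height_relation(
    H: float,
    H0: float,
    C: ShapeConstants | float,
    chamber: ChamberGeometry,
    proboscis: ProboscisGeometry,
) -> float:
    """Normalised impulse of muscular force for the expansion ``H0 -> H``.

    Rectangular:
    ``-(C_r - W/(12L)) (1/H0^2 - 1/H^2) + (64/3)(l_p/(pi d_p))(W/L)^2 (H - H0)``;
    circular with ``(C_c - pi/8)`` and ``(64/3) pi (l_p/d_p) (H - H0)``.
    Equals ``Pi d_p^2 / (6 eta l_i^4)`` where ``Pi = -int F dt``; the relation
    is path-independent (depends on the gap-height endpoints only).
    """
    if not (H > 0 and H0 > 0):
        raise ValueError("H and H0 must be > 0")
    Cval = C.C if isinstance(C, ShapeConstants) else float(C)
    bracket = _bracket_term(Cval, chamber)
    term1 = -bracket * (1.0 / H0**2 - 1.0 / H**2)
    ratio = proboscis.l_p / proboscis.d_p
    if chamber.shape is Shape.RECTANGULAR:
        term2 = (64.0 / 3.0) * (ratio / math.pi) * chamber.aspect**2 * (H - H0)
    else:
        term2 = (64.0 / 3.0) * math.pi * ratio * (H - H0)
    return term1 + term2


def height_from_impulse(
    Pi_normalized: float,
    H0: float,
    C: ShapeConstants | float,
    chamber: ChamberGeometry,
    proboscis: ProboscisGeometry,
    H_max: float = 1e12,
) -> float:
    """Invert the impulse-height relation on the expansion branch.

    The relation is strictly increasing in ``H`` (both terms have positive
    derivative since the Stefan bracket is negative), so the root ``H >= H0``
    is unique; found by bracketed root-finding to 1e-10 relative tolerance.
    """
    if Pi_normalized < 0:
        raise ValueError("expansion-branch impulse must be >= 0")
    if Pi_normalized == 0:
        return H0

    def fun(H: float) -> float:
        return impulse_height_relation(H, H0, C, chamber, proboscis) - Pi_normalized

    hi = 2.0 * H0
    while fun(hi) < 0:
        hi *= 2.0
        if hi > H_max:
            raise RuntimeError(
                f"no bracket for the requested impulse below H_max={H_max}")
    return brentq(fun, H0, hi, rtol=1e-12, xtol=1e-300, maxiter=200)
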