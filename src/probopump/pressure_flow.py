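"""Assemble chamber pressure fields and couple them to the proboscis.

The dimensionless chamber pressure splits as ``P = P_squeeze + P~ + K``:

- ``P_squeeze`` is the particular solution of the volumetric squeezing
  problem (``X^2/2 - 1/8`` on the rectangle, ``r^2/4 - 1/4`` on the disk),
- ``P~`` is the harmonic wall correction solved in :mod:`~probopump.chamber_bvp`,
- ``K`` is the constant opening pressure imposed by the Hagen-Poiseuille
  coupling of the food canal,
  ``K_i = -(32 h^3 l_p A_i) / (3 l_i^2 pi d_p^4)``.

Dimensional pressure is ``p = (12 eta l_i^2 / h^3) (dh/dt) P`` with the
yardstick ``l_r = L`` (rectangle) or ``l_c = R`` (disk); the depth-averaged
lubrication velocity is ``V = -(h^2 / (12 eta)) grad p``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chamber_bvp import (
    ConvergenceRecord,
    ScalarField,
    boundary_flux_through_opening,
    gradient,
)
from .morphometrics import (
    ChamberGeometry,
    FluidProperties,
    PlungerKinematics,
    ProboscisGeometry,
    Shape,
)

logger = logging.getLogger("probopump")


class GeometryFieldMismatch(ValueError):
    """The solved field and the requested chamber geometry disagree."""


def squeeze_pressure(shape: Shape | str, coords: np.ndarray,
                     aspect: Optional[float] = None) -> np.ndarray:
    """Volumetric squeeze part of the dimensionless pressure (excluding K).

    ``X^2/2 - 1/8`` for the rectangle, ``r^2/4 - 1/4`` for the disk; both
    vanish on the chamber boundary rim at ``X = +-1/2`` / ``r = 1``.
    """
    shape = Shape(shape)
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    tol = 1e-9
    if shape is Shape.RECTANGULAR:
        X, Y = pts[:, 0], pts[:, 1]
        if np.any(np.abs(X) > 0.5 + tol):
            raise ValueError("coordinates outside the unit-length rectangle")
        if aspect is not None and np.any(np.abs(Y) > aspect / 2 + tol):
            raise ValueError("coordinates outside the chamber width")
        out = X**2 / 2 - 0.125
    else:
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        if np.any(r2 > 1 + 2 * tol):
            raise ValueError("coordinates outside the unit disk")
        out = r2 / 4 - 0.25
    return out if np.ndim(coords) > 1 else float(out[0])


def compute_K(chamber: ChamberGeometry, proboscis: ProboscisGeometry, h: float) -> float:
    """Dimensionless coupling pressure at the opening,
    ``K_i = -(32 h^3 l_p A_i)/(3 l_i^2 pi d_p^4)`` (always <= 0).

    For the circular chamber the areas and radii cancel to
    ``K_c = -(32/3) f`` with ``f = l_p h^3 / d_p^4``; for the rectangular one
    ``K_r = -(32/(3 pi)) f (W/L)``.
    """
    if not h >= 0:
        raise ValueError("h must be >= 0")
    l_i = chamber.yardstick
    return -(32.0 * h**3 * proboscis.l_p * chamber.area) / (
        3.0 * l_i**2 * math.pi * proboscis.d_p**4
    )


@dataclass
class PressureAssembly:
    """Total dimensionless pressure ``P = P_squeeze + P~ + K`` on a mesh,
    together with the ingredients needed to dimensionalise it."""

    field: ScalarField            # total dimensionless P
    ptilde: ScalarField           # harmonic correction P~
    K: float
    chamber: ChamberGeometry
    proboscis: ProboscisGeometry
    h: float
    converged: bool = True

    @property
    def yardstick(self) -> float:
        return self.chamber.yardstick

    def pressure_scale(self, fluid: FluidProperties, dhdt: float) -> float:
        """Pressure scale (Pa): ``12 eta l_i^2 / h^3 * dh/dt``."""
        return 12.0 * fluid.eta * self.yardstick**2 / self.h**3 * dhdt


def _check_match(ptilde: ScalarField, chamber: ChamberGeometry) -> None:
    mesh = ptilde.mesh
    if mesh.shape is not chamber.shape:
        raise GeometryFieldMismatch(
            f"field solved on a {mesh.shape.value} footprint, chamber is "
            f"{chamber.shape.value}")
    if chamber.shape is Shape.RECTANGULAR:
        ok = (math.isclose(mesh.aspect, chamber.aspect, rel_tol=1e-9)
              and math.isclose(mesh.g, min(chamber.g, chamber.aspect), rel_tol=1e-9))
    else:
        ok = math.isclose(mesh.theta, min(chamber.theta, math.pi), rel_tol=1e-9)
    if not ok:
        raise GeometryFieldMismatch(
            "dimensionless parameters of the solved mesh do not match the chamber")


def assemble_pressure(
    ptilde: ScalarField,
    chamber: ChamberGeometry,
    proboscis: ProboscisGeometry,
    h: float,
    convergence: Optional[ConvergenceRecord] = None,
) -> PressureAssembly:
    """Nodewise total ``P = P_squeeze + P~ + K``.  On the opening the squeeze
    part and P~ vanish, so ``P = K`` there exactly."""
    _check_match(ptilde, chamber)
    K = compute_K(chamber, proboscis, h)
    sq = squeeze_pressure(chamber.shape, ptilde.mesh.nodes)
    total = ScalarField(ptilde.mesh, sq + ptilde.values + K, name="P")
    converged = True if convergence is None else convergence.converged
    return PressureAssembly(field=total, ptilde=ptilde, K=K, chamber=chamber,
                            proboscis=proboscis, h=h, converged=converged)


def dimensional_pressure(
    assembly: PressureAssembly, fluid: FluidProperties, kin: PlungerKinematics
) -> ScalarField:
    """Dimensional pressure field ``p = scale * P`` in Pa (gauge, relative to
    atmospheric).  During the uptake stroke (``dh/dt > 0``) all nodal values
    are <= 0: the chamber is everywhere under suction."""
    if not math.isclose(kin.h, assembly.h, rel_tol=1e-9):
        raise GeometryFieldMismatch(
            f"kinematics h={kin.h} differs from the assembly height h={assembly.h}")
    scale = assembly.pressure_scale(fluid, kin.dhdt)
    return ScalarField(assembly.field.mesh, scale * assembly.field.values,
                       name="p", units="Pa")


def velocity_field(p: ScalarField, h: float, fluid: FluidProperties) -> np.ndarray:
    """Depth-averaged lubrication velocity ``V = -(h^2/(12 eta)) grad p``,
    one (Vx, Vy) per triangle (piecewise-constant gradients)."""
    if not h > 0:
        raise ValueError("h must be > 0")
    g = gradient(p.mesh, p.values)
    return -(h**2 / (12.0 * fluid.eta)) * g


def nodal_velocities(p: ScalarField, h: float, fluid: FluidProperties) -> np.ndarray:
    """Area-weighted nodal average of the per-triangle velocities (for
    export; avoids spurious extrema at the singular opening corners)."""
    v = velocity_field(p, h, fluid)
    mesh = p.mesh
    w = mesh.areas
    num = np.zeros((mesh.n_nodes, 2))
    den = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], v * w[:, None])
        np.add.at(den, mesh.triangles[:, k], w)
    return num / den[:, None]


def poiseuille_discharge(P_p: float, proboscis: ProboscisGeometry,
                         fluid: FluidProperties) -> float:
    """Hagen-Poiseuille discharge through the food canal,
    ``Q = pi d_p^4 P_p / (128 eta l_p)`` (sign follows the driving pressure)."""
    if proboscis.l_p == 0:
        raise ZeroDivisionError(
            "l_p = 0 (separated galeae): Poiseuille flow is not defined")
    return math.pi * proboscis.d_p**4 * P_p / (128.0 * fluid.eta * proboscis.l_p)


def coupling_pressure(chamber: ChamberGeometry, proboscis: ProboscisGeometry,
                      fluid: FluidProperties, kin: PlungerKinematics) -> float:
    """Pressure at the opening set by volume conservation,
    ``P_p = -A (128 eta l_p / (pi d_p^4)) dh/dt`` (suction during uptake)."""
    return -chamber.area * (128.0 * fluid.eta * proboscis.l_p /
                            (math.pi * proboscis.d_p**4)) * kin.dhdt


def opening_flux(assembly: PressureAssembly, fluid: FluidProperties,
                 kin: PlungerKinematics) -> float:
    """Discharge through the opening AB (m^3/s, positive into the chamber
    during expansion), computed from the discrete solution via the
    flux-consistent boundary residual of the stiffness system -- not by raw
    gradient sampling.  By volume conservation it equals ``A dh/dt``."""
    if not assembly.converged:
        logger.warning("opening_flux evaluated on a non-converged field")
    mesh = assembly.ptilde.mesh
    phi_tilde = boundary_flux_through_opening(mesh, assembly.ptilde.values)
    if mesh.shape is Shape.RECTANGULAR:
        phi_squeeze = 0.5 * mesh.g
    else:
        phi_squeeze = mesh.theta
    l_i = assembly.yardstick
    return l_i**2 * kin.dhdt * (phi_tilde + phi_squeeze)
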