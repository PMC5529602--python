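"""Morphometric inputs and dimensionless screening parameters.

The model couples a cylindrical food canal (length ``l_p``, diameter ``d_p``)
to a shallow pump chamber whose floor is either a rectangle (length ``L``,
width ``W``) or a disk (radius ``R``).  All quantities are carried internally
in SI units (metres, Pa*s); readers convert from the conventional mixed
mm/um units at the boundary of the package.

The dimensionless numbers derived here are the ones the flow model is built
on: the opening fractions ``g = d_p/L`` and ``theta = d_p/(2R)``, the chamber
aspect ratio ``W/L``, the Womersley number that screens for quasi-steady
flow, and the crossover gap height at which proboscis and pump dissipation
balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

_logger = logging.getLogger("probopump")


class Shape(str, Enum):
    """Pump-chamber floor shape."""

    RECTANGULAR = "rectangular"
    CIRCULAR = "circular"


class InvalidOpeningError(ValueError):
    """The chamber opening is wider than the side/diameter it sits on."""


@dataclass(frozen=True)
class ProboscisGeometry:
    """Food canal of the proboscis, modelled as a cylindrical tube.

    Parameters
    ----------
    l_p : float
        Food-canal length in metres.  ``l_p = 0`` is the separated-galeae
        limit (no closed canal, no Poiseuille column).
    d_p : float
        Food-canal diameter in metres; must be positive.
    """

    l_p: float
    d_p: float

    def __post_init__(self) -> None:
        if not self.d_p > 0:
            raise ValueError(f"d_p must be > 0, got {self.d_p}")
        if self.l_p < 0:
            raise ValueError(f"l_p must be >= 0, got {self.l_p}")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity ``eta`` (Pa*s), density ``rho`` (kg/m^3)."""

    eta: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.rho > 0):
            raise ValueError("eta and rho must be strictly positive")


#: Water at room temperature, the reference fluid for the screening estimates.
WATER = FluidProperties(eta=1.0e-3, rho=1000.0)


@dataclass(frozen=True)
class PlungerKinematics:
    """State of the moving pump roof (plunger).

    ``h`` is the current gap height (m), ``dhdt`` the expansion rate (m/s,
    positive during the uptake stroke), ``h0`` the height at stroke start and
    ``beat_frequency`` the pump beat rate (1/s) used by the Womersley number.
    """

    h: float
    dhdt: float = 0.0
    h0: Optional[float] = None
    beat_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if self.h0 is not None and not self.h0 > 0:
            raise ValueError(f"h0 must be > 0, got {self.h0}")
        if self.beat_frequency < 0:
            raise ValueError("beat_frequency must be >= 0")


@dataclass(frozen=True)
class ChamberGeometry:
    """Pump-chamber floor: rectangle ``L x W`` or disk of radius ``R``.

    ``opening`` is the width |AB| of the aperture joining the chamber to the
    food canal; when the chamber is coupled to a proboscis it is identified
    with ``d_p``.  Derived dimensionless parameters:

    - ``g = opening / L`` (rectangular opening fraction, Eq. of the model),
    - ``theta = opening / (2R)`` (circular arc half-angle, radians; the
      chord/arc identification is the small-angle one),
    - ``aspect = W / L``,
    - ``area`` = ``L*W`` or ``pi*R^2``.
    """

    shape: Shape
    L: float
    opening: float
    W: Optional[float] = None
    R: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if not self.opening > 0:
            raise ValueError(f"opening must be > 0, got {self.opening}")
        if self.shape is Shape.RECTANGULAR:
            if self.W is None or not self.W > 0:
                raise ValueError("rectangular chamber requires W > 0")
            if self.opening > self.W * (1 + 1e-12):
                raise InvalidOpeningError(
                    f"opening={self.opening} exceeds chamber width W={self.W}"
                )
        else:
            if self.R is None or not self.R > 0:
                raise ValueError("circular chamber requires R > 0")
            # |AB| is identified with the arc 2*R*theta, theta in (0, pi]
            if self.opening > 2 * math.pi * self.R * (1 + 1e-12):
                raise InvalidOpeningError(
                    f"opening={self.opening} exceeds the full circumference "
                    f"2*pi*R={2 * math.pi * self.R} (theta > pi)"
                )

    # -- constructors ------------------------------------------------------
    @classmethod
    def rectangular(cls, L: float, W: float, opening: float) -> "ChamberGeometry":
        return cls(shape=Shape.RECTANGULAR, L=L, W=W, opening=opening)

    @classmethod
    def circular(cls, R: float, opening: float) -> "ChamberGeometry":
        return cls(shape=Shape.CIRCULAR, L=2 * R, R=R, opening=opening)

    @classmethod
    def from_dimensionless(
        cls,
        shape: Shape | str,
        *,
        aspect: Optional[float] = None,
        g: Optional[float] = None,
        theta: Optional[float] = None,
    ) -> "ChamberGeometry":
        """Unit-yardstick chamber from dimensionless parameters only.

        Rectangular: ``L = 1``, ``W = aspect``, ``opening = g`` (requires
        ``g <= aspect``).  Circular: ``R = 1``, ``opening = 2*theta`` so that
        the derived arc half-angle equals ``theta``.
        """
        shape = Shape(shape)
        if shape is Shape.RECTANGULAR:
            if aspect is None or g is None:
                raise ValueError("rectangular chamber needs aspect and g")
            if g > aspect:
                _logger.warning(
                    "opening fraction g=%.4g exceeds W/L=%.4g; clamped to the "
                    "full-opening limit", g, aspect)
                g = aspect
            return cls.rectangular(L=1.0, W=aspect, opening=g)
        if theta is None:
            raise ValueError("circular chamber needs theta")
        if theta > math.pi:
            _logger.warning("theta=%.4g exceeds pi; clamped to the full-opening "
                            "limit", theta)
            theta = math.pi
        return cls.circular(R=1.0, opening=2.0 * theta)

    # -- derived dimensionless quantities ----------------------------------
    @property
    def g(self) -> float:
        return self.opening / self.L

    @property
    def theta(self) -> float:
        if self.shape is Shape.CIRCULAR:
            return self.opening / (2 * self.R)
        # chord-ratio identification with R = L/2
        return self.opening / self.L

    @property
    def aspect(self) -> float:
        if self.shape is Shape.RECTANGULAR:
            return self.W / self.L
        return 1.0

    @property
    def area(self) -> float:
        if self.shape is Shape.RECTANGULAR:
            return self.L * self.W
        return math.pi * self.R**2

    @property
    def yardstick(self) -> float:
        """Pressure-scaling length ``l_i``: ``L`` (rectangular) or ``R`` (circular)."""
        return self.L if self.shape is Shape.RECTANGULAR else self.R


@dataclass(frozen=True)
class SpeciesRecord:
    """One organism's morphometrics (SI units) plus chamber-shape choice."""

    name: str
    proboscis: ProboscisGeometry
    pump_length: float
    pump_width: float
    pump_height: float
    shape: Shape = Shape.RECTANGULAR
    provenance: str = ""
    pump_radius: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        for label, v in (
            ("pump_length", self.pump_length),
            ("pump_width", self.pump_width),
            ("pump_height", self.pump_height),
        ):
            if not v > 0:
                raise ValueError(f"{label} must be > 0, got {v}")
        if self.pump_radius is not None and not self.pump_radius > 0:
            raise ValueError("pump_radius must be > 0 when given")

    @property
    def radius(self) -> float:
        """Circular-chamber radius: ``R = L/2`` unless overridden."""
        return self.pump_radius if self.pump_radius is not None else self.pump_length / 2

    def chamber(
        self, shape: Optional[Shape | str] = None, effective_canals: int = 1
    ) -> ChamberGeometry:
        """Chamber coupled to this species' food canal (opening = ``d_p``).

        ``effective_canals`` widens the opening to ``n * d_p`` for species
        with more than one galeal canal feeding the cibarium.
        """
        shape = Shape(shape) if shape is not None else self.shape
        opening = effective_canals * self.proboscis.d_p
        if shape is Shape.RECTANGULAR:
            if opening > self.pump_width * (1 + 1e-12):
                raise InvalidOpeningError(
                    f"{self.name}: food_canal_diameter (d_p={self.proboscis.d_p}) "
                    f"x {effective_canals} exceeds pump_width (W={self.pump_width})"
                )
            return ChamberGeometry.rectangular(
                L=self.pump_length, W=self.pump_width, opening=opening
            )
        R = self.radius
        if opening > 2 * R * (1 + 1e-12):
            raise InvalidOpeningError(
                f"{self.name}: food_canal_diameter (d_p={self.proboscis.d_p}) "
                f"x {effective_canals} exceeds pump diameter (2R={2 * R})"
            )
        return ChamberGeometry.circular(R=R, opening=opening)


# ---------------------------------------------------------------------------
# screening operations
# ---------------------------------------------------------------------------

def derive_dimensionless(record: SpeciesRecord, effective_canals: int = 1) -> dict:
    """Dimensionless geometry of one species.

    Returns ``g = n*d_p/L``, ``theta = n*d_p/(2R)`` (with ``R = L/2`` unless
    the record overrides it, in which case ``g`` and ``theta`` coincide),
    the aspect ratio ``W/L`` and the floor area of the record's shape.
    ``effective_canals`` (default 1) widens the opening for multi-canal
    proboscises; both conventions are legitimate readings of a two-galea
    morphology and the caller chooses.
    """
    d_eff = effective_canals * record.proboscis.d_p
    if record.shape is Shape.RECTANGULAR and d_eff > record.pump_width * (1 + 1e-12):
        raise InvalidOpeningError(
            f"{record.name}: food_canal_diameter x {effective_canals} "
            f"({d_eff}) exceeds pump_width ({record.pump_width})"
        )
    if d_eff > 2 * record.radius * (1 + 1e-12):
        raise InvalidOpeningError(
            f"{record.name}: food_canal_diameter x {effective_canals} "
            f"({d_eff}) exceeds pump diameter ({2 * record.radius})"
        )
    chamber = record.chamber(effective_canals=effective_canals)
    return {
        "g": d_eff / record.pump_length,
        "theta": d_eff / (2 * record.radius),
        "aspect": record.pump_width / record.pump_length,
        "area": chamber.area,
    }


def womersley(kin: PlungerKinematics, fluid: FluidProperties) -> float:
    """Womersley number ``Wo = h * sqrt(2*pi*f_beat*rho/eta)``.

    ``Wo < 1`` is the quasi-steady validity flag for the lubrication model.
    """
    return kin.h * math.sqrt(2 * math.pi * kin.beat_frequency * fluid.rho / fluid.eta)


def velocity_scales(Q: float, chamber: ChamberGeometry, h: float) -> dict:
    """In-plane velocity scale and flow anisotropy of the thin chamber.

    ``v_inplane = Q/(W*h)`` is the longitudinal velocity estimate at volumetric
    rate ``Q``; ``anisotropy = L/h`` estimates the ratio of in-plane to
    trans-plane velocity (mass balance of the plunger stroke).
    """
    if not h > 0:
        raise ZeroDivisionError("h must be > 0")
    W = chamber.W if chamber.shape is Shape.RECTANGULAR else 2 * chamber.R
    if not W > 0:
        raise ZeroDivisionError("chamber width must be > 0")
    return {"v_inplane": Q / (W * h), "anisotropy": chamber.L / h}


def crossover_height(proboscis: ProboscisGeometry) -> float:
    """Gap height ``h* = d_p * (d_p/l_p)^(1/3)`` at which the f-factor is ~1.

    Below ``h*`` dissipation in the proboscis dominates for any chamber
    geometry.  Undefined in the separated-galeae limit ``l_p = 0``.
    """
    if proboscis.l_p == 0:
        raise ValueError("crossover height is undefined for l_p = 0 (separated galeae)")
    return proboscis.d_p * (proboscis.d_p / proboscis.l_p) ** (1.0 / 3.0)
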