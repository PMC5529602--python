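"""Energy-dissipation regime classification of the proboscis-pump pair.

Viscous dissipation splits between the food canal (proboscis dissipation,
``E_p``) and the squeeze film under the plunger (pump dissipation, ``E_c``).
Their balance is governed by a single dimensionless factor

    f = l_p h^3 / d_p^4

compared against a geometry-dependent boundary value

    f_r(W/L, g)  = (3 pi / 32) (L/W)^2 [W/(12 L) - C_r(W/L, g)]
    f_c(theta)   = (3 / (32 pi)) [pi/8 - C_c(theta)]

Species with ``f`` above the boundary dissipate mostly in the proboscis
(proboscis-limited); below it, mostly in the pump (pump-limited).  The
relative total dissipation is ``E/E_p = 1 + f_boundary/f > 1``.

The proboscis-side power itself is ``E_p = B (dh/dt)^2 eta`` with the purely
geometric B-factor ``B = 128 l_p A^2 / (pi d_p^4)`` (units of length): the
knob evolution can turn to trade fluid viscosity against pump geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .force_impulse import ShapeConstants, compute_shape_constant
from .morphometrics import (
    ChamberGeometry,
    FluidProperties,
    PlungerKinematics,
    ProboscisGeometry,
    Shape,
    SpeciesRecord,
    WATER,
    derive_dimensionless,
    womersley,
)
from .pressure_flow import compute_K

logger = logging.getLogger("probopump")

PROBOSCIS_LIMITED = "proboscis_limited"
PUMP_LIMITED = "pump_limited"
BOUNDARY = "boundary"


def f_factor(proboscis: ProboscisGeometry, h: float) -> float:
    """Dimensionless dissipation factor ``f = l_p h^3 / d_p^4``.

    ``l_p = 0`` (separated galeae) legitimately yields ``f = 0``.
    """
    if not h >= 0:
        raise ValueError("h must be >= 0")
    return proboscis.l_p * h**3 / proboscis.d_p**4


def boundary_f(
    shape: Shape | str,
    *,
    aspect: Optional[float] = None,
    g: Optional[float] = None,
    theta: Optional[float] = None,
    C: Optional[ShapeConstants | float] = None,
    solve: bool = True,
    tol: float = 0.005,
    max_refinements: int = 30,
) -> float:
    """Boundary value of the f-factor separating the two dissipation regimes.

    If the shape constant ``C`` is not supplied it is computed by an adaptive
    solve (``solve=True``) or the call fails (``solve=False``).
    """
    shape = Shape(shape)
    if C is None:
        if not solve:
            raise ValueError("shape constant C not supplied and solve=False")
        chamber = ChamberGeometry.from_dimensionless(
            shape, aspect=aspect, g=g, theta=theta)
        C = compute_shape_constant(chamber, tol=tol, max_refinements=max_refinements)
    Cval = C.C if isinstance(C, ShapeConstants) else float(C)
    if shape is Shape.RECTANGULAR:
        if aspect is None:
            raise ValueError("rectangular boundary_f needs the aspect ratio W/L")
        return (3.0 * math.pi / 32.0) * (1.0 / aspect) ** 2 * (aspect / 12.0 - Cval)
    return (3.0 / (32.0 * math.pi)) * (math.pi / 8.0 - Cval)


def dissipation_ratio(f: float, f_boundary: float) -> dict:
    """Pump/proboscis dissipation ratio and the total relative dissipation.

    ``Ec_over_Ep = f_boundary / f`` and ``total_over_Ep = 1 + Ec_over_Ep``;
    ``f = 0`` is reported as the pump-limited extreme (infinite ratio), not
    as an error.
    """
    if f < 0 or f_boundary <= 0:
        raise ValueError("f must be >= 0 and f_boundary > 0")
    ec = math.inf if f == 0 else f_boundary / f
    return {"Ec_over_Ep": ec, "total_over_Ep": 1.0 + ec}


@dataclass
class RegimeReport:
    """Per-species classification summary."""

    species: str
    shape: Shape
    f: float
    g: float
    theta: float
    aspect: float
    C: float
    f_boundary: float
    ratio_Ec_over_Ep: float
    total_over_Ep: float
    regime: str
    B: float
    K_at_hmax: float
    womersley: Optional[float] = None
    converged: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = self.shape.value
        return d


def b_factor(proboscis: ProboscisGeometry, chamber: ChamberGeometry) -> float:
    """Geometric B-factor ``B = 128 l_p A^2 / (pi d_p^4)`` (metres), such
    that the proboscis dissipation power is ``E_p = B (dh/dt)^2 eta``."""
    return 128.0 * proboscis.l_p * chamber.area**2 / (math.pi * proboscis.d_p**4)


def proboscis_power(B: float, dhdt: float, eta: float) -> float:
    """Proboscis dissipation power ``E_p = B (dh/dt)^2 eta`` in watts."""
    return B * dhdt**2 * eta


def classify(
    record: SpeciesRecord,
    shape: Optional[Shape | str] = None,
    *,
    tie_tol: float = 0.01,
    C: Optional[ShapeConstants | float] = None,
    tol: float = 0.005,
    max_refinements: int = 30,
    beat_frequency: Optional[float] = None,
    fluid: FluidProperties = WATER,
    l_p_override: Optional[float] = None,
) -> RegimeReport:
    """Classify one species into a dissipation regime.

    Follows the three-step recipe: (a) derive the dimensionless chamber
    parameters, (b) evaluate the boundary f-value for that geometry, (c)
    compare ``f = l_p h_max^3 / d_p^4`` against it.  Ties within
    ``tie_tol`` (relative) are labelled ``"boundary"``.

    ``l_p_override`` substitutes the proboscis length (e.g. ``0.0`` for the
    separated-galeae configuration) without touching the record.
    """
    shape = Shape(shape) if shape is not None else record.shape
    prob = record.proboscis
    if l_p_override is not None:
        prob = ProboscisGeometry(l_p=l_p_override, d_p=prob.d_p)
    dims = derive_dimensionless(record)
    chamber = record.chamber(shape)
    if C is None:
        kwargs = (dict(aspect=dims["aspect"], g=dims["g"])
                  if shape is Shape.RECTANGULAR else dict(theta=dims["theta"]))
        const = compute_shape_constant(
            ChamberGeometry.from_dimensionless(shape, **kwargs),
            tol=tol, max_refinements=max_refinements)
    elif isinstance(C, ShapeConstants):
        const = C
    else:
        const = ShapeConstants(shape=shape, C=float(C))
    fb = boundary_f(shape, aspect=dims["aspect"], g=dims["g"],
                    theta=dims["theta"], C=const)
    f = f_factor(prob, record.pump_height)
    if f > fb * (1 + tie_tol):
        regime = PROBOSCIS_LIMITED
    elif f < fb * (1 - tie_tol):
        regime = PUMP_LIMITED
    else:
        regime = BOUNDARY
    ratios = dissipation_ratio(f, fb) if f > 0 else {
        "Ec_over_Ep": math.inf, "total_over_Ep": math.inf}
    wo = None
    if beat_frequency is not None:
        wo = womersley(PlungerKinematics(h=record.pump_height,
                                         beat_frequency=beat_frequency), fluid)
    return RegimeReport(
        species=record.name,
        shape=shape,
        f=f,
        g=dims["g"],
        theta=dims["theta"],
        aspect=dims["aspect"],
        C=const.C,
        f_boundary=fb,
        ratio_Ec_over_Ep=ratios["Ec_over_Ep"],
        total_over_Ep=ratios["total_over_Ep"],
        regime=regime,
        B=b_factor(prob, chamber),
        K_at_hmax=compute_K(chamber, prob, record.pump_height),
        womersley=wo,
        converged=const.converged,
    )


def classify_both_shapes(record: SpeciesRecord, **kwargs) -> dict:
    """Classification under both chamber-shape models; flags disagreement
    rather than resolving it."""
    reports = {s.value: classify(record, s, **kwargs)
               for s in (Shape.RECTANGULAR, Shape.CIRCULAR)}
    regimes = {r.regime for r in reports.values()}
    reports["agree"] = len(regimes) == 1
    if not reports["agree"]:
        logger.warning("%s: chamber-shape models disagree on the regime", record.name)
    return reports


# ---------------------------------------------------------------------------
# shape-constant sweeps and the empirical C_c(theta) fit
# ---------------------------------------------------------------------------

def cc_sweep(thetas: Sequence[float], tol: float = 0.005,
             max_refinements: int = 30) -> pd.DataFrame:
    """Circular shape constant over a theta grid (the C_c(theta) curve)."""
    rows = []
    for th in thetas:
        const = compute_shape_constant(
            ChamberGeometry.from_dimensionless(Shape.CIRCULAR, theta=float(th)),
            tol=tol, max_refinements=max_refinements)
        rows.append({
            "shape": "circular", "parameter": float(th), "aspect": math.nan,
            "C": const.C,
            "refinements": const.convergence.refinement_count,
            "rel_change": const.convergence.final_rel_change,
        })
    return pd.DataFrame(rows)


def cr_sweep(aspects: Sequence[float], gs: Sequence[float], tol: float = 0.005,
             max_refinements: int = 30) -> pd.DataFrame:
    """Rectangular shape constant over an (aspect, g) grid; openings wider
    than the chamber side (g > W/L) are skipped."""
    rows = []
    for a in aspects:
        for g in gs:
            if g > a * (1 + 1e-12):
                continue
            const = compute_shape_constant(
                ChamberGeometry.from_dimensionless(
                    Shape.RECTANGULAR, aspect=float(a), g=float(g)),
                tol=tol, max_refinements=max_refinements)
            rows.append({
                "shape": "rectangular", "parameter": float(g), "aspect": float(a),
                "C": const.C,
                "refinements": const.convergence.refinement_count,
                "rel_change": const.convergence.final_rel_change,
            })
    return pd.DataFrame(rows)


def empirical_cc_fit(
    theta_grid: Sequence[float],
    C_values: Sequence[float],
    fit_range: tuple[float, float] = (0.05, 0.8),
) -> dict:
    """Ordinary least squares of ``C_c = slope * ln(theta) + intercept``.

    The logarithmic form is only a local approximation -- its zero crossing
    near theta ~ 2.1 is unphysical (C_c stays negative up to theta = pi) --
    so all grid points must satisfy ``theta < 2`` and the fit window defaults
    to [0.05, 0.8] rad.
    """
    th = np.asarray(theta_grid, dtype=float)
    C = np.asarray(C_values, dtype=float)
    if len(th) != len(C):
        raise ValueError("theta grid and C values differ in length")
    if len(th) < 5:
        raise ValueError("need at least 5 grid points for a meaningful fit")
    if np.any(th >= 2.0):
        raise ValueError("fit is only valid for theta < 2 rad")
    lo, hi = fit_range
    mask = (th >= lo - 1e-12) & (th <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("fewer points than fit parameters inside fit_range")
    slope, intercept = np.polyfit(np.log(th[mask]), C[mask], 1)
    return {"slope": float(slope), "intercept": float(intercept)}


def fig8_boundary_curves(
    aspects: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    gs: Optional[Sequence[float]] = None,
    thetas: Optional[Sequence[float]] = None,
    tol: float = 0.005,
) -> pd.DataFrame:
    """Regime-diagram boundary curves: f_r(g) per aspect ratio and f_c(theta).

    Rows: shape, parameter (g or theta), aspect (NaN for circular),
    f_boundary.
    """
    if gs is None:
        gs = np.geomspace(0.05, 0.5, 8)
    if thetas is None:
        thetas = np.geomspace(0.05, 1.0, 8)
    rows = []
    rect = cr_sweep(aspects, gs, tol=tol)
    for _, r in rect.iterrows():
        rows.append({
            "shape": "rectangular", "parameter": r["parameter"],
            "aspect": r["aspect"],
            "f_boundary": boundary_f(Shape.RECTANGULAR, aspect=r["aspect"],
                                     g=r["parameter"], C=r["C"]),
        })
    circ = cc_sweep(thetas, tol=tol)
    for _, r in circ.iterrows():
        rows.append({
            "shape": "circular", "parameter": r["parameter"], "aspect": math.nan,
            "f_boundary": boundary_f(Shape.CIRCULAR, theta=r["parameter"], C=r["C"]),
        })
    return pd.DataFrame(rows)
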