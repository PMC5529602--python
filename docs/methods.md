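# Methods

## Model and assumptions

The pump chamber is idealised as a right cylinder over a rectangular
(`L x W`) or circular (radius `R`) footprint, closed by a rigid, flat
plunger at gap height `h(t)`; the floor and roof are rigid and the stroke
is quasi-static.  Three conditions justify the lubrication (Hele-Shaw)
reduction:

- thin gap: `h` is small against the in-plane scales, so in-plane velocity
  dominates trans-plane velocity by a factor ~`L/h` (for the packaged
  species this anisotropy at maximum expansion is a single-digit number,
  and it grows as the gap closes; it is an order-of-magnitude screening
  argument, not a per-species constant);
- quasi-steady flow: the Womersley number `Wo = h sqrt(2 pi f_beat rho/eta)`
  is below one at physiological beat rates (implemented as the formula, not
  a rounded prefactor);
- Newtonian incompressible fluid.

Under these, the depth-averaged velocity is `V = -(h^2/(12 eta)) grad p`.
The printed lubrication relation sometimes omits the viscosity; the
standard form with `1/eta` is implemented throughout, which is the only
reading under which the pointwise momentum balance, the Gauss volume
balance and the Poiseuille coupling are mutually consistent.

The food canal is a cylinder of diameter `d_p` and length `l_p` carrying
Hagen-Poiseuille flow; the canal diameter `d_p` (not any other index) is
used in the discharge and coupling formulas.  `l_p = 0` is the legal
separated-galeae limit: no liquid column, zero f-factor, pure Stefan force.

## Dimensionless formulation and sign conventions

Lengths are scaled by the yardstick `l_r = L` or `l_c = R` and pressure by
`(12 eta l_i^2 / h^3)(dh/dt)`.  The total dimensionless pressure is
`P = P_squeeze + P~ + K` with `P_squeeze = X^2/2 - 1/8` (rectangle) or
`r^2/4 - 1/4` (disk) and `K_i = -(32 h^3 l_p A_i)/(3 l_i^2 pi d_p^4)`.

The wall condition on `P~` is taken as an outward-normal flux,
`dP~/dn = -1/2`, on the `X = +-1/2` walls of the rectangle and on the wall
arc of the disk, with zero flux on the lateral rectangle walls.  This is
the only sign reading under which (i) the total pressure satisfies the
no-penetration condition `dP/dn = 0` on all walls and (ii) the full-opening
rectangle reduces to the closed form `P~ = -X/2 - 1/4`.  Both facts are
regression-tested.

Forces are reported as exerted *by the fluid on the plunger*; the muscle
must supply the negative of the reported total.  The Stefan bracket is
implemented as `[C_r - W/(12L)]` multiplying `L^4` (for the rectangle):
direct integration of the assembled pressure over the plunger produces
exactly this combination, and the in-suite quadrature test (closed form vs
numerical integration of the pressure field) holds to ~1e-6.  Similarly the
normalised impulse is `Pi d_p^2 / (6 eta l_i^4)`: with the second power of
`d_p`, and only with it, the closed form equals `-int F dt` along any
monotone `h(t)` path (verified to 0.1% by trapezoid quadrature on three
different paths).  The B-factor is purely geometric,
`B = 128 l_p A^2/(pi d_p^4)` in metres, so that the proboscis power is
`E_p = B (dh/dt)^2 eta`; including viscosity inside `B` would not reproduce
the published magnitudes for either packaged sphinx moth.

## Numerical solution of the chamber problem

`P~` solves a mixed Dirichlet-Neumann Laplace problem.  At the opening
endpoints A and B the boundary condition changes type, so the gradient
behaves like `dist^(-1/2)`; the field itself is bounded and the integral
shape constants converge under refinement, which is why the singularity is
handled by mesh refinement only (no singular enrichment, no higher-order
elements).

- Discretisation: piecewise-linear (P1) triangles, exact assembly, direct
  sparse solve.  The disk is polygonised to at least 256 boundary segments
  at base level; refined boundary midpoints are projected back onto the
  unit circle.
- Base meshes: structured tensor (rectangle) / polar (disk) grids whose
  lines include the opening endpoints exactly, with dyadic grading toward
  A and B.  `refinement_level` raises the base resolution and grading
  depth; level `k+1` always has more nodes than level `k`.
- Adaptive loop: each pass marks elements by a Doerfler criterion (60% of
  the total indicator mass) and bisects them by longest edge (Rivara),
  which keeps the mesh conforming and the element shapes uniformly bounded.
  The indicator is the element gradient magnitude scaled by the local mesh
  size, `|grad P~| h_T`: an unscaled gradient indicator never
  equidistributes at the corner singularity (the same corner elements are
  re-marked forever), while the size-scaled form balances corner and
  smooth-region contributions to the integral constants.
- Convergence control: the loop stops when the shape constant (the
  integral of `P~` by vertex-average quadrature) changes by less than
  `tol = 0.5%` between passes, with a cap of 30 passes; hitting the cap is
  flagged in the returned record, never silent.  On the parameter grids
  used in the tests, convergence takes 2-5 passes.
- Degenerate inputs: `theta = pi` (all-Dirichlet disk) returns the exact
  zero field; a full-side rectangular opening reproduces the linear closed
  form to machine precision; requests with `g > W/L` or `theta > pi` are
  clamped to the full-opening limit with a logged warning; an empty
  Dirichlet set raises a singular-system error.

Discharge through the opening is evaluated from the discrete residual of
the stiffness system at the Dirichlet nodes (the flux-consistent boundary
flux), not by sampling gradients of the singular field; with it the volume
balance `Q_AB = A dh/dt` holds to round-off by construction, and the Gauss
consistency of the imposed wall flux is exact in the same sense.

## Independent cross-check oracle

A second-order finite-difference solver for the same boundary-value
problem runs on structured grids: Cartesian with ghost-point Neumann
elimination for the rectangle (the grid is aligned so the opening endpoints
are grid nodes -- a misaligned Dirichlet segment would shift the effective
opening by half a cell, which matters because the constants depend
logarithmically on the opening size), and a staggered polar grid for the
disk (half-integer radii avoid the coordinate singularity at the centre).
Grids too coarse to put two intervals across the opening are refused.  The
finite-element and finite-difference fields agree to better than 1%
relative L2 across the whole illustrative parameter grid
(`W/L in {0.4, 1, 1.24} x g in {0.05, 0.1, 0.3}`, `theta in {0.05, 0.3,
1.0}`); both reduce to the same closed forms in the degenerate cases.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `tol` | 0.005 | relative change of the shape constant between refinement passes |
| `max_refinements` | 30 | adaptive-pass cap (flagged, not silent, when hit) |
| `dorfler_fraction` | 0.6 | marked fraction of the total error-indicator mass |
| `fit_range` | (0.05, 0.8) rad | window of the logarithmic `C_c(theta)` fit |
| `tie_tol` | 0.01 | relative half-width of the "boundary" classification band |
| `R` | `L/2` | circular-chamber radius when a record does not supply one |

Internal units are SI throughout (m, Pa s); the CSV reader converts from
the conventional mixed units (mm for proboscis length, um for the rest).
The `R = L/2` default makes `g` and `theta` numerically equal for a given
record, consistent with publishing a single opening-fraction column.  The
logarithmic `C_c` fit window default reflects where the log law is a good
local description; the fitted line crosses zero near `theta ~ 2.1` while
the true constant stays negative up to `theta = pi`, so fits are refused
outside `theta < 2`.  For a two-canal proboscis the opening fraction can be
computed per canal (default) or with the doubled effective opening
(`effective_canals=2`); both conventions are exposed because published
tables are ambiguous on this point.  Species whose recorded proboscis
length is a range are carried at the lower endpoint; range outputs are
obtained by evaluating the endpoints explicitly.

## Synthetic data

`generate_fixtures` writes, besides the packaged species table, a synthetic
morphometric sweep: 25 pseudo-species whose f-factors fall on a log grid
from 1e-2 to 1e7 (deterministic jitter from the single recorded seed), with
chamber lengths of 0.3-2.5 mm, aspect ratios 0.5-1.5 and gap heights of
10-60% of chamber length -- the envelope of the measured insects.  Because
the boundary f-values of admissible geometries lie roughly between 3/256
and ~10, the sweep straddles every regime boundary in both directions.  The
generator emulates scale ranges only: it does not model allometric
correlations between proboscis length and pump size, measurement error, or
phylogenetic structure, so a green classification test establishes that the
decision rule is implemented correctly, not that real taxa are sampled
realistically.  The solver path itself contains no randomness.

## Known limitations

- No time integration of plunger dynamics or muscle mechanics: `h(t)` is an
  input, and impulse results are endpoint relations (plus quadrature along
  user-supplied paths).
- The esophagus-side (injection) stroke is the mirror case with a sign
  change and is not modelled separately.
- The disk boundary is polygonal (>= 256 segments at base level, refined
  adaptively); curved isoparametric elements are out of scope.
- Printed morphometric inputs are rounded to 3-4 digits, so quantities
  recomputed from them (f-factors, B-factors) carry ~1-2% input-rounding
  uncertainty; tolerances in the tests reflect that, not solver error.
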