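"""Mesh the chamber footprint and solve the mixed Laplace problem for P~.

The non-uniform part of the dimensionless chamber pressure, ``P~``, is the
harmonic correction that restores the no-penetration wall condition after the
volumetric "squeeze" pressure is split off.  It satisfies, on the unit-scale
footprint,

    lap P~ = 0            in the chamber,
    P~     = 0            on the opening AB (Dirichlet),
    dP~/dn = -1/2         on the flux walls (X = +-1/2 sides of the
                          rectangle; the full wall arc of the disk),
    dP~/dn = 0            on the lateral rectangle walls (Y = +-W/2L).

``n`` is the outward unit normal.  The mixed boundary-condition transition at
the opening endpoints A and B produces an r^(1/2) corner behaviour (gradient
~ r^(-1/2)); it is handled by adaptive longest-edge (Rivara) bisection driven
by a size-scaled gradient indicator, never by singular enrichment -- the
integral shape constants are bounded and converge under refinement.

A second-order finite-difference solution of the same boundary-value problem
(Cartesian for the rectangle, polar for the disk) is provided as an
independent cross-check oracle.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphometrics import ChamberGeometry, Shape

logger = logging.getLogger("probopump")

OPENING = "opening"
WALL = "wall"
#: imposed outward-normal derivative of P~ on the flux walls
WALL_FLUX = -0.5


class SingularSystemError(RuntimeError):
    """The Dirichlet part of the boundary is empty; the system is singular."""


class OracleResolutionError(ValueError):
    """The structured oracle grid cannot resolve the opening."""


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Conforming triangulation of the dimensionless chamber footprint.

    ``boundary_tags`` partitions the boundary edges into ``"opening"``
    (Dirichlet) and ``"wall"``; ``wall_flux`` carries the imposed
    outward-normal derivative per boundary edge (0 on the opening and on
    zero-flux walls, -1/2 on flux walls).
    """

    nodes: np.ndarray            # (N, 2)
    triangles: np.ndarray        # (M, 3), positively oriented
    boundary_edges: np.ndarray   # (E, 2)
    boundary_tags: np.ndarray    # (E,) str in {opening, wall}
    wall_flux: np.ndarray        # (E,)
    shape: Shape = Shape.RECTANGULAR
    aspect: Optional[float] = None
    g: Optional[float] = None
    theta: Optional[float] = None
    curved: bool = False         # project refined boundary nodes to unit circle

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.boundary_edges = np.asarray(self.boundary_edges, dtype=np.int64)
        self.boundary_tags = np.asarray(self.boundary_tags)
        self.wall_flux = np.asarray(self.wall_flux, dtype=float)
        # enforce positive orientation
        a = _signed_areas(self.nodes, self.triangles)
        flip = a < 0
        if np.any(flip):
            t = self.triangles.copy()
            t[flip] = t[flip][:, ::-1]
            self.triangles = t

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        return _signed_areas(self.nodes, self.triangles)

    def opening_nodes(self) -> np.ndarray:
        mask = self.boundary_tags == OPENING
        return np.unique(self.boundary_edges[mask])

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.nodes[edges[:, 0]] - self.nodes[edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])


def _signed_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


# ---------------------------------------------------------------------------
# base mesh construction
# ---------------------------------------------------------------------------

def _graded_axis(lo: float, hi: float, n: int, anchors: Sequence[float], depth: int) -> np.ndarray:
    """Uniform grid on [lo, hi] with dyadically graded points toward anchors."""
    h0 = (hi - lo) / n
    base = [lo + k * h0 for k in range(n + 1)]
    pts = [v for v in base if all(abs(v - a) > 0.4 * h0 or v in (lo, hi) for a in anchors)]
    for a in anchors:
        if lo - 1e-12 <= a <= hi + 1e-12:
            pts.append(min(max(a, lo), hi))
        for k in range(1, depth + 1):
            d = h0 / 2**k
            for s in (a - d, a + d):
                if lo + 1e-12 < s < hi - 1e-12:
                    pts.append(s)
    arr = np.unique(np.round(np.array(sorted(pts)), 13))
    return arr


def _boundary_edges_of(tris: np.ndarray) -> np.ndarray:
    """Edges that belong to exactly one triangle."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return key[idx[counts == 1]]


def _tensor_triangulation(xs: np.ndarray, ys: np.ndarray):
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    nid = np.arange(nx * ny).reshape(nx, ny)
    a = nid[:-1, :-1].ravel()
    b = nid[1:, :-1].ravel()
    c = nid[1:, 1:].ravel()
    d = nid[:-1, 1:].ravel()
    tris = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return nodes, tris


def _tag_rect(nodes: np.ndarray, tris: np.ndarray, aspect: float, g: float):
    edges = _boundary_edges_of(tris)
    mid = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    tol = 1e-9
    on_left = np.abs(mid[:, 0] + 0.5) < tol
    on_right = np.abs(mid[:, 0] - 0.5) < tol
    in_open = on_left & (np.abs(mid[:, 1]) < g / 2 - tol)
    tags = np.where(in_open, OPENING, WALL)
    flux = np.where(on_left | on_right, WALL_FLUX, 0.0)
    flux[in_open] = 0.0
    return edges, tags, flux


def _build_rect_mesh(aspect: float, g: float, level: int) -> TriMesh:
    nx = 40 + 8 * level
    ny = max(8, int(round(nx * aspect)))
    depth = min(8, 4 + level)
    xs = _graded_axis(-0.5, 0.5, nx, [-0.5], depth)
    y_anchors = [] if g >= aspect * (1 - 1e-12) else [-g / 2, g / 2]
    ys = _graded_axis(-aspect / 2, aspect / 2, ny, y_anchors, depth)
    # the opening endpoints must be mesh lines
    if y_anchors:
        assert np.min(np.abs(ys - g / 2)) < 1e-12
    nodes, tris = _tensor_triangulation(xs, ys)
    edges, tags, flux = _tag_rect(nodes, tris, aspect, g)
    return TriMesh(nodes, tris, edges, tags, flux,
                   shape=Shape.RECTANGULAR, aspect=aspect, g=g)


def _tag_circle(nodes: np.ndarray, tris: np.ndarray, theta: float):
    edges = _boundary_edges_of(tris)
    r0 = np.hypot(nodes[edges[:, 0], 0], nodes[edges[:, 0], 1])
    mid = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    ang = np.arctan2(mid[:, 1], mid[:, 0])
    if theta >= math.pi - 1e-12:
        in_open = np.ones(len(edges), dtype=bool)
    else:
        in_open = np.abs(ang) < theta - 1e-12
    tags = np.where(in_open, OPENING, WALL)
    flux = np.where(in_open, 0.0, WALL_FLUX)
    return edges, tags, flux


def _build_circle_mesh(theta: float, level: int) -> TriMesh:
    n_b = 256 + 32 * level
    dphi = 2 * math.pi / n_b
    base = [-math.pi + k * dphi for k in range(n_b)]
    depth = min(8, 3 + level)
    phis = []
    anchors = [] if theta >= math.pi - 1e-12 else [-theta, theta]
    for v in base:
        if all(abs(v - a) > 0.4 * dphi for a in anchors):
            phis.append(v)
    for a in anchors:
        phis.append(a)
        for k in range(1, depth + 1):
            d = dphi / 2**k
            for s in (a - d, a + d):
                if -math.pi < s < math.pi:
                    phis.append(s)
    phis = np.unique(np.round(np.array(sorted(phis)), 13))
    n_phi = len(phis)
    n_r = max(12, n_b // 12)
    radii = np.linspace(0.0, 1.0, n_r + 1)[1:]

    nodes = [(0.0, 0.0)]
    for r in radii:
        for p in phis:
            nodes.append((r * math.cos(p), r * math.sin(p)))
    nodes = np.array(nodes)

    def nid(k: int, i: int) -> int:
        return 1 + k * n_phi + (i % n_phi)

    tris = []
    for i in range(n_phi):
        tris.append([0, nid(0, i), nid(0, i + 1)])
    for k in range(n_r - 1):
        for i in range(n_phi):
            a, b = nid(k, i), nid(k, i + 1)
            c, d = nid(k + 1, i), nid(k + 1, i + 1)
            tris.append([a, d, c])
            tris.append([a, b, d])
    tris = np.array(tris)
    edges, tags, flux = _tag_circle(nodes, tris, theta)
    return TriMesh(nodes, tris, edges, tags, flux,
                   shape=Shape.CIRCULAR, theta=theta, curved=True)


def build_mesh(chamber: ChamberGeometry, refinement_level: int = 0) -> TriMesh:
    """Triangulate the dimensionless footprint of ``chamber``.

    ``refinement_level`` controls the base resolution and the dyadic grading
    toward the opening endpoints A and B (level ``k + 1`` has strictly more
    nodes than level ``k``); adaptive refinement on top of the base mesh is
    the job of :func:`refine_until_converged`.
    """
    if refinement_level < 0:
        raise ValueError("refinement_level must be >= 0")
    if chamber.shape is Shape.RECTANGULAR:
        aspect, g = chamber.aspect, chamber.g
        if not aspect > 0:
            raise ValueError(f"degenerate aspect ratio W/L = {aspect}")
        if g > aspect * (1 + 1e-12):
            logger.warning("opening fraction g=%.4g exceeds W/L=%.4g; clamped "
                           "to the full-opening limit", g, aspect)
            g = aspect
        return _build_rect_mesh(aspect, g, refinement_level)
    theta = chamber.theta
    if theta > math.pi * (1 + 1e-12):
        logger.warning("theta=%.4g exceeds pi; clamped to the full-opening limit", theta)
        theta = math.pi
    return _build_circle_mesh(theta, refinement_level)


# ---------------------------------------------------------------------------
# P1 finite elements
# ---------------------------------------------------------------------------

def _tri_coeffs(mesh: TriMesh):
    p = mesh.nodes[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    return b, c, area


def stiffness_matrix(mesh: TriMesh) -> sp.csr_matrix:
    b, c, area = _tri_coeffs(mesh)
    Ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (4 * area)[:, None, None]
    t = mesh.triangles
    rows = t[:, [0, 0, 0, 1, 1, 1, 2, 2, 2]].ravel()
    cols = t[:, [0, 1, 2, 0, 1, 2, 0, 1, 2]].ravel()
    K = sp.coo_matrix((Ke.reshape(-1, 9).ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def neumann_load(mesh: TriMesh) -> np.ndarray:
    """Load vector of the imposed wall fluxes: sum over wall edges of q * phi."""
    f = np.zeros(mesh.n_nodes)
    wall = (mesh.boundary_tags == WALL) & (mesh.wall_flux != 0.0)
    edges = mesh.boundary_edges[wall]
    q = mesh.wall_flux[wall]
    le = mesh.edge_lengths(edges)
    contrib = 0.5 * q * le
    np.add.at(f, edges[:, 0], contrib)
    np.add.at(f, edges[:, 1], contrib)
    return f


@dataclass
class ScalarField:
    """Nodal scalar values on a :class:`TriMesh` (piecewise-linear field)."""

    mesh: TriMesh
    values: np.ndarray
    name: str = "P_tilde"
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_nodes:
            raise ValueError("values length does not match mesh node count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        self._interp = None
        self._tree = None

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary points; nearest-node fallback
        for points marginally outside the (polygonal) domain."""
        from matplotlib.tri import LinearTriInterpolator, Triangulation

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._interp is None:
            tri = Triangulation(self.mesh.nodes[:, 0], self.mesh.nodes[:, 1],
                                self.mesh.triangles)
            self._interp = LinearTriInterpolator(tri, self.values)
        out = np.asarray(self._interp(pts[:, 0], pts[:, 1]))
        out = np.ma.filled(out, np.nan)
        bad = ~np.isfinite(out)
        if np.any(bad):
            from scipy.spatial import cKDTree

            if self._tree is None:
                self._tree = cKDTree(self.mesh.nodes)
            _, idx = self._tree.query(pts[bad])
            out[bad] = self.values[idx]
        return out


def solve_mixed_laplace(mesh: TriMesh) -> ScalarField:
    """Solve the mixed Dirichlet-Neumann Laplace problem for P~ on ``mesh``.

    Dirichlet nodes (on the opening) carry exactly 0; the wall flux enters
    through the boundary load.  Raises :class:`SingularSystemError` when the
    opening (Dirichlet) part of the boundary is empty.
    """
    dir_nodes = mesh.opening_nodes()
    if len(dir_nodes) == 0:
        raise SingularSystemError("no opening edges: pure-Neumann problem is singular")
    K = stiffness_matrix(mesh)
    f = neumann_load(mesh)
    free = np.ones(mesh.n_nodes, dtype=bool)
    free[dir_nodes] = False
    u = np.zeros(mesh.n_nodes)
    if np.any(free):
        Kff = K[free][:, free].tocsc()
        u_free = spla.spsolve(Kff, f[free])
        if not np.all(np.isfinite(u_free)):
            raise SingularSystemError("direct solve produced non-finite values")
        u[free] = u_free
        res = np.linalg.norm(Kff @ u_free - f[free])
        scale = max(np.linalg.norm(f[free]), 1e-30)
        if res > 1e-8 * scale:
            raise SingularSystemError(f"solver residual {res:.3e} exceeds tolerance")
    return ScalarField(mesh, u)


def gradient(mesh: TriMesh, values: np.ndarray) -> np.ndarray:
    """Piecewise-constant gradient of a nodal field, one (gx, gy) per triangle."""
    b, c, area = _tri_coeffs(mesh)
    v = values[mesh.triangles]
    gx = np.sum(v * b, axis=1) / (2 * area)
    gy = np.sum(v * c, axis=1) / (2 * area)
    return np.column_stack([gx, gy])


def integrate_field(field: ScalarField) -> float:
    """Integral of the field over the footprint by vertex-average quadrature:
    sum over triangles of area times the mean of the three vertex values."""
    v = field.values[field.mesh.triangles]
    return float(np.sum(field.mesh.areas * v.mean(axis=1)))


def boundary_flux_through_opening(mesh: TriMesh, values: np.ndarray) -> float:
    """Outward flux of the field through the opening, evaluated from the
    discrete residual (flux-consistent, not raw gradient sampling)."""
    K = stiffness_matrix(mesh)
    f = neumann_load(mesh)
    r = K @ values - f
    return float(np.sum(r[mesh.opening_nodes()]))


# ---------------------------------------------------------------------------
# adaptive refinement (Rivara longest-edge bisection)
# ---------------------------------------------------------------------------

def refine_mesh(mesh: TriMesh, marked: Iterable[int]) -> TriMesh:
    """Bisect the marked triangles by their longest edges, propagating to
    neighbours (Rivara) so the mesh stays conforming; boundary tags are
    inherited and, on the disk, new boundary nodes are projected onto the
    unit circle."""
    nodes = [tuple(p) for p in mesh.nodes]
    tris = [list(t) for t in mesh.triangles]
    alive = [True] * len(tris)
    edge_map: dict = defaultdict(set)
    for tid, (a, b, c) in enumerate(tris):
        for e in (frozenset((a, b)), frozenset((b, c)), frozenset((c, a))):
            edge_map[e].add(tid)
    btag = {
        frozenset((int(e[0]), int(e[1]))): (tag, fl)
        for e, tag, fl in zip(mesh.boundary_edges, mesh.boundary_tags, mesh.wall_flux)
    }

    def elen2(e) -> float:
        i, j = tuple(e)
        dx = nodes[i][0] - nodes[j][0]
        dy = nodes[i][1] - nodes[j][1]
        return dx * dx + dy * dy

    def longest_edge(tid: int):
        a, b, c = tris[tid]
        cands = [frozenset((a, b)), frozenset((b, c)), frozenset((c, a))]
        return max(cands, key=lambda e: (elen2(e), min(e), max(e)))

    def split_edge(e) -> None:
        i, j = sorted(e)
        xm = 0.5 * (nodes[i][0] + nodes[j][0])
        ym = 0.5 * (nodes[i][1] + nodes[j][1])
        info = btag.pop(e, None)
        if info is not None and mesh.curved:
            rr = math.hypot(xm, ym)
            ri = math.hypot(*nodes[i])
            rj = math.hypot(*nodes[j])
            if rr > 0 and abs(ri - 1) < 1e-9 and abs(rj - 1) < 1e-9:
                xm, ym = xm / rr, ym / rr
        m = len(nodes)
        nodes.append((xm, ym))
        if info is not None:
            btag[frozenset((i, m))] = info
            btag[frozenset((m, j))] = info
        for tid in list(edge_map[e]):
            vs = tris[tid]
            for k in range(3):
                if {vs[k], vs[(k + 1) % 3]} == {i, j}:
                    p, q, r = vs[k], vs[(k + 1) % 3], vs[(k + 2) % 3]
                    break
            alive[tid] = False
            for ee in (frozenset((vs[0], vs[1])), frozenset((vs[1], vs[2])),
                       frozenset((vs[2], vs[0]))):
                edge_map[ee].discard(tid)
            for child in ([p, m, r], [m, q, r]):
                cid = len(tris)
                tris.append(child)
                alive.append(True)
                for ee in (frozenset((child[0], child[1])),
                           frozenset((child[1], child[2])),
                           frozenset((child[2], child[0]))):
                    edge_map[ee].add(cid)
        edge_map.pop(e, None)

    stack = [int(t) for t in marked]
    guard = 200 * (len(stack) + 1) + 2_000_000
    steps = 0
    while stack:
        steps += 1
        if steps > guard:
            raise RuntimeError("Rivara refinement failed to terminate")
        t = stack[-1]
        if not alive[t]:
            stack.pop()
            continue
        e = longest_edge(t)
        nbs = edge_map[e] - {t}
        nb = next(iter(nbs)) if nbs else None
        if nb is not None and longest_edge(nb) != e:
            stack.append(nb)
            continue
        split_edge(e)
        stack.pop()

    keep = [i for i, a in enumerate(alive) if a]
    new_tris = np.array([tris[i] for i in keep], dtype=np.int64)
    new_nodes = np.array(nodes)
    edges, tags, flux = [], [], []
    for e, (tag, fl) in btag.items():
        i, j = sorted(e)
        edges.append((i, j))
        tags.append(tag)
        flux.append(fl)
    return TriMesh(new_nodes, new_tris, np.array(edges), np.array(tags),
                   np.array(flux), shape=mesh.shape, aspect=mesh.aspect,
                   g=mesh.g, theta=mesh.theta, curved=mesh.curved)


@dataclass
class ConvergenceRecord:
    """Audit trail of the adaptive refinement loop for one geometry."""

    refinement_count: int
    constant_history: list
    final_rel_change: float
    converged: bool
    tol: float


def _error_indicator(mesh: TriMesh, field: ScalarField) -> np.ndarray:
    # gradient magnitude scaled by the local mesh size (longest edge):
    # equidistributes the local field variation, concentrating marks at the
    # corner singularities without starving the smooth interior
    g = gradient(mesh, field.values)
    gm = np.hypot(g[:, 0], g[:, 1])
    p = mesh.nodes[mesh.triangles]
    e0 = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    e1 = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    e2 = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    h = np.maximum(np.maximum(e0, e1), e2)
    return gm * h


def _dorfler_mark(indicator: np.ndarray, fraction: float) -> np.ndarray:
    order = np.argsort(indicator)[::-1]
    csum = np.cumsum(indicator[order])
    total = csum[-1]
    if total <= 0:
        return np.array([], dtype=np.int64)
    k = int(np.searchsorted(csum, fraction * total)) + 1
    return order[:k]


def refine_until_converged(
    chamber: ChamberGeometry,
    tol: float = 0.005,
    max_refinements: int = 30,
    base_level: int = 0,
    dorfler_fraction: float = 0.6,
) -> tuple[TriMesh, ScalarField, ConvergenceRecord]:
    """Adaptively refine until the shape constant (integral of P~) changes by
    less than ``tol`` (relative) between passes.

    Returns the final mesh, the solved field and a :class:`ConvergenceRecord`;
    hitting ``max_refinements`` without meeting the tolerance is flagged in
    the record (``converged = False``), never silent.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if max_refinements < 1:
        raise ValueError("max_refinements must be >= 1")
    mesh = build_mesh(chamber, base_level)
    history: list = []
    rel_change = math.inf
    field = None
    converged = False
    for passno in range(1, max_refinements + 1):
        field = solve_mixed_laplace(mesh)
        C = integrate_field(field)
        history.append(C)
        if len(history) >= 2:
            rel_change = abs(history[-1] - history[-2]) / max(abs(history[-1]), 1e-12)
        logger.info("refinement pass %d: %d nodes, C=%.6g, rel_change=%.3g",
                    passno, mesh.n_nodes, C, rel_change)
        if rel_change <= tol:
            converged = True
            break
        if passno == max_refinements:
            break
        marked = _dorfler_mark(_error_indicator(mesh, field), dorfler_fraction)
        if len(marked) == 0:
            converged = True
            rel_change = 0.0
            break
        mesh = refine_mesh(mesh, marked)
    if not converged:
        logger.warning("refinement loop hit max_refinements=%d with rel_change=%.3g > tol=%.3g",
                       max_refinements, rel_change, tol)
    record = ConvergenceRecord(
        refinement_count=len(history),
        constant_history=history,
        final_rel_change=float(rel_change) if math.isfinite(rel_change) else math.inf,
        converged=converged,
        tol=tol,
    )
    return mesh, field, record


# ---------------------------------------------------------------------------
# finite-difference oracle
# ---------------------------------------------------------------------------

def _aligned_segments(span: float, target: float, first: float):
    """Number/width of uniform intervals covering ``span`` at ~``target``
    spacing; ``first`` <= 0 means no constraint from an inner region."""
    n = max(1, int(round(span / target)))
    return n, span / n


def _nonuniform_d2(coords: np.ndarray, left_bc, right_bc):
    """1-D second-difference operator on an arbitrary node set.

    ``left_bc``/``right_bc``: ("neumann", gradient value) with the gradient
    taken along +coordinate, or ("none",) when the boundary row is handled by
    the caller.  Returns (sparse matrix, rhs contribution).
    """
    n = len(coords)
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)
    h = np.diff(coords)
    for i in range(1, n - 1):
        hm, hp = h[i - 1], h[i]
        A[i, i - 1] += 2 / (hm * (hm + hp))
        A[i, i] += -2 / (hm * hp)
        A[i, i + 1] += 2 / (hp * (hm + hp))
    # ghost-node elimination at the ends (centered, second order)
    if left_bc[0] == "neumann":
        gval = left_bc[1]
        h0 = h[0]
        # ghost at coords[0]-h0: (P_1 - P_ghost)/(2 h0) = gval
        A[0, 0] += -2 / h0**2
        A[0, 1] += 2 / h0**2
        rhs[0] += 2 * gval / h0
    if right_bc[0] == "neumann":
        gval = right_bc[1]
        hn = h[-1]
        # ghost at coords[-1]+hn: (P_ghost - P_{n-2})/(2 hn) = gval
        A[n - 1, n - 1] += -2 / hn**2
        A[n - 1, n - 2] += 2 / hn**2
        rhs[n - 1] += -2 * gval / hn
    return A.tocsr(), rhs


def _fd_rectangular(aspect: float, g: float, grid_n: int) -> ScalarField:
    a = aspect
    if g < 2 * a / grid_n - 1e-12 and g < a * (1 - 1e-12):
        raise OracleResolutionError(
            f"grid_n={grid_n} gives fewer than 2 intervals across the opening g={g}")
    xs = np.linspace(-0.5, 0.5, grid_n + 1)
    if g >= a * (1 - 1e-12):
        ys = np.linspace(-a / 2, a / 2, max(4, int(round(grid_n * a))) + 1)
        g = a
    else:
        dy_nom = a / grid_n
        m, d1 = _aligned_segments(g / 2, dy_nom, 0)
        m = max(m, 1)
        d1 = (g / 2) / m
        k, d2 = _aligned_segments((a - g) / 2, dy_nom, 0)
        ypos = np.concatenate([
            np.arange(m + 1) * d1,
            g / 2 + np.arange(1, k + 1) * d2,
        ])
        ypos[-1] = a / 2
        ys = np.unique(np.concatenate([-ypos, ypos]))

    nx, ny = len(xs), len(ys)
    # outward-normal flux -1/2 on x = +-1/2 => dP/dx = +1/2 at x=-1/2,
    # dP/dx = -1/2 at x=+1/2; zero-flux (mirror) on y = +-a/2
    Lx, bx = _nonuniform_d2(xs, ("neumann", +0.5), ("neumann", -0.5))
    Ly, by = _nonuniform_d2(ys, ("neumann", 0.0), ("neumann", 0.0))
    Ix, Iy = sp.identity(nx), sp.identity(ny)
    A = sp.kron(Iy, Lx) + sp.kron(Ly, Ix)   # flat index = j*nx + i
    rhs = (np.tile(bx, ny) + np.repeat(by, nx))

    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    dir_mask = (ii.ravel() == 0) & (np.abs(ys[jj.ravel()]) <= g / 2 + 1e-12)
    free = ~dir_mask
    D_free = sp.diags(free.astype(float))
    A = (D_free @ A.tocsr() + sp.diags(dir_mask.astype(float))).tocsc()
    rhs = rhs * free
    u = spla.spsolve(A, rhs)

    nodes, tris = _tensor_triangulation(xs, ys)
    # tensor node order is i*ny + j; FD solution is j*nx + i
    u_grid = u.reshape(ny, nx).T.ravel()
    edges, tags, flux = _tag_rect(nodes, tris, a, g)
    mesh = TriMesh(nodes, tris, edges, tags, flux,
                   shape=Shape.RECTANGULAR, aspect=a, g=g)
    return ScalarField(mesh, u_grid)


def _fd_circular(theta: float, grid_n: int) -> ScalarField:
    full = theta >= math.pi - 1e-12
    dphi_nom = math.pi / grid_n
    if not full and 2 * theta < 2 * dphi_nom - 1e-12:
        raise OracleResolutionError(
            f"grid_n={grid_n} gives fewer than 2 intervals across the arc 2*theta={2*theta}")
    dr = 1.0 / grid_n
    r = (np.arange(grid_n) + 0.5) * dr
    nr = grid_n
    if full:
        phis = np.linspace(0.0, math.pi, grid_n + 1)
    else:
        m = max(1, int(round(theta / dphi_nom)))
        d1 = theta / m
        k = max(1, int(round((math.pi - theta) / dphi_nom)))
        d2 = (math.pi - theta) / k
        phis = np.concatenate([np.arange(m + 1) * d1,
                               theta + np.arange(1, k + 1) * d2])
        phis[-1] = math.pi
    nphi = len(phis)

    # radial operator (staggered cells; r_{-1/2}=0 kills the centre term)
    rp = r + dr / 2
    rm = r - dr / 2
    ap = rp / (r * dr * dr)
    am = rm / (r * dr * dr)
    R2 = sp.lil_matrix((nr, nr))
    for j in range(nr - 1):
        R2[j, j] += -(am[j] + ap[j])
        R2[j, j + 1] += ap[j]
        if j > 0:
            R2[j, j - 1] += am[j]
    # last radial row: default Neumann wall handling (constant to rhs);
    # Dirichlet columns corrected below
    j = nr - 1
    R2[j, j - 1] += am[j]
    R2[j, j] += -am[j]
    R2 = R2.tocsr()

    Lphi, bphi = _nonuniform_d2(phis, ("neumann", 0.0), ("neumann", 0.0))
    D_invr2 = sp.diags(1.0 / r**2)
    A = sp.kron(sp.identity(nphi), R2) + sp.kron(Lphi, D_invr2)
    A = A.tolil()
    rhs = np.zeros(nphi * nr)
    open_phi = phis <= theta + 1e-12
    for i in range(nphi):
        row = i * nr + nr - 1
        if open_phi[i]:
            # Dirichlet P(r=1)=0 via ghost: P_gh = -P_last
            A[row, row] += -2 * ap[-1]
        else:
            # Neumann dP/dr = -1/2 via ghost: P_gh = P_last - dr/2
            rhs[row] += ap[-1] * dr / 2
    u = spla.spsolve(A.tocsc(), rhs)
    U = u.reshape(nphi, nr)   # [phi, r]

    # augment with the r=1 ring (boundary values from the BCs) and the centre
    bvals = np.where(open_phi, 0.0, U[:, -1] - dr / 4)
    r_aug = np.concatenate([[0.0], r, [1.0]])
    center_val = float(np.mean(U[:, 0]))
    phi_full = np.concatenate([-phis[::-1], phis[1:]])
    U_full = np.vstack([U[::-1], U[1:]])           # [phi_full, r]
    b_full = np.concatenate([bvals[::-1], bvals[1:]])

    nphi_f = len(phi_full)
    nodes = [(0.0, 0.0)]
    vals = [center_val]
    for j, rr in enumerate(np.concatenate([r, [1.0]])):
        for i in range(nphi_f):
            nodes.append((rr * math.cos(phi_full[i]), rr * math.sin(phi_full[i])))
            vals.append(U_full[i, j] if j < nr else b_full[i])
    nodes = np.array(nodes)
    vals = np.array(vals)

    def nid(k: int, i: int) -> int:
        return 1 + k * nphi_f + i

    tris = []
    for i in range(nphi_f - 1):
        tris.append([0, nid(0, i), nid(0, i + 1)])
    for k in range(nr):
        for i in range(nphi_f - 1):
            a_, b_ = nid(k, i), nid(k, i + 1)
            c_, d_ = nid(k + 1, i), nid(k + 1, i + 1)
            tris.append([a_, d_, c_])
            tris.append([a_, b_, d_])
    tris = np.array(tris)
    edges, tags, flux = _tag_circle(nodes, tris, theta)
    mesh = TriMesh(nodes, tris, edges, tags, flux,
                   shape=Shape.CIRCULAR, theta=theta, curved=True)
    return ScalarField(mesh, vals)


def fd_oracle(chamber: ChamberGeometry, grid_n: int) -> ScalarField:
    """Second-order finite-difference solution of the P~ problem on a
    structured grid (Cartesian / polar), for independent verification of the
    finite-element solver.  Refuses grids too coarse to resolve the opening."""
    if grid_n < 16:
        raise ValueError("grid_n must be >= 16")
    if chamber.shape is Shape.RECTANGULAR:
        return _fd_rectangular(chamber.aspect, min(chamber.g, chamber.aspect), grid_n)
    return _fd_circular(min(chamber.theta, math.pi), grid_n)


def relative_l2_difference(field_a: ScalarField, field_b: ScalarField) -> float:
    """Area-weighted relative L2 difference, evaluated at the centroids of
    ``field_a``'s triangulation (``field_b`` is interpolated there)."""
    mesh = field_a.mesh
    cent = mesh.nodes[mesh.triangles].mean(axis=1)
    w = mesh.areas
    va = field_a.values[mesh.triangles].mean(axis=1)
    vb = field_b.interpolate(cent)
    num = np.sqrt(np.sum(w * (va - vb) ** 2))
    den = np.sqrt(np.sum(w * va**2))
    return float(num / max(den, 1e-300))
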