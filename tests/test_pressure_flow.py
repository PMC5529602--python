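"""Pressure assembly, proboscis coupling and conservation checks."""

import math

import numpy as np
import pytest

from probopump import (
    WATER,
    ChamberGeometry,
    FluidProperties,
    PlungerKinematics,
    ProboscisGeometry,
    assemble_pressure,
    compute_K,
    coupling_pressure,
    dimensional_pressure,
    f_factor,
    fd_oracle,
    opening_flux,
    poiseuille_discharge,
    squeeze_pressure,
    velocity_field,
)
from probopump.pressure_flow import GeometryFieldMismatch

MM, UM = 1e-3, 1e-6


@pytest.fixture(scope="module")
def rect_setup(solve_cache):
    chamber = ChamberGeometry.rectangular(L=1 * MM, W=1 * MM, opening=0.3 * MM)
    proboscis = ProboscisGeometry(l_p=5 * MM, d_p=0.3 * MM)
    mesh, ptilde, rec = solve_cache("rectangular", aspect=1.0, g=0.3)
    asm = assemble_pressure(ptilde, chamber, proboscis, h=0.2 * MM, convergence=rec)
    return chamber, proboscis, asm


class TestSqueezePressure:
    def test_boundary_and_centre_values(self):
        assert squeeze_pressure("rectangular", [[0.5, 0.0]]) == pytest.approx(0.0)
        assert squeeze_pressure("rectangular", [[-0.5, 0.2]]) == pytest.approx(0.0)
        assert squeeze_pressure("rectangular", [[0.0, 0.0]]) == pytest.approx(-0.125)
        assert squeeze_pressure("circular", [[1.0, 0.0]]) == pytest.approx(0.0)
        assert squeeze_pressure("circular", [[0.0, 0.0]]) == pytest.approx(-0.25)

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            squeeze_pressure("rectangular", [[0.6, 0.0]])
        with pytest.raises(ValueError):
            squeeze_pressure("circular", [[1.2, 0.0]])


class TestCouplingConstant:
    def test_circular_identity_with_f_factor(self):
        # areas and radii cancel: K_c = -(32/3) * f
        prob = ProboscisGeometry(l_p=10.1 * MM, d_p=494.6 * UM)
        ch = ChamberGeometry.circular(R=2417.6 * UM / 2, opening=494.6 * UM)
        h = 765.9 * UM
        f = f_factor(prob, h)
        assert compute_K(ch, prob, h) == pytest.approx(-(32 / 3) * f, rel=1e-14)
        assert compute_K(ch, prob, h) == pytest.approx(-808.8, rel=1e-3)

    def test_rectangular_identity(self):
        prob = ProboscisGeometry(l_p=3 * MM, d_p=50 * UM)
        ch = ChamberGeometry.rectangular(L=800 * UM, W=500 * UM, opening=50 * UM)
        h = 150 * UM
        f = f_factor(prob, h)
        expect = -(32 / (3 * math.pi)) * f * ch.aspect
        assert compute_K(ch, prob, h) == pytest.approx(expect, rel=1e-14)

    def test_closed_pump_limit(self):
        prob = ProboscisGeometry(l_p=3 * MM, d_p=50 * UM)
        ch = ChamberGeometry.circular(R=400 * UM, opening=50 * UM)
        assert compute_K(ch, prob, 0.0) == 0.0


class TestAssembly:
    def test_opening_pressure_equals_K(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        onodes = asm.field.mesh.opening_nodes()
        assert np.max(np.abs(asm.field.values[onodes] - asm.K)) < 1e-12 * abs(asm.K)

    def test_geometry_mismatch_rejected(self, rect_setup, solve_cache):
        chamber, proboscis, _ = rect_setup
        _, wrong, _ = solve_cache("circular", theta=0.3)
        with pytest.raises(GeometryFieldMismatch):
            assemble_pressure(wrong, chamber, proboscis, h=0.2 * MM)

    def test_poisson_residual_is_one(self):
        # assemble on the structured-oracle field: the discrete five-point
        # Laplacian of the total P must equal 1 at uniform interior nodes
        chamber = ChamberGeometry.rectangular(L=1 * MM, W=1 * MM, opening=0.3 * MM)
        proboscis = ProboscisGeometry(l_p=5 * MM, d_p=0.3 * MM)
        ptilde = fd_oracle(ChamberGeometry.from_dimensionless(
            "rectangular", aspect=1.0, g=0.3), 64)
        asm = assemble_pressure(ptilde, chamber, proboscis, h=0.2 * MM)
        xs = np.unique(np.round(ptilde.mesh.nodes[:, 0], 12))
        ys = np.unique(np.round(ptilde.mesh.nodes[:, 1], 12))
        val = {(round(x, 12), round(y, 12)): v
               for (x, y), v in zip(ptilde.mesh.nodes, asm.field.values)}
        hx = xs[1] - xs[0]
        checked = 0
        for i in range(1, len(xs) - 1):
            for j in range(1, len(ys) - 1):
                hm, hp = ys[j] - ys[j - 1], ys[j + 1] - ys[j]
                if abs(hm - hp) > 1e-12:
                    continue  # skip the junction rows of the aligned grid
                x, y = xs[i], ys[j]
                lap = ((val[(round(x - hx, 12), y)] + val[(round(x + hx, 12), y)]
                        - 2 * val[(x, y)]) / hx**2
                       + (val[(x, round(y - hm, 12))] + val[(x, round(y + hp, 12))]
                          - 2 * val[(x, y)]) / hm**2)
                assert lap == pytest.approx(1.0, abs=1e-8)
                checked += 1
        assert checked > 100

    def test_wall_normal_velocity_vanishes(self, rect_setup):
        # Eq-12 consequence: no flow through the impermeable walls
        chamber, proboscis, asm = rect_setup
        kin = PlungerKinematics(h=0.2 * MM, dhdt=1 * MM)
        p = dimensional_pressure(asm, WATER, kin)
        v = velocity_field(p, kin.h, WATER)
        vmax = np.max(np.hypot(v[:, 0], v[:, 1]))
        mesh = asm.field.mesh
        edge_owner = {}
        for tid, (a, b, c) in enumerate(mesh.triangles):
            for e in ((a, b), (b, c), (c, a)):
                edge_owner.setdefault(frozenset(e), []).append(tid)
        bad = []
        for e, tag in zip(mesh.boundary_edges, mesh.boundary_tags):
            mid = mesh.nodes[e].mean(axis=0)
            if abs(mid[0] - 0.5) < 1e-9:          # right wall, normal = +x
                for tid in edge_owner[frozenset(map(int, e))]:
                    bad.append(abs(v[tid, 0]))
        assert max(bad) < 0.02 * vmax


class TestDimensionalPressure:
    def test_zero_rate_gives_zero(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        p = dimensional_pressure(asm, WATER, PlungerKinematics(h=0.2 * MM, dhdt=0.0))
        assert np.max(np.abs(p.values)) == 0.0

    def test_uptake_is_all_suction(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        p = dimensional_pressure(asm, WATER, PlungerKinematics(h=0.2 * MM, dhdt=1e-3))
        assert np.max(p.values) <= 0.0
        assert p.units == "Pa"

    def test_cubic_height_dependence_of_the_scale(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        s1 = asm.pressure_scale(WATER, 1e-3)
        chamber3 = chamber
        from probopump import assemble_pressure as ap
        asm3 = ap(asm.ptilde, chamber3, proboscis, h=3 * 0.2 * MM)
        s3 = asm3.pressure_scale(WATER, 1e-3)
        assert s1 / s3 == pytest.approx(27.0, rel=1e-12)


class TestVelocityField:
    def test_uniform_pressure_means_no_flow(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        from probopump.chamber_bvp import ScalarField
        p = ScalarField(asm.field.mesh, np.full(asm.field.mesh.n_nodes, 7.0),
                        units="Pa")
        v = velocity_field(p, 1e-4, WATER)
        assert np.max(np.abs(v)) < 1e-12

    def test_quadratic_height_scaling(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        kin = PlungerKinematics(h=0.2 * MM, dhdt=1e-3)
        p = dimensional_pressure(asm, WATER, kin)
        v1 = velocity_field(p, 2e-4, WATER)
        v2 = velocity_field(p, 1e-4, WATER)
        assert np.allclose(v1, 4 * v2, rtol=1e-12)


class TestProboscisCoupling:
    def test_poiseuille_worked_example(self):
        # d_p = 100 um, l_p = 10 mm, water, 100 Pa
        prob = ProboscisGeometry(l_p=10 * MM, d_p=100 * UM)
        q = poiseuille_discharge(100.0, prob, WATER)
        assert q == pytest.approx(2.454369e-11, rel=1e-6)
        assert poiseuille_discharge(0.0, prob, WATER) == 0.0
        assert poiseuille_discharge(-100.0, prob, WATER) == -q

    def test_fourth_power_of_diameter(self):
        p1 = ProboscisGeometry(l_p=10 * MM, d_p=100 * UM)
        p2 = ProboscisGeometry(l_p=10 * MM, d_p=200 * UM)
        assert poiseuille_discharge(50.0, p2, WATER) == pytest.approx(
            16 * poiseuille_discharge(50.0, p1, WATER), rel=1e-12)

    def test_separated_galeae_rejected(self):
        with pytest.raises(ZeroDivisionError):
            poiseuille_discharge(10.0, ProboscisGeometry(l_p=0.0, d_p=1e-4), WATER)

    def test_volume_conservation_round_trip(self):
        # poiseuille(coupling(...)) = -A dh/dt, an exact algebraic identity
        prob = ProboscisGeometry(l_p=7 * MM, d_p=80 * UM)
        ch = ChamberGeometry.rectangular(L=900 * UM, W=600 * UM, opening=80 * UM)
        kin = PlungerKinematics(h=2e-4, dhdt=3.7e-4)
        Pp = coupling_pressure(ch, prob, WATER, kin)
        assert Pp < 0
        assert poiseuille_discharge(Pp, prob, WATER) == pytest.approx(
            -ch.area * kin.dhdt, rel=1e-14)

    def test_suction_scales_with_area(self):
        prob = ProboscisGeometry(l_p=7 * MM, d_p=80 * UM)
        kin = PlungerKinematics(h=2e-4, dhdt=1e-4)
        c1 = ChamberGeometry.rectangular(L=900 * UM, W=600 * UM, opening=80 * UM)
        c2 = ChamberGeometry.rectangular(L=900 * UM, W=1200 * UM, opening=80 * UM)
        assert coupling_pressure(c2, prob, WATER, kin) == pytest.approx(
            2 * coupling_pressure(c1, prob, WATER, kin), rel=1e-14)


class TestOpeningFlux:
    def test_conservation(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        kin = PlungerKinematics(h=0.2 * MM, dhdt=1e-3)
        q = opening_flux(asm, WATER, kin)
        assert q == pytest.approx(chamber.area * kin.dhdt, rel=0.01)

    def test_sign_follows_the_stroke(self, rect_setup):
        chamber, proboscis, asm = rect_setup
        q_up = opening_flux(asm, WATER, PlungerKinematics(h=0.2 * MM, dhdt=1e-3))
        q_down = opening_flux(asm, WATER, PlungerKinematics(h=0.2 * MM, dhdt=-1e-3))
        assert q_down == pytest.approx(-q_up, rel=1e-12)
        assert opening_flux(asm, WATER,
                            PlungerKinematics(h=0.2 * MM, dhdt=0.0)) == 0.0

    def test_opening_pressure_matches_the_coupling_pressure(self, rect_setup):
        # Eq-10 scaling of K reproduces the lumped coupling pressure
        chamber, proboscis, asm = rect_setup
        kin = PlungerKinematics(h=0.2 * MM, dhdt=1e-3)
        p = dimensional_pressure(asm, WATER, kin)
        onodes = p.mesh.opening_nodes()
        Pp = coupling_pressure(chamber, proboscis, WATER, kin)
        assert np.mean(p.values[onodes]) == pytest.approx(Pp, rel=1e-3)
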