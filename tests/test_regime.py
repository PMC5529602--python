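"""f-factor, regime boundaries, classification and the B-factor."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from probopump import (
    ChamberGeometry,
    ProboscisGeometry,
    Shape,
    SpeciesRecord,
    b_factor,
    boundary_f,
    classify,
    classify_both_shapes,
    dissipation_ratio,
    empirical_cc_fit,
    f_factor,
    fig8_boundary_curves,
    proboscis_power,
)
from probopump.regime import PROBOSCIS_LIMITED, PUMP_LIMITED, BOUNDARY, cc_sweep

MM, UM = 1e-3, 1e-6

#: printed (l_p mm, d_p um, h um, f) — printed inputs are rounded, so the
#: recomputed f matches the printed value to ~2%
PRINTED_F = [
    ("Acherontia atropos", 10.1, 494.6, 765.9, 75.8),
    ("Danaus plexippus", 14.4, 35.0, 145.6, 29519.0),
    ("Manduca sexta", 50.0, 82.5, 1227.4, 1995780.0),
    ("Nadata gibosa", 3.58, 25.4, 240.4, 119495.0),
    ("Symmerista albifrons", 0.35, 17.3, 91.0, 2891.0),
]


class TestFFactor:
    @pytest.mark.parametrize("name, lp, dp, h, printed", PRINTED_F)
    def test_printed_values_reproduce(self, name, lp, dp, h, printed):
        prob = ProboscisGeometry(l_p=lp * MM, d_p=dp * UM)
        assert f_factor(prob, h * UM) == pytest.approx(printed, rel=0.02)

    def test_separated_galeae_gives_zero(self):
        assert f_factor(ProboscisGeometry(l_p=0.0, d_p=17.3 * UM), 91 * UM) == 0.0

    @given(scale=st.floats(1e-3, 1e3))
    def test_unit_invariance(self, scale):
        prob1 = ProboscisGeometry(l_p=5e-3, d_p=4e-5)
        prob2 = ProboscisGeometry(l_p=5e-3 * scale, d_p=4e-5 * scale)
        assert f_factor(prob2, 2e-4 * scale) == pytest.approx(
            f_factor(prob1, 2e-4), rel=1e-12)


class TestBoundaryF:
    def test_all_dirichlet_disk_closed_form(self):
        # C_c(pi) = 0 -> f_c = 3/256
        assert boundary_f("circular", theta=math.pi, C=0.0) == \
            pytest.approx(3 / 256, rel=1e-14)

    def test_full_opening_square_closed_form(self):
        # C_r = -1/4 at W/L = 1 -> f_r = pi/32
        assert boundary_f("rectangular", aspect=1.0, g=1.0, C=-0.25) == \
            pytest.approx(math.pi / 32, rel=1e-14)

    def test_small_opening_value_from_the_fit(self):
        C = 3.1 * math.log(0.2) - 2.25
        assert boundary_f("circular", theta=0.2, C=C) == pytest.approx(0.23, rel=0.02)

    def test_requires_constant_or_permission_to_solve(self):
        with pytest.raises(ValueError):
            boundary_f("circular", theta=0.5, solve=False)

    def test_monotonicity_in_opening_size(self, solve_cache):
        # wider openings hinder the flow less: f_c decreasing in theta,
        # f_r decreasing in g at fixed aspect
        fc = [boundary_f("circular", theta=t,
                         C=solve_cache("circular", theta=t)[2].constant_history[-1])
              for t in (0.3, 1.0)]
        assert fc[0] > fc[1] > 0
        fr = [boundary_f("rectangular", aspect=1.0, g=g,
                         C=solve_cache("rectangular", aspect=1.0, g=g)[2].constant_history[-1])
              for g in (0.05, 0.3)]
        assert fr[0] > fr[1] > 0


class TestDissipationRatio:
    def test_always_exceeds_one(self):
        out = dissipation_ratio(75.8, 0.23)
        assert out["total_over_Ep"] == pytest.approx(1.003, abs=5e-4)
        assert out["total_over_Ep"] > 1.0

    def test_proboscis_dominated_limit(self):
        assert dissipation_ratio(1e12, 0.3)["total_over_Ep"] == \
            pytest.approx(1.0, rel=1e-10)

    def test_zero_f_reports_the_pump_limited_extreme(self):
        out = dissipation_ratio(0.0, 0.3)
        assert math.isinf(out["Ec_over_Ep"]) and math.isinf(out["total_over_Ep"])

    def test_matches_direct_energy_balance(self):
        # 1 + f_b/f equals the direct evaluation of the dissipation ratio
        # from (C, h, l_p, d_p, L, W)
        lp, dp, h, L, W, C = 5e-3, 6e-5, 2e-4, 9e-4, 7e-4, -1.7
        f = lp * h**3 / dp**4
        fb = boundary_f("rectangular", aspect=W / L, g=dp / L, C=C)
        direct = 1 + (3 * math.pi * dp**4 / (32 * lp * h**3)) * (L / W) ** 2 \
            * (W / (12 * L) - C)
        assert dissipation_ratio(f, fb)["total_over_Ep"] == \
            pytest.approx(direct, rel=1e-12)


class TestClassification:
    def test_coilable_species_are_proboscis_limited(self, table1):
        by_name = {r.name: r for r in table1}
        for name in ("Acherontia atropos", "Danaus plexippus",
                     "Manduca sexta", "Nadata gibosa"):
            assert classify(by_name[name]).regime == PROBOSCIS_LIMITED

    def test_separated_galeae_flips_the_regime(self, table1):
        rec = next(r for r in table1 if "albifrons" in r.name)
        assert classify(rec, l_p_override=0.0).regime == PUMP_LIMITED
        # with linked galeae the same moth sits in the proboscis category
        assert classify(rec).regime == PROBOSCIS_LIMITED

    def test_exact_tie_is_labelled_boundary(self):
        C = -2.0
        aspect, g = 0.8, 0.1
        fb = boundary_f("rectangular", aspect=aspect, g=g, C=C)
        d_p, L = 50 * UM, 500 * UM
        l_p = 5 * MM
        h = (fb * d_p**4 / l_p) ** (1 / 3)
        rec = SpeciesRecord(
            name="tie", proboscis=ProboscisGeometry(l_p=l_p, d_p=d_p),
            pump_length=L, pump_width=aspect * L, pump_height=h)
        assert classify(rec, C=C).regime == BOUNDARY

    def test_unit_invariance_of_classification(self, table1):
        rec = table1[0]
        base = classify(rec, C=-2.0)
        scaled = SpeciesRecord(
            name=rec.name,
            proboscis=ProboscisGeometry(l_p=rec.proboscis.l_p * 1e3,
                                        d_p=rec.proboscis.d_p * 1e3),
            pump_length=rec.pump_length * 1e3,
            pump_width=rec.pump_width * 1e3,
            pump_height=rec.pump_height * 1e3)
        other = classify(scaled, C=-2.0)
        assert other.regime == base.regime
        assert other.f == pytest.approx(base.f, rel=1e-12)
        assert other.f_boundary == pytest.approx(base.f_boundary, rel=1e-12)

    def test_both_shapes_report(self, table1):
        out = classify_both_shapes(table1[0], C=-2.0)
        assert set(out) == {"rectangular", "circular", "agree"}
        assert isinstance(out["agree"], bool)


class TestEmpiricalFit:
    def test_input_validation(self):
        with pytest.raises(ValueError):
            empirical_cc_fit([0.1, 0.2, 0.3], [-1, -2, -3])       # too few
        with pytest.raises(ValueError):
            empirical_cc_fit([0.1, 0.2, 0.3, 0.5, 2.5],
                             [-1, -2, -3, -4, -5])                # theta >= 2

    def test_recovers_an_exact_log_law(self):
        th = np.linspace(0.06, 0.7, 9)
        C = 2.9 * np.log(th) - 2.1
        out = empirical_cc_fit(th, C)
        assert out["slope"] == pytest.approx(2.9, rel=1e-12)
        assert out["intercept"] == pytest.approx(-2.1, rel=1e-12)

    def test_small_theta_slope_tends_to_the_point_sink_value(self, solve_cache):
        # logarithmic asymptotics of the 2-D problem: dC_c/d(ln theta) -> pi
        ths = np.linspace(0.04, 0.1, 6)
        Cs = [solve_cache("circular", theta=float(t))[2].constant_history[-1]
              for t in ths]
        out = empirical_cc_fit(ths, Cs, fit_range=(0.0, 0.11))
        assert out["slope"] == pytest.approx(math.pi, rel=0.05)


class TestBFactor:
    def test_death_head_sphinx(self, table1):
        rec = next(r for r in table1 if "atropos" in r.name)
        assert b_factor(rec.proboscis, rec.chamber()) == \
            pytest.approx(0.17e3, rel=0.03)

    def test_carolina_sphinx_lower_endpoint(self, table1):
        rec = next(r for r in table1 if "sexta" in r.name)
        assert b_factor(rec.proboscis, rec.chamber()) == \
            pytest.approx(765e3, rel=0.03)

    def test_viscosity_capacity_ratio(self, table1):
        by = {r.name.split()[-1]: r for r in table1}
        ratio = b_factor(by["atropos"].proboscis, by["atropos"].chamber()) / \
            b_factor(by["sexta"].proboscis, by["sexta"].chamber())
        assert 5e-5 < ratio < 5e-4   # the ~1e-4 honey/nectar viscosity window

    def test_power_scaling(self):
        assert proboscis_power(2e5, 1e-3, 1e-3) == pytest.approx(2e-4, rel=1e-14)


def test_fig8_boundary_curves_structure(solve_cache):
    df = fig8_boundary_curves(aspects=(1.0,), gs=(0.1, 0.3), thetas=(0.3, 1.0),
                              tol=0.01)
    assert (df["f_boundary"] > 0).all()
    rect = df[df["shape"] == "rectangular"].sort_values("parameter")
    circ = df[df["shape"] == "circular"].sort_values("parameter")
    assert rect["f_boundary"].is_monotonic_decreasing
    assert circ["f_boundary"].is_monotonic_decreasing
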