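"""Production model: photosynthesis closed forms, equilibria, R*/I*."""

import math

import numpy as np
import pytest

from coexist_eca.forcing import DailyWeather, default_forcing
from coexist_eca.production import (
    DEFAULT_CONSTANTS,
    DEFAULT_PHOTO,
    PlantState,
    _arrhenius,
    canopy_gpp_day,
    i_star,
    intercellular_co2,
    leaf_assimilation,
    r_star,
    simulate_monoculture,
    simulate_monocultures,
    solve_equilibria,
    solve_equilibrium,
    equilibria_to_frame,
)
from coexist_eca.traits import base_traits, sample_traits

AMBIENT, ELEVATED = 360.0, 550.0
SUMMER = DailyWeather(day_of_year=172, par=10.0, tair=20.0, vpd=1.0, daylength=15.0)


class TestIntercellularCO2:
    def test_closed_form_value(self):
        assert intercellular_co2(360.0, 1.0, 3.7) == pytest.approx(360.0 * 3.7 / 4.7, rel=1e-12)

    def test_low_vpd_limit_approaches_ca(self):
        assert intercellular_co2(360.0, 1e-12, 3.7) == pytest.approx(360.0, rel=1e-5)

    def test_monotone_in_g1_and_below_ca(self):
        lo = intercellular_co2(360.0, 1.0, 3.7)
        hi = intercellular_co2(360.0, 1.0, 7.4)
        assert lo < hi < 360.0

    def test_nonpositive_vpd_rejected(self):
        with pytest.raises(ValueError):
            intercellular_co2(360.0, 0.0, 3.7)


class TestLeafAssimilation:
    def test_dark_leaf_fixes_nothing(self):
        assert leaf_assimilation(50.0, 93.0, 280.0, 20.0, 0.0) == 0.0

    def test_zero_at_compensation_point(self):
        gamma = _arrhenius(DEFAULT_PHOTO.gamma_star_25, DEFAULT_PHOTO.e_gamma_star, 20.0)
        assert leaf_assimilation(50.0, 93.0, float(gamma), 20.0, 1000.0) == pytest.approx(0.0, abs=1e-9)

    def test_saturating_light_reaches_rubisco_limit(self):
        tair, ci = 25.0, 600.0
        vcmax, jmax = 30.0, 300.0  # large Jmax so Rubisco limits
        gamma = float(_arrhenius(DEFAULT_PHOTO.gamma_star_25, DEFAULT_PHOTO.e_gamma_star, tair))
        kc = float(_arrhenius(DEFAULT_PHOTO.kc_25, DEFAULT_PHOTO.e_kc, tair))
        ko = float(_arrhenius(DEFAULT_PHOTO.ko_25, DEFAULT_PHOTO.e_ko, tair))
        km = kc * (1.0 + DEFAULT_PHOTO.o2 / ko)
        expected = vcmax * (ci - gamma) / (ci + km)
        got = leaf_assimilation(vcmax, jmax, ci, tair, 1e5)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_light(self):
        irr = np.linspace(0.0, 2000.0, 30)
        a = leaf_assimilation(50.0, 93.0, 280.0, 20.0, irr)
        assert (np.diff(a) >= -1e-12).all()


class TestCanopyGpp:
    def test_no_leaf_area_no_carbon(self):
        state = PlantState(bf=0.0, br=50.0, nplant=1.0)
        assert canopy_gpp_day(state, base_traits(), SUMMER, AMBIENT) == pytest.approx(0.0, abs=1e-12)

    def test_co2_fertilization_at_fixed_state(self):
        state = PlantState(bf=150.0, br=150.0, nplant=8.0)
        a = canopy_gpp_day(state, base_traits(), SUMMER, AMBIENT)
        e = canopy_gpp_day(state, base_traits(), SUMMER, ELEVATED)
        assert e > a > 0.0

    def test_light_saturation_with_leaf_area(self):
        traits = base_traits()
        cs = DEFAULT_CONSTANTS

        def gpp_at_lai(lai):
            bf = lai * cs.cf / (cs.canopy_sla_factor * traits.sla / 1000.0)
            state = PlantState(bf=bf, br=bf, nplant=0.03 * (bf + traits.rho * bf))
            return canopy_gpp_day(state, traits, SUMMER, AMBIENT)

        gain_low = gpp_at_lai(1.0) / gpp_at_lai(0.5)
        gain_high = gpp_at_lai(12.0) / gpp_at_lai(6.0)
        assert gain_high < gain_low


class TestResidualResources:
    def test_r_star_zero_npp_returns_nmin(self):
        assert r_star(base_traits(), 0.0) == pytest.approx(3.0)

    def test_r_star_closed_form(self):
        expected = 3.0 * math.exp(-0.0239 * (0.6 / 0.75) * 200.0)
        assert r_star(base_traits(), 200.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0656, abs=2e-4)

    def test_r_star_vanishes_at_high_npp(self):
        assert r_star(base_traits(), 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_i_star_zero_npp_returns_ipar(self):
        assert i_star(base_traits(), 0.0, 2500.0) == pytest.approx(2500.0)

    def test_i_star_closed_form(self):
        expected = 2500.0 * math.exp(-0.6 * 0.4 * 0.014 * 0.4 / 0.44 * 200.0)
        assert i_star(base_traits(), 200.0, 2500.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1359.0, abs=2.0)

    def test_monotonicity(self):
        t = base_traits()
        assert i_star(t.replace(sla=28.0), 200.0, 2500.0) < i_star(t, 200.0, 2500.0)
        assert r_star(t, 300.0) < r_star(t, 200.0)
        assert r_star(t.replace(kr=2 * t.kr), 200.0) < r_star(t, 200.0)

    def test_negative_npp_rejected(self):
        with pytest.raises(ValueError):
            r_star(base_traits(), -1.0)


class TestEquilibrium:
    def test_base_monoculture_converges_within_23_years(self, forcing):
        eq = simulate_monoculture(base_traits(), forcing, AMBIENT)
        assert eq.converged
        assert eq.years_run == 23
        assert eq.npp_star > 0.0

    def test_elevated_co2_raises_equilibrium_npp(self, forcing):
        a = solve_equilibrium(base_traits(), forcing, AMBIENT)
        e = solve_equilibrium(base_traits(), forcing, ELEVATED)
        assert e.npp_star > a.npp_star

    def test_equilibrium_bounds(self, forcing):
        eq = solve_equilibrium(base_traits(), forcing, AMBIENT)
        assert 0.0 <= eq.r_star <= DEFAULT_CONSTANTS.nmin
        assert 0.0 <= eq.i_star <= forcing.ipar
        assert eq.nup_star == pytest.approx(DEFAULT_CONSTANTS.nmin - eq.r_star, rel=1e-9)

    def test_vanishing_foliage_allocation_collapses(self, forcing):
        eq = solve_equilibrium(base_traits().replace(af=1e-9), forcing, AMBIENT)
        assert eq.npp_star == pytest.approx(0.0, abs=0.1)

    def test_saturating_uptake_drives_r_star_to_zero(self, forcing):
        eq = solve_equilibrium(base_traits().replace(kr=10.0), forcing, AMBIENT)
        assert eq.nup_star == pytest.approx(3.0, abs=1e-6)
        assert eq.r_star == pytest.approx(0.0, abs=1e-6)

    def test_higher_carbon_use_efficiency_raises_npp(self, forcing):
        lo = solve_equilibrium(base_traits().replace(Y=0.4), forcing, AMBIENT)
        hi = solve_equilibrium(base_traits().replace(Y=0.6), forcing, AMBIENT)
        assert hi.npp_star > lo.npp_star

    def test_simulation_agrees_with_analytic_oracle(self, forcing):
        """Daily simulation and annual-balance fixed point meet within 1%.

        Leaf N:C and LAI are annual means of a seasonally cycling state,
        compared at 1.5% against the constant-state balance.
        """
        species = sample_traits(50, 7)
        for ca in (AMBIENT, ELEVATED):
            sim = simulate_monocultures(species, forcing, ca)
            ana = solve_equilibria(species, forcing, ca)
            checked = 0
            for s, a in zip(sim, ana):
                if a.npp_star <= 1.0 or not s.converged:
                    continue
                checked += 1
                assert s.npp_star == pytest.approx(a.npp_star, rel=0.01)
                assert s.nf_star == pytest.approx(a.nf_star, rel=0.015)
                assert s.lai_star == pytest.approx(a.lai_star, rel=0.015)
            assert checked >= 40

    def test_equilibrium_independent_of_initial_state(self, forcing):
        import coexist_eca.production as P

        base = base_traits()
        ref = simulate_monoculture(base, forcing, AMBIENT, years=30)
        orig = (P._INIT_BF, P._INIT_BR, P._INIT_NF)
        try:
            P._INIT_BF, P._INIT_BR, P._INIT_NF = 400.0, 600.0, 0.06
            far = simulate_monoculture(base, forcing, AMBIENT, years=30)
        finally:
            P._INIT_BF, P._INIT_BR, P._INIT_NF = orig
        assert far.npp_star == pytest.approx(ref.npp_star, rel=0.01)

    def test_nitrogen_closure_at_equilibrium(self, forcing):
        """Integrated annual N uptake balances N losses to within 0.5%."""
        eq = simulate_monoculture(base_traits(), forcing, AMBIENT, years=30)
        assert eq.converged
        assert eq.nloss_flux == pytest.approx(eq.nup_flux, rel=0.005)

    def test_equilibria_frame_joins_traits_and_state(self, forcing):
        species = sample_traits(3, 1)
        eqs = solve_equilibria(species, forcing, AMBIENT)
        frame = equilibria_to_frame(species, eqs)
        assert len(frame) == 3
        for col in ("species_id", "af", "npp_star", "r_star", "i_star", "converged"):
            assert col in frame.columns

    def test_co2_fertilization_and_slow_grower_advantage(self, random_species_200):
        """Elevated CO2 raises every viable species' NPP*, most for slow growers."""
        import scipy.stats

        _, equilibria = random_species_200
        na = np.array([e.npp_star for e in equilibria[AMBIENT]])
        ne = np.array([e.npp_star for e in equilibria[ELEVATED]])
        viable = na > 1.0
        assert viable.sum() > 150
        assert (ne[viable] > na[viable]).all()
        rho = scipy.stats.spearmanr(ne[viable] / na[viable], na[viable]).statistic
        assert rho < 0.0
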