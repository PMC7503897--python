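"""Energy-budget streams, conservation, orderings and monotonicities."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from heatbudget import budget as bd
from heatbudget.micromet import MicrometRecord

TS = pd.Timestamp("2020-05-19T19:30:00")


def rec(ta=33.3, rh=48.0, ws=2.4, sr=886.8, tg=None, ts=None):
    return MicrometRecord(TS, ta_c=ta, rh_pct=rh, ws_ms=ws, sr_wm2=sr, tg_c=tg, ts_c=ts)


@pytest.fixture
def boy(personas):
    return personas[0]["athlete"]


@pytest.fixture
def coach(personas):
    return personas[0]["coach"]


class TestSubModels:
    def test_body_surface_area_dubois(self):
        assert bd.body_surface_area(1.70, 67.0) == pytest.approx(1.78, abs=0.01)
        assert bd.body_surface_area(1.378, 31.9) == pytest.approx(1.11, abs=0.01)
        with pytest.raises(ValueError):
            bd.body_surface_area(-1.0, 60.0)

    def test_child_has_higher_area_to_mass_ratio(self, boy, coach):
        child_ratio = bd.body_surface_area(boy.height_m, boy.mass_kg) / boy.mass_kg
        adult_ratio = bd.body_surface_area(coach.height_m, coach.mass_kg) / coach.mass_kg
        assert child_ratio == pytest.approx(0.035, abs=0.002)
        assert adult_ratio == pytest.approx(0.026, abs=0.002)
        assert child_ratio > adult_ratio

    def test_metabolic_heat(self, boy, coach):
        assert bd.metabolic_heat(boy) == pytest.approx(364.0)  # 7 x 52
        assert bd.metabolic_heat(coach) == pytest.approx(168.0)  # 4 x 42
        resting = dataclasses.replace(coach, met=1.0)
        assert bd.metabolic_heat(resting) == pytest.approx(coach.rmr_wm2)

    def test_core_temperature_closure(self):
        assert bd.core_temperature(0.0) == pytest.approx(36.5)
        assert bd.core_temperature(364.0) == pytest.approx(38.07, abs=0.01)
        ms = np.linspace(0, 500, 11)
        tcs = [bd.core_temperature(m) for m in ms]
        assert all(a < b for a, b in zip(tcs, tcs[1:]))

    def test_resistances(self, boy, coach):
        ra, rc, rt = bd.resistances(boy, rec(ws=2.4))
        assert rc == pytest.approx(1.3 * 0.155 * 1212.0)
        assert ra == pytest.approx(88.0, abs=15.0)
        assert rt == pytest.approx(13.0, abs=0.5)  # 104 - 0.25*364, clamped above 10
        _, rc_coach, _ = bd.resistances(coach, rec())
        assert rc_coach == pytest.approx(0.6 * 0.155 * 1212.0)  # ~113 s/m

    def test_wind_floor_keeps_ra_finite(self, boy):
        ra_calm, _, _ = bd.resistances(boy, rec(ws=0.0))
        ra_floor, _, _ = bd.resistances(boy, rec(ws=0.3))
        assert np.isfinite(ra_calm)
        assert ra_calm == pytest.approx(ra_floor)


class TestRadiation:
    def test_longwave_only_when_dark(self, boy):
        r = rec(ta=25.0, rh=50.0, sr=0.0)
        site = bd.SiteContext(sky_view_factor=1.0, ground_surface_temp_c=25.0)
        got = bd.absorbed_radiation(r, site, boy, elevation_deg=10.0)
        c = bd.DEFAULT_CONSTANTS
        e_air = 0.5 * bd.saturation_vapor_pressure_kpa(25.0)
        eps_sky = bd._idso_sky_emissivity(25.0, e_air)
        ta4 = c.sigma * (25.0 + 273.15) ** 4
        expected = boy.emissivity * (0.5 * eps_sky * ta4 + 0.5 * c.ground_emissivity * ta4)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shade_scales_beam_and_sky_terms_only(self, boy):
        r = rec()
        shaded = bd.SiteContext(shade_transmissivity=0.175, ground_surface_temp_c=40.0)
        open_sky = bd.SiteContext(shade_transmissivity=1.0, ground_surface_temp_c=40.0)
        sw_open = bd.absorbed_radiation(r, open_sky, boy, elevation_deg=60.0)
        sw_shade = bd.absorbed_radiation(r, shaded, boy, elevation_deg=60.0)
        # difference is (1 - tau) x (beam + sky-diffuse); reflected + longwave unchanged
        dark = rec(sr=0.0)
        lw = bd.absorbed_radiation(dark, open_sky, boy, elevation_deg=60.0)
        reflected = (1 - boy.clothing_albedo) * 0.5 * open_sky.ground_albedo * r.sr_wm2
        beam_sky_open = sw_open - lw - reflected
        beam_sky_shade = sw_shade - lw - reflected
        assert beam_sky_shade == pytest.approx(0.175 * beam_sky_open, rel=1e-9)

    def test_may_mean_magnitude(self, boy):
        site = bd.SiteContext(ground_albedo=0.08, ground_surface_temp_c=60.0)
        got = bd.absorbed_radiation(rec(), site, boy, elevation_deg=60.0)
        assert got == pytest.approx(750.0, abs=80.0)

    def test_low_sun_with_high_sr_warns(self, boy):
        site = bd.SiteContext(ground_surface_temp_c=30.0)
        with pytest.warns(UserWarning, match="inconsistent"):
            bd.absorbed_radiation(rec(sr=400.0), site, boy, elevation_deg=1.0)


class TestConvectionEvaporation:
    def test_zero_gradient_means_zero_flux(self, coach):
        m = bd.metabolic_heat(coach)
        tc = bd.core_temperature(m)
        r = rec(ta=tc)
        conv, tsk, tsurf = bd.convective_loss(coach, r)
        assert conv == pytest.approx(0.0, abs=1e-12)
        assert tsk == pytest.approx(tc)
        assert tsurf == pytest.approx(tc)

    def test_sign_flips_when_air_hotter_than_core(self, coach):
        conv_hot, _, _ = bd.convective_loss(coach, rec(ta=45.0))
        conv_cool, _, _ = bd.convective_loss(coach, rec(ta=25.0))
        assert conv_hot < 0 < conv_cool

    def test_athlete_magnitude_at_may_mean(self, boy):
        conv, tsk, tsurf = bd.convective_loss(boy, rec())
        assert conv == pytest.approx(23.0, abs=10.0)
        assert rec().ta_c < tsurf < tsk < bd.core_temperature(bd.metabolic_heat(boy))

    def test_no_vapor_gradient_no_evaporation(self, coach):
        r = rec(ta=30.0, rh=100.0)
        assert bd.evaporative_loss(coach, r, tsk_c=30.0) == pytest.approx(0.0, abs=1e-12)

    def test_child_cap_is_half_adult(self, boy, coach):
        # at cap saturation, the child evaporates exactly half the adult max
        r = rec(ta=40.0, rh=20.0, ws=5.0)
        hot_adult = dataclasses.replace(coach, met=7.0, rmr_wm2=52.0)
        e_adult = bd.evaporative_loss(hot_adult, r, tsk_c=38.0)
        e_child = bd.evaporative_loss(boy, r, tsk_c=38.0)
        c = bd.DEFAULT_CONSTANTS
        assert e_adult == pytest.approx(c.s_cap_adult_wm2)
        assert e_child == pytest.approx(0.5 * c.s_cap_adult_wm2)

    def test_athlete_hits_child_cap_at_may_mean(self, boy):
        _, tsk, _ = bd.convective_loss(boy, rec())
        assert bd.evaporative_loss(boy, rec(), tsk) == pytest.approx(182.5)

    def test_emitted_longwave_stefan_boltzmann(self, boy):
        got = bd.emitted_longwave(35.0, boy)
        assert got == pytest.approx(486.0, abs=1.0)
        assert bd.emitted_longwave(36.0, boy) > got


class TestEnergyBudget:
    def test_conservation_identity(self, boy):
        site = bd.SiteContext(ground_surface_temp_c=60.0, ground_albedo=0.08)
        bb = bd.energy_budget(boy, rec(), site, elevation_deg=60.0)
        assert bb.budget_wm2 == pytest.approx(
            bb.m_wm2 + bb.rabs_wm2 - bb.conv_wm2 - bb.evap_wm2 - bb.tremit_wm2, abs=1e-9
        )
        assert bb.evap_wm2 >= 0
        assert bb.tremit_wm2 > 0

    def test_plausibility_corridor_at_may_mean(self, personas):
        profiles, sites, _ = personas
        turf = bd.SiteContext(ground_albedo=0.08, ground_surface_temp_c=60.0)
        athlete = bd.energy_budget(profiles["athlete"], rec(), turf, elevation_deg=60.0)
        coach = bd.energy_budget(profiles["coach"], rec(), sites["grass_sideline"],
                                 elevation_deg=60.0)
        assert athlete.budget_wm2 > 340.0
        assert 120.0 < coach.budget_wm2 < 340.0

    def test_child_budget_dominates_adult_on_grid(self, boy, coach):
        site = bd.SiteContext()  # grass, Ts = Ta
        for ta, ws, sr in itertools.product(
            np.linspace(25, 40, 4), np.linspace(0.5, 6, 4), np.linspace(0, 1000, 5)
        ):
            r = rec(ta=ta, rh=50.0, ws=ws, sr=sr)
            b_child = bd.energy_budget(boy, r, site, elevation_deg=60.0).budget_wm2
            b_adult = bd.energy_budget(coach, r, site, elevation_deg=60.0).budget_wm2
            assert b_child >= b_adult

    def test_monotone_in_forcing(self, boy):
        base = rec()
        site = bd.SiteContext(ground_surface_temp_c=50.0)
        b0 = bd.energy_budget(boy, base, site, elevation_deg=60.0).budget_wm2
        b_sr = bd.energy_budget(boy, rec(sr=986.8), site, elevation_deg=60.0).budget_wm2
        b_ts = bd.energy_budget(boy, base, bd.SiteContext(ground_surface_temp_c=60.0),
                                elevation_deg=60.0).budget_wm2
        hotter = dataclasses.replace(boy, met=boy.met + 1.0)
        b_met = bd.energy_budget(hotter, base, site, elevation_deg=60.0).budget_wm2
        assert b_sr > b0 and b_ts > b0 and b_met > b0

    def test_shade_monotonicity(self, boy):
        budgets = [
            bd.energy_budget(boy, rec(), bd.SiteContext(shade_transmissivity=tau),
                             elevation_deg=60.0).budget_wm2
            for tau in (0.1, 0.3, 0.5, 0.8, 1.0)
        ]
        assert all(a <= b for a, b in zip(budgets, budgets[1:]))

    def test_persona_ordering_athlete_coach_parent(self, personas, may_mean_record):
        profiles, sites, _ = personas
        b = {
            name: bd.energy_budget(profiles[name], may_mean_record, sites[site],
                                   elevation_deg=60.0).budget_wm2
            for name, site in (("athlete", "turf_field"), ("coach", "grass_sideline"),
                               ("parent", "oak_shade"))
        }
        assert b["athlete"] > b["coach"] > b["parent"]

    def test_turf_site_requires_record_surface_temp(self, boy, personas):
        _, sites, _ = personas
        with pytest.raises(ValueError, match="ts_c"):
            bd.energy_budget(boy, rec(ts=None), sites["turf_field"], elevation_deg=60.0)


class TestConstantsRegistry:
    def test_positive_only(self):
        with pytest.raises(ValueError):
            bd.ConstantsRegistry(rho_cp=-1.0)

    def test_override_changes_result(self, boy):
        site = bd.SiteContext(ground_surface_temp_c=50.0)
        base = bd.energy_budget(boy, rec(), site, elevation_deg=60.0)
        alt = bd.energy_budget(boy, rec(), site, elevation_deg=60.0,
                               constants=bd.DEFAULT_CONSTANTS.replace(s_cap_adult_wm2=500.0))
        assert alt.evap_wm2 > base.evap_wm2
        assert "s_cap_adult_wm2" in bd.DEFAULT_CONSTANTS.as_dict()
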