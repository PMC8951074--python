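import dataclasses

import numpy as np
import pytest

from milletswb import (CropState, InvalidConfigError, Management, SoilProfile,
                       Stage, advance_phenology, dm_increment, partition_dm,
                       root_depth, simulate_season, update_lai)
from conftest import constant_weather


class TestPhenology:
    def test_emergence_crossing(self, kangara):
        state = CropState(gdd_cum=55.0)
        stage = advance_phenology(state, 10.0, 0.0, kangara)
        assert stage is Stage.EMERGED

    def test_vegetative_after_emergence_day(self, kangara):
        state = CropState(gdd_cum=55.0)
        advance_phenology(state, 10.0, 0.0, kangara)
        assert advance_phenology(state, 10.0, 0.0, kangara) is Stage.VEGETATIVE

    def test_landrace_flowering_threshold(self, kantana):
        state = CropState(gdd_cum=1050.0, stage=Stage.REPRODUCTIVE)
        assert advance_phenology(state, 10.0, 0.0, kantana) is Stage.REPRODUCTIVE
        assert state.gdd_cum >= 1058.0

    def test_zero_increment_keeps_stage(self, kantana):
        state = CropState(gdd_cum=500.0, stage=Stage.VEGETATIVE)
        assert advance_phenology(state, 0.0, 0.0, kantana) is Stage.VEGETATIVE

    def test_transitions_irreversible(self, kangara):
        state = CropState(gdd_cum=700.0, stage=Stage.REPRODUCTIVE)
        advance_phenology(state, 0.0, 0.0, kangara)
        assert state.stage is Stage.REPRODUCTIVE

    def test_misordered_thresholds_rejected(self, kantana):
        with pytest.raises(InvalidConfigError):
            dataclasses.replace(kantana, gdd_flower=50.0)


class TestDryMatterProduction:
    def test_no_interception_no_growth(self, kantana):
        assert dm_increment(5.0, 800.0, 0.0, 25.0, kantana) == 0.0

    def test_radiation_limited_rate(self, kantana):
        # RUE 0.0026 * FI 0.5 * 20 MJ = 0.026 kg m-2, water not limiting
        inc = dm_increment(9.0, 100.0, 0.5, 20.0, kantana)
        assert inc == pytest.approx(0.026, rel=1e-12)

    def test_transpiration_limited_rate(self, agrigreen):
        # DWR 11.3 Pa * 5 mm / 1000 Pa under unlimited radiation
        inc = dm_increment(5.0, 1000.0, 0.99, 1000.0, agrigreen)
        assert inc == pytest.approx(0.0565, rel=1e-12)

    def test_never_exceeds_either_limit(self, kantana):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t_act, vpd = rng.uniform(0, 9), rng.uniform(100, 3000)
            fi, rs = rng.uniform(0, 0.99), rng.uniform(0, 32)
            inc = dm_increment(t_act, vpd, fi, rs, kantana)
            assert inc <= kantana.rue * fi * rs + 1e-15
            assert inc <= kantana.dwr * t_act / max(vpd, 100.0) + 1e-15


class TestPartitioning:
    def test_p_zero_all_leaf(self, kantana):
        params = dataclasses.replace(kantana, p=0.0,
                                     root_fraction_initial=0.0)
        state = CropState(gdd_cum=500.0)
        partition_dm(state, 0.5, Stage.VEGETATIVE, params)
        assert state.ldm == pytest.approx(0.5)
        assert state.sdm == 0.0

    def test_leaf_stem_split(self, kantana):
        params = dataclasses.replace(kantana, p=2.0,
                                     root_fraction_initial=0.0)
        state = CropState(gdd_cum=500.0)
        partition_dm(state, 1.0, Stage.VEGETATIVE, params)
        assert state.ldm == pytest.approx(1.0 / 3.0)
        assert state.sdm == pytest.approx(2.0 / 3.0)

    def test_reproductive_goes_to_grain(self, kantana):
        state = CropState(gdd_cum=kantana.gdd_flower + 1, ldm=0.3, sdm=0.5)
        before = state.total_dm
        partition_dm(state, 0.04, Stage.REPRODUCTIVE, kantana)
        assert state.hdm == pytest.approx(0.04)  # root share is 0 at flowering
        assert state.total_dm - before == pytest.approx(0.04, abs=1e-12)

    def test_mass_conserved_with_root_share(self, kantana):
        state = CropState(gdd_cum=300.0)
        before = state.total_dm
        partition_dm(state, 0.02, Stage.VEGETATIVE, kantana)
        assert state.total_dm - before == pytest.approx(0.02, abs=1e-15)
        assert state.rdm > 0

    def test_lai_tracks_leaf_mass(self, kantana):
        state = CropState(gdd_cum=500.0)
        partition_dm(state, 0.3, Stage.VEGETATIVE, kantana)
        assert state.lai == pytest.approx(kantana.sla * state.ldm, abs=1e-12)


class TestLaiAndRoots:
    def test_lai_examples(self):
        assert update_lai(0.0, 20.0) == 0.0
        assert update_lai(0.4817, 19.91) == pytest.approx(9.59, abs=0.01)
        assert update_lai(0.1, 22.49) == pytest.approx(2.249)

    def test_root_depth_profile(self, kantana):
        assert root_depth(0.0, kantana) == 0.05
        assert root_depth(kantana.gdd_flower, kantana) == kantana.rd_max
        mid = (kantana.gdd_emerge + kantana.gdd_flower) / 2
        assert root_depth(mid, kantana) == pytest.approx((0.05 + 1.0) / 2)
        assert root_depth(kantana.gdd_flower + 500, kantana) == kantana.rd_max


class TestSeasonSimulation:
    def test_landrace_reaches_maturity_in_long_season(self, kantana,
                                                      long_warm_weather,
                                                      ample_management):
        result = simulate_season(kantana, long_warm_weather,
                                 management=ample_management)
        assert result.status == "mature"
        assert result.final_state.gdd_cum >= 2124.0

    def test_water_mass_closure_every_day(self, kantana, season_weather):
        result = simulate_season(kantana, season_weather)
        for rec in result.days:
            assert abs(rec.flux.closure_residual) < 1e-9

    def test_dry_matter_pool_conservation(self, kantana, season_weather):
        result = simulate_season(kantana, season_weather)
        produced = sum(rec.dm_inc for rec in result.days)
        final = result.final_state
        assert final.total_dm == pytest.approx(
            kantana.dm_at_emergence + produced, abs=1e-9)

    def test_deterministic_trace(self, kangara, season_weather):
        a = simulate_season(kangara, season_weather).to_dataframe()
        b = simulate_season(kangara, season_weather).to_dataframe()
        assert a.equals(b)

    def test_stage_sequence_monotone(self, kangara, season_weather,
                                     ample_management):
        result = simulate_season(kangara, season_weather,
                                 management=ample_management)
        orders = [rec.state.stage.order for rec in result.days]
        assert orders == sorted(orders)
        assert result.status == "mature"

    def test_drought_stunts_growth(self, kangara, ample_management):
        weather = constant_weather(120, t_max=32, t_min=20, rain=0.0,
                                   rh_max=60, rh_min=25)
        dry = simulate_season(kangara, weather,
                              management=Management(mode="rainfed"))
        wet = simulate_season(kangara, weather, management=ample_management)
        assert dry.final_state.agdm < wet.final_state.agdm
        # the rainfed profile runs down to severe stress
        assert max(rec.state.si_today for rec in dry.days) > 0.5

    def test_doubling_rue_doubles_radiation_limited_biomass(
            self, trial_truth, season_weather, ample_management):
        # canopy saturated (huge k_par and SLA -> FI = 1 from emergence) so
        # interception does not feed back on growth; water never limits
        water_unlimited = dataclasses.replace(trial_truth, dwr=1e6,
                                              k_par=5.0, sla=1e4)
        doubled = dataclasses.replace(water_unlimited,
                                      rue=2 * water_unlimited.rue)
        base = simulate_season(water_unlimited, season_weather,
                               management=ample_management)
        twice = simulate_season(doubled, season_weather,
                                management=ample_management)
        e0 = trial_truth.dm_at_emergence
        gain = base.final_state.agdm - e0
        gain2 = twice.final_state.agdm - e0
        assert gain2 == pytest.approx(2 * gain, rel=1e-9)

    def test_radiation_limited_closed_form(self, trial_truth, season_weather,
                                           ample_management):
        # under ample water, AGDM growth equals RUE * sum(FI * Rs) exactly
        result = simulate_season(trial_truth, season_weather,
                                 management=ample_management)
        cum = sum(rec.fi_rad * season_weather[rec.day_index].solar_rad
                  for rec in result.days)
        assert result.final_state.agdm - trial_truth.dm_at_emergence == \
            pytest.approx(trial_truth.rue * cum, abs=1e-9)

    def test_short_weather_reports_incomplete(self, kantana):
        weather = constant_weather(3, t_max=22, t_min=18)
        result = simulate_season(kantana, weather)
        assert result.status == "ended_before_emergence"

    def test_theta_stays_within_hydraulic_limits(self, kangara,
                                                 season_weather):
        soil = SoilProfile.default(theta=0.20)
        result = simulate_season(kangara, season_weather, soil=soil)
        frame = result.to_dataframe()
        assert (frame.storage_end <= 0.27 * 1000 + 1e-9).all()
        assert (frame.storage_end >= 0.13 * 1000 - 1e-9).all()
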