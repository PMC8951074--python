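import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milletswb import (InvalidInputError, SoilLayer, SoilProfile,
                       et_from_balance, extract_evaporation,
                       extract_transpiration, infiltrate_cascade,
                       irrigation_decision, load_fixture_tables,
                       partition_et, profile_deficit, stress_index)


class TestEtFromBalance:
    def test_printed_first_week(self):
        # first weekly row of the landrace ledger
        assert et_from_balance(26, 0, 0, 0, 315, 328) == pytest.approx(13.0)

    def test_printed_storm_week(self):
        # the ~209 mm storm week: heavy drainage, modest ET
        assert et_from_balance(209, 0, 0, 88, 357, 434) == pytest.approx(44.0)

    def test_all_zero(self):
        assert et_from_balance(0, 0, 0, 0, 100, 100) == 0.0

    def test_negative_et_warns(self):
        with pytest.warns(UserWarning):
            et = et_from_balance(0, 0, 0, 0, 300, 320)
        assert et == pytest.approx(-20.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            et_from_balance(float("nan"), 0, 0, 0, 300, 320)


class TestCascade:
    def test_saturated_profile_passes_everything(self):
        profile = SoilProfile.default()  # starts at field capacity
        before = profile.storage_mm()
        assert infiltrate_cascade(profile, 15.0) == pytest.approx(15.0)
        assert profile.storage_mm() == pytest.approx(before)

    def test_single_layer_absorbs_to_capacity(self):
        profile = SoilProfile([SoilLayer(0.2, fc=0.30, pwp=0.10, theta=0.25)])
        drainage = infiltrate_cascade(profile, 20.0)
        assert drainage == pytest.approx(10.0)
        assert profile.layers[0].theta == pytest.approx(0.30)

    def test_no_water_no_change(self):
        profile = SoilProfile.default(theta=0.20)
        before = profile.storage_mm()
        assert infiltrate_cascade(profile, 0.0) == 0.0
        assert profile.storage_mm() == before

    @settings(derandomize=True, max_examples=100)
    @given(theta=st.floats(0.14, 0.27), water=st.floats(0, 300),
           split=st.floats(0, 1))
    def test_conservation_and_path_independence(self, theta, water, split):
        one = SoilProfile.default(theta=theta)
        two = SoilProfile.default(theta=theta)
        before = one.storage_mm()
        d_one = infiltrate_cascade(one, water)
        d_two = infiltrate_cascade(two, water * split) + \
            infiltrate_cascade(two, water * (1 - split))
        assert one.storage_mm() - before + d_one == pytest.approx(water, abs=1e-9)
        assert d_two == pytest.approx(d_one, abs=1e-9)
        for la, lb in zip(one.layers, two.layers):
            assert la.theta == pytest.approx(lb.theta, abs=1e-12)
            assert la.theta <= la.fc + 1e-12


class TestDeficit:
    def test_field_capacity_means_none(self):
        assert profile_deficit(SoilProfile.default(), 1.0) == 0.0

    def test_uniform_dry_down(self):
        profile = SoilProfile([SoilLayer(0.2, fc=0.27, pwp=0.13, theta=0.22)
                               for _ in range(5)])
        assert profile_deficit(profile, 1.0) == pytest.approx(50.0)

    def test_wet_layers_clamp_to_zero(self):
        layers = [SoilLayer(0.2, fc=0.27, pwp=0.13, theta=0.35),
                  SoilLayer(0.2, fc=0.27, pwp=0.13, theta=0.22)]
        assert profile_deficit(SoilProfile(layers), 0.4) == pytest.approx(10.0)

    def test_partial_layer_prorata(self):
        profile = SoilProfile([SoilLayer(0.2, fc=0.27, pwp=0.13, theta=0.22)])
        assert profile_deficit(profile, 0.1) == pytest.approx(5.0)

    def test_depth_beyond_profile_rejected(self):
        with pytest.raises(InvalidInputError):
            profile_deficit(SoilProfile.default(), 2.0)


class TestPartitionEt:
    @pytest.mark.parametrize("eto, fi, expected", [
        (5.0, 0.0, (5.0, 0.0)),
        (6.0, 0.5, (3.0, 3.0)),
        (4.0, 1 - 1e-9, (4e-9, 4.0)),
    ])
    def test_split(self, eto, fi, expected):
        e_pot, t_pot = partition_et(eto, fi)
        assert e_pot == pytest.approx(expected[0], abs=1e-6)
        assert t_pot == pytest.approx(expected[1], abs=1e-6)
        assert e_pot + t_pot == pytest.approx(eto, abs=1e-12)


class TestTranspiration:
    def test_unlimited_at_field_capacity(self):
        profile = SoilProfile.default()
        assert extract_transpiration(profile, 5.0, 1.0) == pytest.approx(5.0)
        assert extract_transpiration(SoilProfile.default(), 12.0, 1.0) == \
            pytest.approx(9.0)  # capped at the crop maximum rate

    def test_none_at_wilting_point(self):
        profile = SoilProfile.default(theta=0.13)
        assert extract_transpiration(profile, 5.0, 1.0) == 0.0

    def test_linear_reduction_below_threshold(self):
        # available fraction 0.15 against threshold 0.30 halves the demand
        theta = 0.13 + 0.15 * (0.27 - 0.13)
        profile = SoilProfile.default(theta=theta)
        t_act = extract_transpiration(profile, 4.0, 1.0,
                                      stress_threshold=0.30)
        assert t_act == pytest.approx(2.0, rel=1e-9)

    def test_water_comes_from_root_zone_proportionally(self):
        profile = SoilProfile.default()
        extract_transpiration(profile, 6.0, 0.4)
        wet = [layer.theta for layer in profile.layers]
        assert wet[0] < 0.27 and wet[1] < 0.27
        assert all(t == pytest.approx(0.27) for t in wet[2:])

    def test_never_draws_below_wilting(self):
        profile = SoilProfile.default(theta=0.135)
        for _ in range(50):
            extract_transpiration(profile, 9.0, 1.0)
        assert all(layer.theta >= layer.pwp - 1e-12
                   for layer in profile.layers)

    def test_bad_root_depth_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_transpiration(SoilProfile.default(), 1.0, 0.0)


class TestEvaporation:
    def test_dry_surface_gives_none(self):
        profile = SoilProfile.default(theta=0.13)
        assert extract_evaporation(profile, 5.0) == 0.0

    def test_supply_limited(self):
        # top layer holds 3 mm above wilting: theta = pwp + 3/(0.2*1000)
        profile = SoilProfile.default(theta=0.13 + 0.015)
        assert extract_evaporation(profile, 5.0) == pytest.approx(3.0)
        assert profile.layers[0].theta == pytest.approx(0.13)
        # deeper layers untouched
        assert profile.layers[1].theta == pytest.approx(0.145)

    def test_zero_demand(self):
        assert extract_evaporation(SoilProfile.default(), 0.0) == 0.0


class TestStressIndex:
    @pytest.mark.parametrize("t_act, t_pot, expected", [
        (4.0, 4.0, 0.0),
        (0.0, 4.0, 1.0),
        (2.0, 4.0, 0.5),
        (0.0, 0.0, 0.0),  # no demand, no stress
    ])
    def test_values(self, t_act, t_pot, expected):
        assert stress_index(t_act, t_pot) == pytest.approx(expected)

    def test_actual_exceeding_potential_rejected(self):
        with pytest.raises(InvalidInputError):
            stress_index(5.0, 4.0)


class TestIrrigationDecision:
    def test_rainfed_never_irrigates(self):
        profile = SoilProfile.default(theta=0.15)
        assert all(irrigation_decision(profile, "rainfed", d, 1.0) == 0.0
                   for d in range(30))

    def test_weekly_refill_matches_deficit(self):
        profile = SoilProfile.default(theta=0.22)
        assert irrigation_decision(profile, "weekly_refill", 14, 1.0) == \
            pytest.approx(50.0)

    def test_off_schedule_days_give_nothing(self):
        profile = SoilProfile.default(theta=0.22)
        assert irrigation_decision(profile, "weekly_refill", 8, 1.0) == 0.0

    def test_fortnightly_schedule(self):
        profile = SoilProfile.default(theta=0.22)
        applied = [irrigation_decision(profile, "fortnightly_refill", d, 1.0)
                   for d in range(29)]
        assert [d for d, a in enumerate(applied) if a > 0] == [14, 28]


class TestPrintedLedgerReplay:
    def test_seasonal_landrace_closure(self):
        season = load_fixture_tables().seasonal_balance
        row = season[season.variety == "kantana"].iloc[0]
        weekly = load_fixture_tables().weekly_balance
        block = weekly[weekly.variety == "kantana"]
        q_start, q_end = block.Qi.iloc[0], block.Qo.iloc[-1]
        et = et_from_balance(row.P, row.I, row.R, row.D, q_start, q_end)
        assert et == 670.0  # exact closure of the printed season

    def test_weekly_rows_close_within_rounding(self):
        weekly = load_fixture_tables().weekly_balance
        ok = 0
        for row in weekly.itertuples(index=False):
            et = et_from_balance(row.P, row.I, row.R, row.D, row.Qi, row.Qo)
            ok += abs(et - row.ET) <= 1.0
        assert ok / len(weekly) >= 0.90
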