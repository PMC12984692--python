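"""CO2 mass-balance estimator: analytic examples, properties, invertibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barnflux.massbalance as mb

HERD = mb.HerdState(n_cows=56, mass_kg=625.0, days_after_insemination=100.0,
                    milk_yield_kg_day=25.0)


def oracle_emissions(m, p, y, ti, n, co2_in, co2_out, gas_in, gas_out):
    """Straight-line re-implementation of the balance equations (test oracle)."""
    qt = 5.6 * m**0.75 + 1.6e-5 * p**3 + 22 * y
    cf = 4e-5 * (20 - ti) ** 3 + 1
    qcor = qt * cf
    p_co2 = 0.299 * qcor
    q = p_co2 * n / (co2_in - co2_out)
    et = q * (gas_in - gas_out)
    e = et * 500 / (n * m)
    return q, et, e


class TestHeatProduction:
    def test_hand_example(self):
        # 625^0.75 = 125 exactly: 5.6*125 + 1.6e-5*1e6 + 22*25 = 700+16+550
        assert mb.heat_production(HERD) == pytest.approx(1266.0, rel=1e-12)

    def test_vanishes_at_zero(self):
        h = mb.HerdState(1, 1e-9, 0.0, 0.0)
        assert mb.heat_production(h) == pytest.approx(0.0, abs=1e-6)

    def test_milk_yield_term_is_linear(self):
        h26 = mb.HerdState(56, 625.0, 100.0, 26.0)
        assert mb.heat_production(h26) - mb.heat_production(HERD) == pytest.approx(22.0)

    @given(
        m=st.floats(100, 1200), p=st.floats(0, 280), y=st.floats(0, 60),
        dm=st.floats(0.1, 100), dp=st.floats(0.1, 50), dy=st.floats(0.1, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_each_argument(self, m, p, y, dm, dp, dy):
        base = mb.heat_production(mb.HerdState(1, m, p, y))
        assert mb.heat_production(mb.HerdState(1, m + dm, p, y)) > base
        assert mb.heat_production(mb.HerdState(1, m, p + dp, y)) > base
        assert mb.heat_production(mb.HerdState(1, m, p, y + dy)) > base

    @pytest.mark.parametrize("bad", [dict(n_cows=0), dict(mass_kg=-5.0),
                                     dict(days_after_insemination=-1.0),
                                     dict(milk_yield_kg_day=-0.1)])
    def test_invalid_herd_rejected(self, bad):
        kwargs = dict(n_cows=56, mass_kg=625.0, days_after_insemination=100.0,
                      milk_yield_kg_day=25.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            mb.HerdState(**kwargs)


class TestTemperatureCorrection:
    @pytest.mark.parametrize("ti, cf", [(20.0, 1.0), (10.0, 1.04), (30.0, 0.96)])
    def test_point_values(self, ti, cf):
        assert mb.temperature_correction(ti) == pytest.approx(cf, rel=1e-12)

    @given(ti=st.floats(-20, 45), dt=st.floats(0.01, 30))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing(self, ti, dt):
        assert mb.temperature_correction(ti + dt) <= mb.temperature_correction(ti)


class TestCO2Excretion:
    def test_chained_example(self):
        qcor, p_co2 = mb.co2_excretion_rate(HERD, 10.0)
        assert qcor == pytest.approx(1266.0 * 1.04, rel=1e-12)
        assert p_co2 == pytest.approx(0.299 * 1266.0 * 1.04, rel=1e-12)
        assert p_co2 == pytest.approx(393.68, abs=0.01)

    def test_reference_temperature_is_neutral(self):
        qcor, _ = mb.co2_excretion_rate(HERD, 20.0)
        assert qcor == pytest.approx(mb.heat_production(HERD), rel=1e-14)

    @given(ti=st.floats(-10, 40))
    @settings(max_examples=30, deadline=None)
    def test_fixed_excretion_ratio(self, ti):
        qcor, p_co2 = mb.co2_excretion_rate(HERD, ti)
        assert p_co2 / qcor == pytest.approx(0.299, rel=1e-12)


class TestVentilationAndEmission:
    def test_hand_example(self):
        q, flag = mb.ventilation_rate(393.68, 56, 1.5, 0.87)
        assert flag is mb.EmissionFlag.OK
        assert q == pytest.approx(393.68 * 56 / 0.63, rel=1e-12)
        assert q == pytest.approx(34994, rel=1e-3)

    def test_zero_gradient_flagged_not_raised(self):
        q, flag = mb.ventilation_rate(393.68, 56, 1.0, 1.0)
        assert flag is mb.EmissionFlag.INVALID_GRADIENT
        assert np.isnan(q)

    def test_linear_in_herd_size(self):
        q1, _ = mb.ventilation_rate(400.0, 28, 1.5, 0.9)
        q2, _ = mb.ventilation_rate(400.0, 56, 1.5, 0.9)
        assert q2 == pytest.approx(2 * q1, rel=1e-14)

    def test_emission_rate_example_and_linearity(self):
        q = 34994.0
        assert mb.emission_rate(q, 3e-4, 1e-4) == pytest.approx(q * 2e-4, rel=1e-14)
        assert mb.emission_rate(q, 1.0, 1.0) == 0.0
        assert mb.emission_rate(q, 5e-4, 1e-4) == pytest.approx(
            2 * mb.emission_rate(q, 3e-4, 1e-4), rel=1e-14
        )

    def test_per_lu_normalization(self):
        assert mb.emission_per_lu(7.0, HERD) == pytest.approx(7.0 * 500 / 35000, rel=1e-14)
        h500 = mb.HerdState(10, 500.0, 0.0, 0.0)
        assert mb.emission_per_lu(3.0, h500) == pytest.approx(0.3, rel=1e-14)
        assert mb.emission_per_lu(0.0, HERD) == 0.0


class TestUnitConversion:
    def test_zero_maps_to_zero(self):
        assert mb.ppm_to_mass_concentration(0.0, "CO2") == 0.0

    def test_molar_volume_oracle_at_standard_conditions(self):
        got = mb.ppm_to_mass_concentration(1.0, "CO2", temp_c=0.0, pressure_kpa=101.325)
        assert got == pytest.approx(44.010e-3 / 22.414, rel=1e-4)

    @pytest.mark.parametrize("gas", ["NH3", "CH4", "CO2"])
    def test_round_trip_is_identity(self, gas, rng):
        c = rng.uniform(0.01, 1000, size=50)
        t = rng.uniform(-5, 35, size=50)
        back = mb.mass_concentration_to_ppm(
            mb.ppm_to_mass_concentration(c, gas, t), gas, t
        )
        np.testing.assert_allclose(back, c, rtol=1e-12)

    def test_unknown_gas_rejected(self):
        with pytest.raises(ValueError, match="unknown gas"):
            mb.ppm_to_mass_concentration(1.0, "N2O")


class TestSeriesEstimation:
    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(100):
            m = rng.uniform(300, 900)
            p = rng.uniform(0, 250)
            y = rng.uniform(0, 50)
            ti = rng.uniform(-5, 35)
            n = int(rng.integers(1, 200))
            co2_out = rng.uniform(0.5, 1.0)
            co2_in = co2_out + rng.uniform(0.05, 1.5)
            gas_out = rng.uniform(1e-5, 1e-3)
            gas_in = gas_out + rng.uniform(1e-5, 5e-3)
            herd = mb.HerdState(n, m, p, y)
            qcor, p_co2 = mb.co2_excretion_rate(herd, ti)
            q, flag = mb.ventilation_rate(p_co2, n, co2_in, co2_out)
            et = mb.emission_rate(q, gas_in, gas_out)
            e = mb.emission_per_lu(et, herd)
            qo, eto, eo = oracle_emissions(m, p, y, ti, n, co2_in, co2_out, gas_in, gas_out)
            assert flag is mb.EmissionFlag.OK
            assert q == pytest.approx(qo, rel=1e-12)
            assert et == pytest.approx(eto, rel=1e-12)
            assert e == pytest.approx(eo, rel=1e-12)

    def test_noiseless_study_recovered_exactly(self, noiseless_study):
        s = noiseless_study
        for gas in ("NH3", "CH4"):
            table = mb.estimate_emissions_series(s.records, s.config.herd, gas=gas)
            np.testing.assert_allclose(
                table["Q"], s.truth["Q_true"], rtol=1e-9
            )
            np.testing.assert_allclose(
                table["Et"], s.truth[f"E_{gas}_true"], rtol=1e-9
            )
            assert (table["flag"] == "ok").all()

    def test_invalid_hour_is_isolated(self, noiseless_study):
        records = noiseless_study.records.copy()
        records.loc[5, "C_CO2_in"] = records.loc[5, "C_CO2_out"]  # kill the gradient
        table = mb.estimate_emissions_series(records, noiseless_study.config.herd)
        assert table.loc[5, "flag"] == "invalid_gradient"
        assert (table.drop(index=5)["flag"] == "ok").all()

    def test_constant_inputs_give_identical_estimates(self):
        row = dict(T_in=15.0, C_CO2_in=900.0, C_CO2_out=420.0,
                   C_NH3_in=1.0, C_NH3_out=0.25)
        records = pd.DataFrame([row] * 10)
        table = mb.estimate_emissions_series(records, HERD)
        assert table["Q"].nunique() == 1 and table["Et"].nunique() == 1

    def test_indoor_sampling_points_are_averaged(self):
        base = dict(T_in=15.0, C_CO2_out=420.0, C_NH3_out=0.25)
        multi = pd.DataFrame([{**base, "C_CO2_in_1": 880.0, "C_CO2_in_2": 920.0,
                               "C_NH3_in_1": 0.8, "C_NH3_in_2": 1.2}])
        single = pd.DataFrame([{**base, "C_CO2_in": 900.0, "C_NH3_in": 1.0}])
        t_multi = mb.estimate_emissions_series(multi, HERD)
        t_single = mb.estimate_emissions_series(single, HERD)
        assert t_multi["Et"].iloc[0] == pytest.approx(t_single["Et"].iloc[0], rel=1e-12)

    def test_missing_columns_reported_by_name(self):
        records = pd.DataFrame({"T_in": [15.0], "C_CO2_in": [900.0]})
        with pytest.raises(KeyError, match="C_CO2_out"):
            mb.MassBalanceModel(records, HERD)

    def test_negative_policy_zero_and_drop(self):
        rows = pd.DataFrame({
            "T_in": [15.0, 15.0],
            "C_CO2_in": [900.0, 900.0], "C_CO2_out": [420.0, 420.0],
            "C_NH3_in": [0.2, 1.0], "C_NH3_out": [0.5, 0.25],
        })
        kept = mb.estimate_emissions_series(rows, HERD)
        assert kept.loc[0, "flag"] == "negative_emission" and kept.loc[0, "Et"] < 0
        zeroed = mb.estimate_emissions_series(rows, HERD, negative_policy="zero")
        assert zeroed.loc[0, "Et"] == 0.0
        dropped = mb.estimate_emissions_series(rows, HERD, negative_policy="drop")
        assert len(dropped) == 1

    def test_conservation_recheckable_from_stored_fields(self, tiny_study):
        s = tiny_study
        table = mb.estimate_emissions_series(s.records, s.config.herd, gas="CH4")
        # Et = Q * gradient and E = Et*500/(N*m) must hold exactly per row
        herd = s.config.herd
        np.testing.assert_allclose(
            table["E"], table["Et"] * 500 / (herd.n_cows * herd.mass_kg), rtol=1e-12
        )
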