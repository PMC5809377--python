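"""Subtraction vs attribution sector apportionment."""

import numpy as np
import pandas as pd
import pytest

from pm25burden.apportion import (
    apportion_all,
    attribution_method,
    subtraction_method,
    table_attribution,
)
from pm25burden.burden import compute_burden, total_burden
from pm25burden.exposure import SECTORS, ScenarioSet, round_half_up
from pm25burden.grids import GridSpec
from pm25burden.synthetic import (
    SyntheticConfig,
    gen_pm25_control,
    gen_population,
    gen_sector_off_fields,
)

from .conftest import uniform_field


class TestSubtraction:
    def test_difference(self):
        assert subtraction_method(100.0, 60.0) == pytest.approx(40.0)

    def test_zero_when_equal(self):
        assert subtraction_method(100.0, 100.0) == 0.0

    def test_tiny_negative_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            assert subtraction_method(100.0, 100.0 + 1e-10) == 0.0

    def test_large_negative_rejected(self):
        with pytest.raises(ValueError):
            subtraction_method(100.0, 150.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subtraction_method(-1.0, 0.0)


class TestAttribution:
    def test_residential_aggregate_arithmetic(self):
        m = attribution_method(990_000, 57.2, 57.2 - 29.5)
        assert round_half_up(m / 1000) == 511

    def test_energy_aggregate_arithmetic(self):
        m = attribution_method(990_000, 57.2, 57.2 - 12.0)
        assert round_half_up(m / 1000) == 208

    def test_zero_reduction(self):
        assert attribution_method(990_000, 57.2, 57.2) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            attribution_method(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            attribution_method(1.0, 10.0, 11.0)


def _pipeline_inputs(spec, cfg, total_pop, ages, bm, ens, lt):
    control, _ = gen_pm25_control(spec, cfg)
    scen = gen_sector_off_fields(control, cfg)
    pop = gen_population(spec, total_pop, cfg)
    return scen, pop


class TestApportionAll:
    def test_identical_scenarios_give_zero(self, spec10, population, ages,
                                           baseline_mortality, ensemble,
                                           life_table):
        control = uniform_field(spec10, 60.0)
        scen = ScenarioSet(control=control,
                           sector_off={s: control for s in SECTORS})
        table = apportion_all(scen, population, ages, baseline_mortality,
                              ensemble, life_table)
        body = table[table["sector"] != "TOTAL"]
        assert np.allclose(body["m_subtraction"], 0.0)
        assert np.allclose(body["m_attribution"], 0.0)

    def test_attribution_sum_identity(self, ages, baseline_mortality,
                                      ensemble, life_table):
        spec = GridSpec(n_lat=12, n_lon=12)
        cfg = SyntheticConfig(seed=5)
        scen, pop = _pipeline_inputs(spec, cfg, 2_000_000, ages,
                                     baseline_mortality, ensemble, life_table)
        table = apportion_all(scen, pop, ages, baseline_mortality, ensemble,
                              life_table)
        body = table[table["sector"] != "TOTAL"]
        m_all = table.attrs["m_all"]
        np.testing.assert_allclose(
            body["m_attribution"].sum(),
            m_all * body["pm_fraction"].sum(),
            rtol=1e-12,
        )

    def test_subtraction_matches_definitional_oracle(self, ages,
                                                     baseline_mortality,
                                                     ensemble, life_table):
        spec = GridSpec(n_lat=8, n_lon=8)
        cfg = SyntheticConfig(seed=6)
        scen, pop = _pipeline_inputs(spec, cfg, 1_000_000, ages,
                                     baseline_mortality, ensemble, life_table)
        table = apportion_all(scen, pop, ages, baseline_mortality, ensemble,
                              life_table)
        bt_all = compute_burden(scen.control, pop, ages, baseline_mortality,
                                ensemble, life_table, urban_split=False)
        bt_res = compute_burden(scen.sector_off["RES"], pop, ages,
                                baseline_mortality, ensemble, life_table,
                                urban_split=False)
        expected = total_burden(bt_all) - total_burden(bt_res)
        got = float(table.set_index("sector").loc["RES", "m_subtraction"])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_methods_agree_in_near_linear_regime(self, population, ages,
                                                 baseline_mortality,
                                                 life_table, spec10):
        # RR - 1 << 1 with gamma=1 keeps the attributable fraction linear
        # through the origin (no saturation, negligible TMREL offset), so
        # attribution ~ subtraction
        rows = []
        for disease in ("ALRI", "IHD", "CEV", "COPD", "LC"):
            for i in range(4):
                rows.append(
                    {"disease": disease, "age_group": "ALL", "draw": i,
                     "alpha": 5.0, "beta": 2e-5, "gamma": 1.0, "tmrel": 2.4}
                )
        from pm25burden.ier import IERParameterEnsemble

        ens = IERParameterEnsemble(pd.DataFrame(rows))
        control = uniform_field(spec10, 150.0)
        off = {}
        fractions = {"AGR": 0.01, "BBU": 0.03, "DUS": 0.01, "ENE": 0.2,
                     "IND": 0.15, "RES": 0.4, "TRA": 0.1}
        for s in SECTORS:
            off[s] = uniform_field(spec10, 150.0 * (1 - fractions[s]))
        scen = ScenarioSet(control=control, sector_off=off)
        table = apportion_all(scen, population, ages, baseline_mortality,
                              ens, life_table)
        body = table[table["sector"] != "TOTAL"]
        ratio = body["m_attribution"] / body["m_subtraction"]
        assert ((ratio - 1).abs() < 0.05).all()

    def test_saturating_regime_attribution_dominates(self, ages,
                                                     baseline_mortality,
                                                     life_table):
        # default IER medians saturate above ~50 ug/m3; at the polluted-band
        # concentrations the attribution estimate exceeds subtraction by
        # roughly a factor of 2 for the major sectors
        from pm25burden.synthetic import gen_ier_parameters

        spec = GridSpec(n_lat=30, n_lon=30)
        cfg = SyntheticConfig(seed=9)
        ens = gen_ier_parameters(n_draws=200, seed=9)
        scen, pop = _pipeline_inputs(spec, cfg, 5_000_000, ages,
                                     baseline_mortality, ens, life_table)
        table = apportion_all(scen, pop, ages, baseline_mortality, ens,
                              life_table).set_index("sector")
        for sector in ("ENE", "IND", "RES", "TRA"):
            ratio = table.loc[sector, "m_attribution"] / table.loc[
                sector, "m_subtraction"]
            assert ratio > 1.5, sector
        res_ratio = table.loc["RES", "m_attribution"] / table.loc[
            "RES", "m_subtraction"]
        assert 1.5 < res_ratio < 4.0


class TestTableArithmetic:
    def test_printed_sector_mortalities(self):
        reductions = {"RES": 29.5, "ENE": 12.0, "IND": 9.3, "TRA": 5.9,
                      "BBU": 1.6, "AGR": 0.2}
        table = table_attribution(990_000, 57.2, reductions).set_index("sector")
        assert table["mortality_thousands"].to_dict() == {
            "RES": 511, "ENE": 208, "IND": 161, "TRA": 102, "BBU": 28, "AGR": 3
        }

    def test_printed_percent_contributions(self):
        reductions = {"RES": 29.5, "ENE": 12.0, "IND": 9.3, "TRA": 5.9,
                      "BBU": 1.6, "AGR": 0.2}
        table = table_attribution(990_000, 57.2, reductions).set_index("sector")
        assert table["percent"].to_dict() == {
            "RES": 52, "ENE": 21, "IND": 16, "TRA": 10, "BBU": 3, "AGR": 0
        }
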