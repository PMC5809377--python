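"""Mortality/YLL arithmetic and aggregation contracts."""

import numpy as np
import pandas as pd
import pytest

from pm25burden.burden import (
    AgeStructure,
    LifeTable,
    apply_state_scaling,
    attributable_fraction,
    classify_urban,
    compute_burden,
    disease_age_groups,
    mortality_cell,
    total_burden,
    yll_from_mortality,
)
from pm25burden.grids import GriddedField, GridSpec
from pm25burden.ier import DISEASES
from pm25burden.synthetic import gen_pm25_control, gen_population, SyntheticConfig


class TestMortalityCell:
    def test_closed_form(self):
        assert mortality_cell(1000, 0.01, 2.0) == pytest.approx(5.0)

    def test_zero_at_unit_rr(self):
        assert mortality_cell(1000, 0.01, 1.0) == 0.0

    def test_limit_is_baseline_deaths(self):
        assert mortality_cell(1000, 0.01, 1e12) == pytest.approx(10.0, rel=1e-9)

    def test_monotone_in_rr(self):
        values = [mortality_cell(100, 0.02, rr) for rr in (1.0, 1.5, 2.0, 5.0)]
        assert values == sorted(values)
        assert all(v < 100 * 0.02 for v in values[1:] + [values[-1]])

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            mortality_cell(1000, 0.01, 0.99)


def test_attributable_fraction_identity():
    rr = np.array([1.0, 1.3, 2.0, 10.0])
    np.testing.assert_allclose(attributable_fraction(rr), (rr - 1) / rr, rtol=1e-15)


class TestComputeBurden:
    def test_zero_below_tmrel(self, population, ages, baseline_mortality,
                              ensemble, life_table):
        spec = population.spec
        conc = GriddedField(np.full(spec.shape, 2.0), spec)
        bt = compute_burden(conc, population, ages, baseline_mortality,
                            ensemble, life_table)
        assert total_burden(bt) == 0.0

    def test_matches_brute_force_triple_loop(self, ages, baseline_mortality,
                                             ensemble, life_table):
        spec = GridSpec(n_lat=20, n_lon=20)
        cfg = SyntheticConfig(seed=13)
        conc, _ = gen_pm25_control(spec, cfg)
        pop = gen_population(spec, 5_000_000, cfg)

        bt = compute_burden(conc, pop, ages, baseline_mortality, ensemble,
                            life_table, urban_split=False)
        total = total_burden(bt)

        # brute-force oracle: explicit loop over cells, diseases, ages with
        # scalar IER evaluation per draw
        from pm25burden.ier import relative_risk

        expected = 0.0
        bm = baseline_mortality
        rr_cache: dict[tuple, list] = {}
        for disease in DISEASES:
            for age_group in disease_age_groups(disease):
                key = age_group if (disease, age_group) in ensemble._groups else "ALL"
                if (disease, key) not in rr_cache:
                    draws = ensemble.draws_for(disease, key)
                    rr_cache[(disease, key)] = [
                        np.mean([relative_risk(float(c), d) for d in draws])
                        for c in conc.values.ravel()
                    ]
                rr_means = rr_cache[(disease, key)]
                rate = float(
                    bm[(bm["disease"] == disease)
                       & (bm["age_group"] == age_group)]["mean"].iloc[0]
                )
                frac = ages.fraction(age_group)
                for rr_mean, p in zip(rr_means, pop.values.ravel()):
                    expected += mortality_cell(p * frac, rate, rr_mean)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_single_cell_reduces_to_mortality_cell(self, baseline_mortality,
                                                   ensemble, life_table):
        spec = GridSpec(n_lat=1, n_lon=1)
        conc = GriddedField(np.array([[80.0]]), spec)
        pop = GriddedField(np.array([[10000.0]]), spec)
        groups = disease_age_groups("COPD")
        fractions = np.zeros(len(groups))
        fractions[groups.index("60-64")] = 1.0
        ages = AgeStructure(groups=groups, fractions=fractions)
        bt = compute_burden(conc, pop, ages, baseline_mortality, ensemble,
                            life_table, urban_split=False, diseases=("COPD",))
        bm = baseline_mortality
        rate = float(
            bm[(bm["disease"] == "COPD") & (bm["age_group"] == "60-64")]["mean"].iloc[0]
        )
        rr = float(ensemble.mean_rr(np.array([80.0]), "COPD", "ALL")[0])
        assert total_burden(bt) == pytest.approx(mortality_cell(10000, rate, rr))

    def test_additive_over_disjoint_regions(self, control, population, ages,
                                            baseline_mortality, ensemble,
                                            life_table):
        shape = control.shape
        left = np.zeros(shape, dtype=bool)
        left[:, : shape[1] // 2] = True
        masks = {"west": left, "east": ~left}
        bt = compute_burden(control, population, ages, baseline_mortality,
                            ensemble, life_table, region_masks=masks,
                            urban_split=False)
        national = total_burden(bt, region="India")
        split = total_burden(bt, region="west") + total_burden(bt, region="east")
        assert split == pytest.approx(national, rel=1e-12)

    def test_urban_rural_partition(self, control, population, ages,
                                   baseline_mortality, ensemble, life_table):
        bt = compute_burden(control, population, ages, baseline_mortality,
                            ensemble, life_table)
        total = total_burden(bt, klass="total")
        parts = total_burden(bt, klass="urban") + total_burden(bt, klass="rural")
        assert parts == pytest.approx(total, rel=1e-12)

    def test_monotone_in_concentration(self, control, population, ages,
                                       baseline_mortality, ensemble, life_table):
        bt0 = compute_burden(control, population, ages, baseline_mortality,
                             ensemble, life_table, urban_split=False)
        bumped = control.copy_with(control.values + 20.0)
        bt1 = compute_burden(bumped, population, ages, baseline_mortality,
                             ensemble, life_table, urban_split=False)
        assert total_burden(bt1) >= total_burden(bt0)

    def test_stratum_bounds_ordering(self, control, population, ages,
                                     baseline_mortality, ensemble, life_table):
        bt = compute_burden(control, population, ages, baseline_mortality,
                            ensemble, life_table)
        assert (bt["mortality_lower"] <= bt["mortality_mean"]).all()
        assert (bt["mortality_mean"] <= bt["mortality_upper"]).all()


class TestUrbanClassification:
    def test_density_threshold_is_inclusive(self):
        spec = GridSpec(n_lat=1, n_lon=2)
        areas = spec.cell_areas()
        pop = GriddedField(
            np.array([[399.9 * areas[0, 0], 400.0 * areas[0, 1]]]), spec
        )
        urban = classify_urban(pop)
        assert not urban[0, 0] and urban[0, 1]

    def test_zero_population_is_rural(self, spec10):
        pop = GriddedField(np.zeros(spec10.shape), spec10)
        assert not classify_urban(pop).any()


class TestStateScaling:
    def test_identity_ratios(self, baseline_mortality):
        scaled = apply_state_scaling(baseline_mortality, {"A": 1.0})["A"]
        pd.testing.assert_frame_equal(scaled, baseline_mortality)

    def test_ratio_two_doubles_scaled_diseases_only(self, baseline_mortality):
        scaled = apply_state_scaling(baseline_mortality, {"A": 2.0})["A"]
        for disease in ("COPD", "IHD", "CEV"):
            before = baseline_mortality[baseline_mortality["disease"] == disease]
            after = scaled[scaled["disease"] == disease]
            np.testing.assert_allclose(
                after[["mean", "lower", "upper"]], 2 * before[["mean", "lower", "upper"]]
            )
        for disease in ("LC", "ALRI"):
            before = baseline_mortality[baseline_mortality["disease"] == disease]
            after = scaled[scaled["disease"] == disease]
            np.testing.assert_array_equal(
                after[["mean", "lower", "upper"]], before[["mean", "lower", "upper"]]
            )


class TestYLL:
    def test_stratum_identity(self, control, population, ages,
                              baseline_mortality, ensemble, life_table):
        bt = compute_burden(control, population, ages, baseline_mortality,
                            ensemble, life_table, urban_split=False)
        le = bt["age_group"].map(life_table.le)
        np.testing.assert_allclose(bt["yll_mean"], bt["mortality_mean"] * le)

    def test_linear_in_life_expectancy(self, control, population, ages,
                                       baseline_mortality, ensemble, life_table):
        bt = compute_burden(control, population, ages, baseline_mortality,
                            ensemble, life_table, urban_split=False)
        frame = life_table.to_frame()
        halved = LifeTable(dict(zip(frame["age_group"], 0.5 * frame["le_remaining"])))
        bt_half = yll_from_mortality(bt, halved)
        np.testing.assert_allclose(bt_half["yll_mean"], 0.5 * bt["yll_mean"])

    def test_scalar_example(self, life_table):
        bt = pd.DataFrame(
            [{"disease": "COPD", "age_group": "60-64", "region": "India",
              "class": "total", "mortality_mean": 10.0, "mortality_lower": 10.0,
              "mortality_upper": 10.0}]
        )
        frame = LifeTable({"60-64": 20.0})
        out = yll_from_mortality(bt, frame)
        assert out["yll_mean"].iloc[0] == pytest.approx(200.0)


class TestContainers:
    def test_age_structure_validation(self):
        with pytest.raises(ValueError):
            AgeStructure(groups=("a", "b"), fractions=[0.6, 0.5])
        with pytest.raises(ValueError):
            AgeStructure(groups=("a", "b"), fractions=[1.2, -0.2])

    def test_life_table_must_decrease(self):
        with pytest.raises(ValueError):
            LifeTable({"25-29": 50.0, "30-34": 55.0})
        with pytest.raises(ValueError):
            LifeTable({"25-29": -1.0})
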