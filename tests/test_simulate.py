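"""Synthetic-survey generator: determinism, recovery of known truths."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from reefseed import annual_recruit_density, classify_maturity, mean_quadrat_density
from reefseed.io import HabitatSpec, SamplerSpec
from reefseed.moorea import default_params
from reefseed.reproduction import fit_allometry
from reefseed.simulate import (HabitatYearTruth, SimulationScenario,
                               default_scenario, simulate_allometry_pairs,
                               simulate_colony_sizes, simulate_point_counts,
                               simulate_quadrats, simulate_survey, simulate_tiles)

H = (HabitatSpec("reef", 1.0),)


def _scen(truth, seed=1, **kw):
    return SimulationScenario(seed=seed, habitats=H, truths=(truth,), **kw)


class TestTiles:
    def test_zero_density_all_zero(self):
        t = HabitatYearTruth("reef", 2010, recruit_density_per_period={"early": 0.0, "late": 0.0},
                             juvenile_density=0, colony_density=0)
        assert all(r.recruit_count == 0 for r in simulate_tiles(_scen(t)))

    def test_same_seed_identical_records(self):
        t = HabitatYearTruth("reef", 2010)
        assert simulate_tiles(_scen(t, seed=4)) == simulate_tiles(_scen(t, seed=4))
        assert simulate_tiles(_scen(t, seed=4)) != simulate_tiles(_scen(t, seed=5))

    def test_poisson_recovery_of_annual_density(self, sampler):
        """200 tiles at summed truth 3.29 per tile-year: the estimate lands
        within 3 SE of the truth."""
        t = HabitatYearTruth("reef", 2010,
                             recruit_density_per_period={"early": 0.57, "late": 2.72},
                             juvenile_density=0, colony_density=0,
                             sites=("s1",), n_tiles=200)
        est = annual_recruit_density(simulate_tiles(_scen(t, seed=2)), sampler)
        se = np.sqrt(3.29 / 200)
        assert abs(est.density - 3.29) < 3 * se


class TestQuadrats:
    def test_juveniles_nested_within_colonies(self):
        t = HabitatYearTruth("reef", 2014, juvenile_density=4.75, colony_density=9.08,
                             n_quadrats=100)
        recs = simulate_quadrats(_scen(t))
        by_quad = {}
        for r in recs:
            by_quad.setdefault(r.quadrat_id, {})[r.life_stage] = r.colony_count
        assert by_quad and all(v["juvenile"] <= v["all"] for v in by_quad.values())

    def test_recovery_within_3se(self, sampler):
        t = HabitatYearTruth("reef", 2014, juvenile_density=0.4, colony_density=0.8,
                             sites=("s1",), n_quadrats=300)
        recs = [r for r in simulate_quadrats(_scen(t, seed=6)) if r.life_stage == "all"]
        est = mean_quadrat_density(recs, sampler)
        se = np.sqrt(0.8 / 300)
        assert abs(est.density - 0.8) < 3 * se

    def test_juvenile_truth_above_colony_truth_rejected(self):
        with pytest.raises(ValueError, match="juvenile"):
            HabitatYearTruth("reef", 2014, juvenile_density=2.0, colony_density=1.0)

    def test_zero_effort_rejected(self):
        t = HabitatYearTruth("reef", 2014, n_quadrats=0)
        with pytest.raises(ValueError, match="effort"):
            _scen(t)


class TestColonySizes:
    def test_mature_fraction_matches_lognormal_tail(self, params):
        """Closed-form oracle: P(D ≥ 14) for a lognormal(median 5, σ 0.5)."""
        t = HabitatYearTruth("reef", 2014, size_median_cm=5.0, size_log_sd=0.5,
                             n_colonies=4000)
        recs = simulate_colony_sizes(_scen(t, seed=8))
        p_true = stats.norm.sf((np.log(14) - np.log(5)) / 0.5)
        assert t.mature_fraction(14.0) == pytest.approx(p_true)
        summary = classify_maturity(recs, params)
        se = np.sqrt(p_true * (1 - p_true) / 4000)
        assert abs(summary.prop_mature - p_true) < 3 * se

    def test_degenerate_distribution_exact_diameter(self, params):
        t = HabitatYearTruth("reef", 2014, size_median_cm=22.3, size_log_sd=0.0,
                             n_colonies=50)
        summary = classify_maturity(simulate_colony_sizes(_scen(t)), params)
        assert summary.prop_mature == 1.0
        assert summary.mean_mature_diameter_cm == pytest.approx(22.3)

    def test_zero_colonies_empty_with_warning(self, caplog):
        t = HabitatYearTruth("reef", 2014, n_colonies=0)
        with caplog.at_level("WARNING", logger="reefseed.simulate"):
            recs = simulate_colony_sizes(_scen(t))
        assert recs == [] and "zero colony sizes" in caplog.text


class TestPointCounts:
    def test_saturated_cover_all_points_in_category(self):
        t = HabitatYearTruth("reef", 2010, cover={"coral": 1.0}, n_images=3)
        for r in simulate_point_counts(_scen(t)):
            assert r.label_counts == {"coral": 200}

    def test_counts_conserve_points_per_image(self, sampler):
        t = HabitatYearTruth("reef", 2010, cover={"a": 0.3, "b": 0.2}, n_images=10)
        for r in simulate_point_counts(_scen(t)):
            assert r.total_points() == sampler.points_per_image


class TestAllometryPairs:
    def test_zero_noise_exact_fit(self):
        scen = SimulationScenario(seed=1, habitats=H, truths=(),
                                  allometry_noise_log_sd=0.0)
        fit = fit_allometry(simulate_allometry_pairs(scen))
        assert fit.coefficient_a == pytest.approx(2.493, rel=1e-9)
        assert fit.exponent_b == pytest.approx(2.312, rel=1e-9)

    def test_r2_decreases_with_noise(self):
        r2 = []
        for sd in (0.02, 0.1, 0.4):
            vals = []
            for seed in range(5):
                scen = SimulationScenario(seed=seed, habitats=H, truths=(),
                                          allometry_noise_log_sd=sd,
                                          n_allometry_pairs=80)
                vals.append(fit_allometry(simulate_allometry_pairs(scen)).r_squared)
            r2.append(np.mean(vals))
        assert r2[0] > r2[1] > r2[2]


def test_overdispersed_counts_have_larger_variance():
    t = HabitatYearTruth("reef", 2010,
                         recruit_density_per_period={"early": 0.0, "late": 3.0},
                         juvenile_density=0, colony_density=0,
                         sites=("s1",), n_tiles=2000)
    poisson = [r.recruit_count for r in simulate_tiles(_scen(t, seed=3))
               if r.period == "late"]
    nb = [r.recruit_count for r in simulate_tiles(_scen(t, seed=3, overdispersion=1.0))
          if r.period == "late"]
    assert np.mean(nb) == pytest.approx(3.0, abs=0.3)
    assert np.var(nb) > 1.5 * np.var(poisson)


def test_full_survey_is_valid_and_reproducible():
    ds1 = simulate_survey(default_scenario(seed=12))
    ds2 = simulate_survey(default_scenario(seed=12))
    assert ds1.tiles == ds2.tiles and ds1.points == ds2.points
    assert ds1.validate() is ds1
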