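"""Maturity, allometry, fecundity pooling, egg/zygote chains."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefseed import (classify_maturity, colony_egg_output, fit_allometry,
                      pooled_fecundity, pooled_fertilization,
                      population_egg_output, tissue_area, zygote_production)
from reefseed.abundance import AbundanceEstimate
from reefseed.io import ColonyRecord
from reefseed.moorea import ALLOMETRY, FECUNDITY_STUDIES
from reefseed.reproduction import FecundityStudy, MaturitySummary
from reefseed.simulate import SimulationScenario, simulate_allometry_pairs
from reefseed.io import HabitatSpec


def _colonies(diams):
    return [ColonyRecord("s", "h", 2014, d) for d in diams]


class TestMaturity:
    def test_threshold_is_inclusive(self, params):
        s = classify_maturity(_colonies([14.0, 22.0]), params)
        assert s.n_mature == 2
        assert s.mean_mature_diameter_cm == pytest.approx(18.0)

    def test_proportion_mature(self, params):
        diams = [20.0] * 19 + [5.0] * 172  # 19 of 191 at/above threshold
        s = classify_maturity(_colonies(diams), params)
        assert s.prop_mature == pytest.approx(19 / 191)

    def test_no_mature_colonies(self, params):
        s = classify_maturity(_colonies([3.0, 5.0]), params)
        assert s.prop_mature == 0.0
        assert math.isnan(s.mean_mature_diameter_cm)

    def test_empty_list_rejected(self, params):
        with pytest.raises(ValueError):
            classify_maturity([], params)


class TestAllometry:
    def test_unit_diameter_isolates_coefficient(self):
        assert tissue_area(1.0, ALLOMETRY) == pytest.approx(2.493)

    @pytest.mark.parametrize("d,expected", [(22.3, 3266.0), (17.1, 1768.0)])
    def test_power_law_evaluation(self, d, expected):
        # oracle: direct power-law evaluation 2.493 * d**2.312
        assert tissue_area(d, ALLOMETRY) == pytest.approx(2.493 * d**2.312)
        assert tissue_area(d, ALLOMETRY) == pytest.approx(expected, rel=2e-3)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            tissue_area(0.0, ALLOMETRY)

    def test_exact_recovery_on_noise_free_data(self):
        d = np.array([3.0, 7.5, 12.0, 21.0, 30.0])
        pairs = [(x, 2.493 * x**2.312) for x in d]
        fit = fit_allometry(pairs)
        assert fit.coefficient_a == pytest.approx(2.493, rel=1e-9)
        assert fit.exponent_b == pytest.approx(2.312, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_consistency(self):
        two = [(5.0, 2.493 * 5**2.312), (20.0, 2.493 * 20**2.312)]
        mid_d = math.exp((math.log(5) + math.log(20)) / 2)
        three = two + [(mid_d, 2.493 * mid_d**2.312)]
        f3 = fit_allometry(three)
        assert f3.exponent_b == pytest.approx(2.312, rel=1e-9)

    def test_noisy_recovery_within_fitted_ci(self):
        """Lognormal multiplicative noise (σ_log = 0.1, n = 50): the true
        exponent lies inside the fitted 95 % interval."""
        scen = SimulationScenario(seed=9, habitats=(HabitatSpec("h", 1.0),),
                                  truths=(), allometry_noise_log_sd=0.1,
                                  n_allometry_pairs=50)
        fit = fit_allometry(simulate_allometry_pairs(scen))
        lo, hi = fit.exponent_ci
        assert lo <= 2.312 <= hi
        assert fit.r_squared < 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_allometry([(1.0, 2.0), (2.0, 10.0)])


class TestFecundityPooling:
    def test_published_studies_pool_to_6327_1882(self):
        """{7300 cm⁻²; 63 and 114 polyp⁻¹} × 66 polyps cm⁻² → 6327 ± 1882."""
        dist = pooled_fecundity(FECUNDITY_STUDIES, 66.0)
        assert dist.mean == pytest.approx(6327.33, abs=0.01)
        assert dist.sd == pytest.approx(1882.0, abs=0.5)
        assert dist.n_studies == 3

    def test_identical_studies_have_zero_sd(self):
        studies = [FecundityStudy(f"s{i}", 100.0, "eggs_per_polyp") for i in range(3)]
        assert pooled_fecundity(studies, 66.0).sd == 0.0

    def test_single_study_sd_undefined(self):
        (dist,) = [pooled_fecundity([FECUNDITY_STUDIES[0]], 66.0)]
        assert dist.mean == 7300.0
        assert not dist.sd_defined

    @given(st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=2, max_size=8),
           st.floats(min_value=1.0, max_value=100.0))
    def test_matches_brute_force_mean_sd(self, values, polyps):
        """Pooling equals a direct mean/SD over the converted values."""
        studies = [FecundityStudy(f"s{i}", v, "eggs_per_polyp")
                   for i, v in enumerate(values)]
        dist = pooled_fecundity(studies, polyps)
        conv = np.array(values) * polyps
        assert dist.mean == pytest.approx(conv.mean(), rel=1e-12)
        assert dist.sd == pytest.approx(conv.std(ddof=1), rel=1e-9, abs=1e-9)


class TestFertilizationPooling:
    def test_mean_and_sd_over_fractions(self):
        dist = pooled_fertilization([0.0, 1.0])
        assert dist.mean == pytest.approx(0.5)

    def test_equal_observations_zero_sd(self):
        assert pooled_fertilization([0.15, 0.15, 0.15]).sd == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pooled_fertilization([0.5, 1.2])


class TestEggChains:
    @pytest.mark.parametrize("d,expected", [
        (22.3, 2.07e7), (17.1, 1.12e7), (19.1, 1.44e7)])
    def test_per_colony_outputs_match_survey(self, params, d, expected):
        assert colony_egg_output(d, params) == pytest.approx(expected, rel=5e-3)

    def test_homogeneous_in_fecundity(self, params):
        import dataclasses
        doubled = dataclasses.replace(
            params, fecundity=dataclasses.replace(params.fecundity,
                                                  mean=2 * params.fecundity.mean))
        assert colony_egg_output(20.0, doubled) == pytest.approx(
            2 * colony_egg_output(20.0, params))

    def test_population_output_back_reef_2014(self, params):
        """1.466e7 colonies × 10 % mature × eggs(22.3 cm) ≈ 3.03e13 eggs."""
        ab = AbundanceEstimate("back_reef", 2014, "all_colonies", 1.4656e7)
        mat = MaturitySummary(191, 19, 0.10, 22.3)
        eggs = population_egg_output(ab, mat, params)
        assert eggs == pytest.approx(3.03e13, rel=5e-3)

    def test_zero_iff_no_colonies_or_none_mature(self, params):
        mat0 = MaturitySummary(100, 0, 0.0, float("nan"))
        ab = AbundanceEstimate("h", 2014, "all_colonies", 1e6)
        assert population_egg_output(ab, mat0, params) == 0.0
        ab0 = AbundanceEstimate("h", 2014, "all_colonies", 0.0)
        mat = MaturitySummary(10, 5, 0.5, 20.0)
        assert population_egg_output(ab0, mat, params) == 0.0
        assert population_egg_output(ab, mat, params) > 0.0

    def test_undefined_diameter_with_positive_maturity_rejected(self, params):
        ab = AbundanceEstimate("h", 2014, "all_colonies", 1e6)
        bad = MaturitySummary(10, 5, 0.5, float("nan"))
        with pytest.raises(ValueError):
            population_egg_output(ab, bad, params)

    def test_integrate_mode_uses_size_list(self, params):
        ab = AbundanceEstimate("h", 2014, "all_colonies", 1e6)
        mat = MaturitySummary(10, 5, 0.5, 20.0)
        same = population_egg_output(ab, mat, params, per_colony="integrate",
                                     diameters_cm=[20.0, 20.0])
        assert same == pytest.approx(population_egg_output(ab, mat, params))
        # convexity: a size spread with the same mean produces more eggs
        spread = population_egg_output(ab, mat, params, per_colony="integrate",
                                       diameters_cm=[15.0, 25.0])
        assert spread > same

    def test_zygote_production(self, params):
        assert zygote_production(5.29e11, params) == pytest.approx(7.94e10, rel=1e-2)
        assert zygote_production(0.0, params) == 0.0
        import dataclasses
        full = dataclasses.replace(
            params, fertilization=dataclasses.replace(params.fertilization, mean=1.0))
        assert zygote_production(3.5e9, full) == pytest.approx(3.5e9)

    @given(st.floats(min_value=0.5, max_value=100.0),
           st.floats(min_value=0.5, max_value=100.0))
    def test_tissue_area_strictly_increasing(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert tissue_area(lo, ALLOMETRY) < tissue_area(hi, ALLOMETRY)
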