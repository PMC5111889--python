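"""Self-seeding assessment: requirements, ratios, report assembly."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefseed import (SelfSeedingScenario, build_report,
                      recruit_to_juvenile_survival, required_larvae,
                      sufficiency_ratio)
from reefseed.abundance import AbundanceEstimate
from reefseed.moorea import larval_budget
from reefseed.selfseed import ReconciliationError


class TestRequiredLarvae:
    def test_999_per_mille_loss_multiplies_by_1000(self):
        scen = SelfSeedingScenario(larval_loss_fraction=0.999)
        assert required_larvae(5.05e8, scen) == pytest.approx(5.05e11)

    def test_zero_loss_identity(self):
        scen = SelfSeedingScenario(larval_loss_fraction=0.0)
        assert required_larvae(1234.0, scen) == 1234.0

    def test_zero_recruits(self):
        assert required_larvae(0.0, SelfSeedingScenario()) == 0.0

    def test_total_loss_rejected(self):
        with pytest.raises(ValueError):
            SelfSeedingScenario(larval_loss_fraction=1.0)

    @given(st.floats(min_value=1e-3, max_value=1e9),
           st.floats(min_value=1e-3, max_value=1e9),
           st.floats(min_value=0.0, max_value=0.999))
    def test_linear_in_recruits_increasing_in_loss(self, r1, r2, loss):
        scen = SelfSeedingScenario(larval_loss_fraction=loss)
        assert required_larvae(r1 + r2, scen) == pytest.approx(
            required_larvae(r1, scen) + required_larvae(r2, scen), rel=1e-9)
        if loss < 0.99:
            harder = SelfSeedingScenario(larval_loss_fraction=loss + 1e-3)
            assert required_larvae(r1, harder) > required_larvae(r1, scen)


class TestRatios:
    def test_2010_whole_shore_excess(self):
        """Printed productions (7.89e10 + 8.30e11) against the requirement
        for 5.05e8 recruits at 99.9 % loss give ≈ 1.8-fold excess."""
        produced = 7.89e10 + 8.30e11
        req = required_larvae(5.05e8, SelfSeedingScenario(0.999))
        assert sufficiency_ratio(produced, req) == pytest.approx(1.8, abs=0.02)

    def test_boundaries(self):
        assert sufficiency_ratio(10.0, 10.0) == 1.0
        assert sufficiency_ratio(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            sufficiency_ratio(1.0, 0.0)

    @given(st.floats(min_value=1e-3, max_value=1e12),
           st.floats(min_value=1e-3, max_value=1e12),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, produced, req, k):
        assert sufficiency_ratio(k * produced, k * req) == pytest.approx(
            sufficiency_ratio(produced, req), rel=1e-9)

    def test_2014_survival_below_one_third(self):
        """Printed juveniles (5.98e7 + 1.10e7) vs 2.18e8 recruits ≈ 0.32."""
        surv = recruit_to_juvenile_survival(5.98e7 + 1.10e7, 2.18e8)
        assert surv == pytest.approx(0.325, abs=0.005)
        assert surv < 1 / 3

    def test_survival_boundaries(self):
        assert recruit_to_juvenile_survival(0.0, 5.0) == 0.0
        assert recruit_to_juvenile_survival(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            recruit_to_juvenile_survival(1.0, 0.0)


def _abundances(overrides=None):
    base = {
        ("br", 2010, "recruit"): 1e7, ("or", 2010, "recruit"): 4e7,
        ("br", 2010, "juvenile"): 1e6, ("or", 2010, "juvenile"): 2e6,
        ("br", 2010, "all_colonies"): 1e6, ("or", 2010, "all_colonies"): 5e5,
    }
    base.update(overrides or {})
    return [AbundanceEstimate(h, y, s, v) for (h, y, s), v in base.items()
            if not (isinstance(v, float) and math.isnan(v))]


def _chains():
    return {("br", 2010): {"n_colonies": 1e6, "prop_mature": 0.2,
                           "mean_mature_diameter_cm": 20.0,
                           "eggs_per_year": 1e12, "zygotes_per_year": 1.5e11},
            ("or", 2010): {"n_colonies": 5e5, "prop_mature": 0.0,
                           "mean_mature_diameter_cm": float("nan"),
                           "eggs_per_year": 0.0, "zygotes_per_year": 0.0}}


class TestBuildReport:
    def test_totals_are_sum_of_habitat_components(self):
        report = build_report(_abundances(), _chains(), SelfSeedingScenario())
        t = report.table
        all_row = t[(t.habitat == "all") & (t.year == 2010)].iloc[0]
        parts = t[(t.habitat != "all") & (t.year == 2010)]
        assert all_row.larvae_produced == pytest.approx(parts.larvae_produced.sum())
        assert all_row.recruits_observed == pytest.approx(parts.recruits_observed.sum())

    def test_zero_production_habitat_still_assessed_against_shore_total(self):
        report = build_report(_abundances(), _chains(), SelfSeedingScenario())
        t = report.table
        all_row = t[(t.habitat == "all")].iloc[0]
        # whole-shore production comes from the producing habitat alone
        assert all_row.larvae_produced == pytest.approx(1.5e11)
        assert all_row.sufficiency_ratio == pytest.approx(1.5e11 / (5e7 * 1000))

    def test_missing_recruits_reported_as_gap_not_zero(self):
        ab = [a for a in _abundances() if not (a.habitat == "br" and a.life_stage == "recruit")]
        report = build_report(ab, _chains(), SelfSeedingScenario())
        assert any("br 2010: recruit abundance missing" in g for g in report.gaps)
        all_row = report.table[report.table.habitat == "all"].iloc[0]
        assert math.isnan(all_row.recruits_observed)

    def test_mismatched_chain_key_is_reconciliation_error(self):
        chains = dict(_chains())
        chains[("nowhere", 1999)] = chains.pop(("or", 2010))
        with pytest.raises(ReconciliationError):
            build_report(_abundances(), chains, SelfSeedingScenario())

    def test_implausible_survival_flagged_not_clamped(self):
        ab = _abundances({("br", 2010, "juvenile"): 5e7})
        report = build_report(ab, _chains(), SelfSeedingScenario())
        row = report.table[(report.table.habitat == "br")].iloc[0]
        assert row.recruit_to_juvenile_survival == pytest.approx(5.0)
        assert any("implausible" in f for f in report.flags)

    def test_loss_sweep_monotone(self):
        report = build_report(_abundances(), _chains(), SelfSeedingScenario())
        sw = report.loss_sweep.sort_values("larval_loss_fraction")
        assert sw.sufficiency_ratio.is_monotonic_decreasing


def test_full_budget_report_shape():
    """The published-inputs budget yields 2 habitats × 2 years plus totals,
    with all four life stages represented."""
    report, draws = larval_budget(seed=2, n_draws=500)
    t = report.table
    assert set(t.habitat) == {"back_reef", "outer_reef", "all"}
    assert set(t.year) == {2010, 2014}
    assert len(t) == 6
    stages = set(report.abundance_table.life_stage)
    assert stages == {"recruit", "juvenile", "all_colonies"}
    assert set(draws) == {("back_reef", 2010), ("back_reef", 2014),
                          ("outer_reef", 2010), ("outer_reef", 2014)}
    assert np.all(draws[("outer_reef", 2014)] == 0.0)
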