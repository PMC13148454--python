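"""Cohort exposure arithmetic and the stochastic cohort simulation."""

import pytest

from cascade import (
    BoundedRange,
    CohortScenario,
    InputError,
    avoided_exposure,
    cohort_exposure,
    events_avoided,
    institutional_exposure,
    simulate_cohort,
)


class TestEventsAvoided:
    def test_published_hundred_case_bounds(self, hundred_case_scenario):
        assert events_avoided(hundred_case_scenario) == (10.0, 20.0)

    def test_no_intervention_effect_avoids_nothing(self):
        rates = BoundedRange(lower=0.15, upper=0.15)
        scenario = CohortScenario(
            n_cases=100,
            baseline_rate_range=rates,
            intervention_rate_range=rates,
            failure_cost_range=BoundedRange(lower=1, upper=1),
        )
        low, high = events_avoided(scenario)
        assert low == 0.0 and high == 0.0

    def test_point_rates_give_point_reduction(self):
        scenario = CohortScenario(
            n_cases=100,
            baseline_rate_range=BoundedRange(lower=0.20, upper=0.20),
            intervention_rate_range=BoundedRange(lower=0.07, upper=0.07),
            failure_cost_range=BoundedRange(lower=600_000, upper=600_000),
        )
        low, high = events_avoided(scenario)
        assert low == pytest.approx(13.0) and high == pytest.approx(13.0)

    def test_intervention_above_baseline_rejected(self):
        with pytest.raises(ValueError):
            CohortScenario(
                n_cases=100,
                baseline_rate_range=BoundedRange(lower=0.10, upper=0.15),
                intervention_rate_range=BoundedRange(lower=0.12, upper=0.14),
                failure_cost_range=BoundedRange(lower=1, upper=2),
            )


class TestAvoidedExposure:
    def test_published_exposure_and_per_case_bounds(self, hundred_case_scenario):
        result = cohort_exposure(hundred_case_scenario)
        assert result.avoided_exposure_range == (4_000_000.0, 20_000_000.0)
        assert result.per_case_range == (40_000.0, 200_000.0)

    def test_zero_events_zero_exposure(self):
        result = avoided_exposure((0.0, 0.0), BoundedRange(lower=1, upper=9e9), 100)
        assert result.avoided_exposure_range == (0.0, 0.0)

    def test_conservative_scenario_reaches_one_million(self):
        result = avoided_exposure(
            (10.0, 10.0), BoundedRange(lower=100_000, upper=100_000), 100
        )
        assert result.avoided_exposure_range == (1_000_000.0, 1_000_000.0)
        assert result.per_case_range == (10_000.0, 10_000.0)

    def test_out_of_order_events_rejected(self):
        with pytest.raises(InputError):
            avoided_exposure((5.0, 2.0), BoundedRange(lower=1, upper=2), 10)

    def test_scale_equivariance(self, hundred_case_scenario):
        doubled = hundred_case_scenario.model_copy(update={"n_cases": 200})
        r1, r2 = cohort_exposure(hundred_case_scenario), cohort_exposure(doubled)
        assert r2.events_avoided_range == tuple(2 * v for v in r1.events_avoided_range)
        assert r2.avoided_exposure_range == tuple(2 * v for v in r1.avoided_exposure_range)
        assert r2.per_case_range == r1.per_case_range


class TestInstitutionalExposure:
    @pytest.mark.parametrize(
        "n, rate, lo, hi, expected",
        [
            (100, 0.20, 400_000, 600_000, (8_000_000.0, 12_000_000.0)),
            (100, 0.0, 400_000, 600_000, (0.0, 0.0)),
            (50, 0.10, 400_000, 400_000, (2_000_000.0, 2_000_000.0)),
        ],
    )
    def test_annual_exposure(self, n, rate, lo, hi, expected):
        got = institutional_exposure(n, rate, BoundedRange(lower=lo, upper=hi))
        assert got == pytest.approx(expected)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            institutional_exposure(100, 1.2, BoundedRange(lower=1, upper=2))


class TestSimulateCohort:
    def _scenario(self, cost: float) -> CohortScenario:
        return CohortScenario(
            n_cases=100,
            baseline_rate_range=BoundedRange(lower=0.15, upper=0.25),
            intervention_rate_range=BoundedRange(lower=0.05, upper=0.10),
            failure_cost_range=BoundedRange(lower=cost, upper=cost),
        )

    def test_identical_arms_agree_within_mc_error(self):
        sim = simulate_cohort(self._scenario(600_000), 0.2, 0.2, 0.0, 50_000, seed=1)
        assert abs(sim.mean_difference) <= 3 * sim.se_difference

    def test_recovers_analytic_expected_difference(self):
        """mean(S1) - mean(S2) converges to dP * E[C] - dC = 28,000."""
        sim = simulate_cohort(self._scenario(600_000), 0.20, 0.07, 50_000, 100_000, seed=3)
        assert sim.mean_difference == pytest.approx(28_000, abs=3 * sim.se_difference)

    def test_zero_failure_probability_difference_is_exactly_delta_c(self):
        sim = simulate_cohort(self._scenario(600_000), 0.0, 0.0, 40_000, 1_000, seed=4)
        assert sim.mean_difference == pytest.approx(-40_000)
        assert sim.se_difference == 0.0

    def test_seed_determinism(self):
        a = simulate_cohort(self._scenario(500_000), 0.2, 0.07, 50_000, 5_000, seed=8)
        b = simulate_cohort(self._scenario(500_000), 0.2, 0.07, 50_000, 5_000, seed=8)
        assert a == b
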