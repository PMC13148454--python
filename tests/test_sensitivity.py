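"""Deterministic threshold grids, one-way sweeps, and the Monte Carlo PSA."""

import math

import numpy as np
import pytest

from cascade import (
    CascadeError,
    DecisionInputs,
    Distribution,
    InputError,
    PSAConfig,
    Verdict,
    decision_threshold,
    one_way,
    run_psa,
    two_way_grid,
)
from cascade.sensitivity import DEFAULT_GRID_COSTS, DEFAULT_GRID_DPS, enumerate_psa_exact


class TestTwoWayGrid:
    def test_every_cell_matches_decision_threshold(self):
        grid = two_way_grid()
        for cost in grid.costs:
            for dp in grid.dps:
                assert grid.cell(cost, dp) == pytest.approx(
                    decision_threshold(dp, 0.0, cost), rel=1e-12
                )

    def test_monotone_rows_and_columns(self):
        t = two_way_grid().table.to_numpy()
        assert (np.diff(t, axis=0) >= 0).all()
        assert (np.diff(t, axis=1) >= 0).all()

    def test_single_cell_grid_consistent_with_rule(self):
        grid = two_way_grid([600_000], [0.13])
        assert grid.cell(600_000, 0.13) == pytest.approx(78_000)

    def test_empty_axis_rejected(self):
        with pytest.raises(InputError):
            two_way_grid([], DEFAULT_GRID_DPS)

    def test_high_and_extreme_cost_rows_clear_50k_at_dp_010(self):
        """Directional robustness: severe/catastrophic cost rows exceed a
        $50,000 threshold whenever the risk reduction is at least 0.10."""
        grid = two_way_grid()
        for cost in (600_000, 900_000):
            for dp in (0.10, 0.13, 0.20, 0.25):
                assert grid.cell(cost, dp) > 50_000


class TestOneWay:
    def test_cost_sweep_reproduces_worked_sensitivity(self):
        inputs = DecisionInputs(delta_c=50_000, p1=0.20, p2=0.07, c=600_000)
        table = one_way(inputs, "c", [600_000, 800_000])
        assert list(table["threshold"]) == [pytest.approx(78_000), pytest.approx(104_000)]
        assert set(table["verdict"]) == {Verdict.RECONSTRUCTION_FAVORED.value}

    def test_delta_c_sweep_flips_verdict_exactly_once(self):
        inputs = DecisionInputs(delta_c=50_000, p1=0.20, p2=0.07, c=600_000)
        values = list(range(10_000, 150_001, 10_000))
        verdicts = list(one_way(inputs, "delta_c", values)["verdict"])
        flips = sum(a != b for a, b in zip(verdicts, verdicts[1:]))
        assert flips == 1

    def test_p2_sweep_threshold_strictly_decreasing(self):
        inputs = DecisionInputs(delta_c=50_000, p1=0.20, p2=0.07, c=600_000)
        thr = list(one_way(inputs, "p2", [0.02, 0.05, 0.08, 0.11])["threshold"])
        assert all(a > b for a, b in zip(thr, thr[1:]))

    def test_unknown_parameter_rejected(self):
        inputs = DecisionInputs(delta_c=0, p1=0.2, p2=0.1, c=1)
        with pytest.raises(InputError, match="unknown parameter"):
            one_way(inputs, "c0", [1.0])


def _point_config(delta_c: float, n: int = 100, seed: int = 0) -> PSAConfig:
    return PSAConfig(
        p1=Distribution.point(0.20),
        p2=Distribution.point(0.07),
        c=Distribution.point(600_000),
        delta_c=delta_c,
        n_samples=n,
        seed=seed,
    )


class TestPSA:
    @pytest.mark.parametrize("delta_c, expected", [(50_000, 1.0), (200_000, 0.0)])
    def test_point_mass_psa_equals_deterministic_verdict(self, delta_c, expected):
        assert run_psa(_point_config(delta_c)).probability_favored == expected

    def test_uniform_cost_at_median_threshold_is_a_coin_flip(self):
        config = PSAConfig(
            p1=Distribution.point(0.20),
            p2=Distribution.point(0.07),
            c=Distribution.uniform(400_000, 800_000),
            delta_c=78_000,
            n_samples=10_000,
            seed=11,
        )
        result = run_psa(config)
        se = math.sqrt(0.5 * 0.5 / config.n_samples)
        assert result.probability_favored == pytest.approx(0.5, abs=3 * se)

    def test_monotone_non_increasing_in_delta_c(self):
        config = PSAConfig(
            p1=Distribution.uniform(0.15, 0.25),
            p2=Distribution.uniform(0.05, 0.10),
            c=Distribution.uniform(400_000, 800_000),
            delta_c=0.0,
            n_samples=4_000,
            seed=5,
        )
        probs = [
            run_psa(config.model_copy(update={"delta_c": float(dc)})).probability_favored
            for dc in (0, 30_000, 60_000, 90_000, 150_000)
        ]
        assert probs == sorted(probs, reverse=True)

    def test_seed_determinism_bit_identical(self):
        config = PSAConfig(
            p1=Distribution.triangular(0.15, 0.25),
            p2=Distribution.triangular(0.05, 0.10),
            c=Distribution.triangular(400_000, 800_000),
            delta_c=60_000,
            n_samples=2_000,
            seed=42,
        )
        assert run_psa(config) == run_psa(config)

    def test_quantiles_ordered_and_rejection_reported(self):
        config = PSAConfig(
            p1=Distribution.uniform(0.05, 0.15),
            p2=Distribution.uniform(0.03, 0.12),  # overlaps p1: forces rejections
            c=Distribution.uniform(100_000, 250_000),
            delta_c=10_000,
            n_samples=5_000,
            seed=9,
        )
        result = run_psa(config)
        q = list(result.threshold_quantiles.values())
        assert q == sorted(q)
        assert result.rejection_rate > 0
        assert result.n_effective == config.n_samples

    def test_infeasible_ordering_raises_with_rejection_rate(self):
        config = PSAConfig(
            p1=Distribution.point(0.05),
            p2=Distribution.point(0.10),  # p2 can never fall below p1
            c=Distribution.point(100_000),
            delta_c=0.0,
            n_samples=10,
            seed=1,
        )
        with pytest.raises(CascadeError, match="rejection rate"):
            run_psa(config)

    def test_discrete_psa_matches_exhaustive_enumeration(self):
        """Brute-force oracle: for small finite supports the sampled
        probability must converge to the exact enumeration."""
        config = PSAConfig(
            p1=Distribution.discrete([0.15, 0.25]),
            p2=Distribution.discrete([0.05, 0.10, 0.20]),
            c=Distribution.discrete([400_000, 800_000]),
            delta_c=60_000,
            n_samples=100_000,
            seed=2,
        )
        exact = enumerate_psa_exact(config)
        mc = run_psa(config).probability_favored
        se = math.sqrt(exact * (1 - exact) / config.n_samples)
        assert mc == pytest.approx(exact, abs=4 * se)
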