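"""Cohort-level expected-value modeling: avoided failures and cost exposure.

Scales the per-case decision arithmetic to hypothetical cohorts: how many
failure events an early-reconstruction strategy avoids per n cases, the
avoided episode-cost exposure those events represent, the same exposure
normalized per case, and a service line's annual modeled exposure at a given
volume and failure rate.

Range arithmetic is interval-style bookkeeping, not a confidence interval:
the lower bound pairs the lower baseline rate with the lower intervention
rate, while the upper bound takes the widest corner pairing (upper baseline
rate minus lower intervention rate). Exposure bounds then pair low event
counts with low costs and high counts with high costs.

A seeded stochastic counterpart, :func:`simulate_cohort`, realizes the same
expected-value identities by simulation: Bernoulli failure per episode, a
cost draw on failure, the incremental reconstruction cost added under the
reconstruction arm. Its empirical per-case cost difference converges to
dP * E[C] - dC.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import InputError
from .parameters import BoundedRange

__all__ = [
    "CohortScenario",
    "ExposureResult",
    "CohortSimulationResult",
    "events_avoided",
    "avoided_exposure",
    "cohort_exposure",
    "institutional_exposure",
    "simulate_cohort",
]


class CohortScenario(BaseModel):
    """A hypothetical cohort: case count, failure-rate ranges under each
    strategy, and the episode-cost range a failure incurs."""

    model_config = {"frozen": True, "extra": "forbid"}

    n_cases: int = Field(ge=1)
    baseline_rate_range: BoundedRange
    intervention_rate_range: BoundedRange
    failure_cost_range: BoundedRange

    @model_validator(mode="after")
    def _valid_rates(self) -> "CohortScenario":
        for name in ("baseline_rate_range", "intervention_rate_range"):
            r = getattr(self, name)
            if not (0.0 <= r.lower and r.upper <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        b, i = self.baseline_rate_range, self.intervention_rate_range
        if i.lower > b.lower or i.upper > b.upper:
            raise ValueError("intervention rates must not exceed baseline rates elementwise")
        if self.failure_cost_range.lower < 0:
            raise ValueError("failure costs must be non-negative")
        return self


class ExposureResult(BaseModel):
    """Avoided failure events and avoided cost exposure, as (low, high)
    bounds, plus the exposure normalized per case."""

    model_config = {"frozen": True}

    n_cases: int
    events_avoided_range: tuple[float, float]
    avoided_exposure_range: tuple[float, float]
    per_case_range: tuple[float, float]


def events_avoided(scenario: CohortScenario) -> tuple[float, float]:
    """Bounds on failure events avoided by the intervention per cohort.

    low  = n * (baseline.lower - intervention.lower)
    high = n * (baseline.upper - intervention.lower)   (widest corner)
    """
    b, i = scenario.baseline_rate_range, scenario.intervention_rate_range
    low = scenario.n_cases * (b.lower - i.lower)
    high = scenario.n_cases * (b.upper - i.lower)
    if low < 0 or high < 0:
        raise InputError("avoided events negative under the chosen rate pairing")
    return low, high


def avoided_exposure(
    events: tuple[float, float],
    cost_range: BoundedRange,
    n_cases: int,
) -> ExposureResult:
    """Convert avoided-event bounds into avoided cost-exposure bounds.

    Low events pair with the low cost bound, high with high; per-case values
    divide each bound by the cohort size.
    """
    low_events, high_events = events
    if low_events > high_events:
        raise InputError(f"events bounds out of order: {events}")
    if cost_range.lower < 0:
        raise InputError("failure costs must be non-negative")
    if n_cases < 1:
        raise InputError(f"n_cases must be >= 1, got {n_cases}")
    low = low_events * cost_range.lower
    high = high_events * cost_range.upper
    return ExposureResult(
        n_cases=n_cases,
        events_avoided_range=(low_events, high_events),
        avoided_exposure_range=(low, high),
        per_case_range=(low / n_cases, high / n_cases),
    )


def cohort_exposure(scenario: CohortScenario) -> ExposureResult:
    """Convenience composition: events_avoided then avoided_exposure."""
    return avoided_exposure(
        events_avoided(scenario), scenario.failure_cost_range, scenario.n_cases
    )


def institutional_exposure(
    n_cases_per_year: int,
    failure_rate: float,
    avg_cost_range: BoundedRange,
) -> tuple[float, float]:
    """Annual modeled failure-cost exposure for a service line:
    n * rate * cost, evaluated at each cost bound."""
    if not (0.0 <= failure_rate <= 1.0):
        raise InputError(f"failure rate must lie in [0, 1], got {failure_rate}")
    if n_cases_per_year < 0:
        raise InputError("case volume must be non-negative")
    return (
        n_cases_per_year * failure_rate * avg_cost_range.lower,
        n_cases_per_year * failure_rate * avg_cost_range.upper,
    )


class CohortSimulationResult(BaseModel):
    """Empirical per-episode mean costs per strategy with MC standard errors."""

    model_config = {"frozen": True}

    mean_cost_s1: float
    se_s1: float
    mean_cost_s2: float
    se_s2: float
    mean_difference: float  # mean(S1) - mean(S2)
    se_difference: float
    n_reps: int


def simulate_cohort(
    scenario: CohortScenario,
    p1: float,
    p2: float,
    delta_c: float,
    n_reps: int,
    seed: int,
) -> CohortSimulationResult:
    """Stochastic realization of the expected-value comparison.

    Simulates ``n_reps`` independent episodes per strategy: failure is
    Bernoulli (p1 under routine closure, p2 under reconstruction), a failed
    episode draws its trajectory cost uniformly from the scenario's cost
    range, and the reconstruction arm pays ``delta_c`` up front. The mean
    difference converges to dP * E[C] - dC.
    """
    if n_reps < 1:
        raise InputError(f"n_reps must be >= 1, got {n_reps}")
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 <= p <= 1.0):
            raise InputError(f"{name} must lie in [0, 1], got {p}")
    if delta_c < 0:
        raise InputError(f"delta_c must be non-negative, got {delta_c}")

    rng = np.random.default_rng(seed)
    lo, hi = scenario.failure_cost_range.lower, scenario.failure_cost_range.upper

    def _arm(p: float, upfront: float) -> np.ndarray:
        fail = rng.random(n_reps) < p
        costs = np.full(n_reps, upfront, dtype=float)
        n_fail = int(fail.sum())
        if n_fail:
            draws = np.full(n_fail, lo) if lo == hi else rng.uniform(lo, hi, size=n_fail)
            costs[fail] += draws
        return costs

    s1 = _arm(p1, 0.0)
    s2 = _arm(p2, delta_c)
    se1 = float(s1.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else float("nan")
    se2 = float(s2.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else float("nan")
    diff = float(s1.mean() - s2.mean())
    se_diff = math.hypot(se1, se2) if n_reps > 1 else float("nan")
    return CohortSimulationResult(
        mean_cost_s1=float(s1.mean()),
        se_s1=se1,
        mean_cost_s2=float(s2.mean()),
        se_s2=se2,
        mean_difference=diff,
        se_difference=se_diff,
        n_reps=n_reps,
    )
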