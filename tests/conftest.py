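import json

import pytest

from cascade import BoundedRange, CohortScenario

HIGH_RISK_FACTORS = {"hardware", "perfusion", "soft_tissue", "operative", "comorbidity"}


@pytest.fixture
def high_risk_case_text() -> str:
    """High-risk posterior-spine style case: five factors, severe cost tier,
    printed probability midpoints supplied as explicit overrides."""
    return json.dumps(
        {
            "case_id": "high-risk",
            "factors": sorted(HIGH_RISK_FACTORS),
            "fct": 3,
            "delta_c": 50_000,
            "overrides": {"p1": 0.20, "p2": 0.07},
        }
    )


@pytest.fixture
def low_risk_case_text() -> str:
    """Low-risk case: single comorbidity point, limited cost tier."""
    return json.dumps(
        {
            "case_id": "low-risk",
            "factors": ["comorbidity"],
            "fct": 1,
            "delta_c": 6_000,
            "overrides": {"p1": 0.07, "p2": 0.04},
        }
    )


@pytest.fixture
def hundred_case_scenario() -> CohortScenario:
    """100-case high-risk cohort with the published rate and cost ranges."""
    return CohortScenario(
        n_cases=100,
        baseline_rate_range=BoundedRange(lower=0.15, upper=0.25),
        intervention_rate_range=BoundedRange(lower=0.05, upper=0.10),
        failure_cost_range=BoundedRange(lower=400_000, upper=1_000_000),
    )
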