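"""The expected-value decision rule for the index reconstructive strategy.

Two mutually exclusive strategies are compared at the index operation:
S1, routine closure, and S2, definitive reconstruction. With baseline
episode cost C0, failure probabilities p1 and p2, failure trajectory cost C
and incremental reconstruction cost dC, the expected total episode costs are

    E[Cost | S1] = C0 + p1 * C
    E[Cost | S2] = C0 + dC + p2 * C

so reconstruction is favored on expected-value grounds exactly when
dC < (p1 - p2) * C = dP * C. C0 cancels from the comparison and the verdict
never depends on it. Physician professional fees are structurally excluded:
no field exists for them, as they would shift both strategies equally.

Real-valued equality ("dC = dP * C") defines the indeterminate verdict; in
floating point this is implemented as a configurable tolerance band
(relative 1e-9, absolute half a cent by default).
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import InputError
from .risk import Applicability

__all__ = [
    "Verdict",
    "DecisionInputs",
    "DecisionResult",
    "expected_costs",
    "decision_threshold",
    "decide",
    "evaluate",
]

#: Default tolerance for the indeterminate band: |dC - threshold| within
#: max(REL_TOL * threshold, ABS_TOL) counts as equality.
REL_TOL = 1e-9
ABS_TOL = 0.005


class Verdict(str, Enum):
    RECONSTRUCTION_FAVORED = "reconstruction_favored"
    INDETERMINATE = "indeterminate"
    CLOSURE_FAVORED = "closure_favored"


class DecisionInputs(BaseModel):
    """Resolved point inputs to the decision rule (all costs in USD)."""

    model_config = {"frozen": True, "extra": "forbid"}

    delta_c: float = Field(ge=0, description="incremental reconstruction cost dC")
    p1: float = Field(ge=0, le=1, description="failure probability, routine closure")
    p2: float = Field(ge=0, le=1, description="failure probability, reconstruction")
    c: float = Field(ge=0, description="failure trajectory cost C")
    c0: float = Field(default=0.0, ge=0, description="baseline episode cost (cancels)")

    @model_validator(mode="after")
    def _ordered_probabilities(self) -> "DecisionInputs":
        if self.p2 > self.p1:
            raise ValueError(f"p2 ({self.p2}) must not exceed p1 ({self.p1})")
        return self

    @property
    def dp(self) -> float:
        return self.p1 - self.p2


class DecisionResult(BaseModel):
    """Threshold, expected costs per strategy, and the three-way verdict."""

    model_config = {"frozen": True}

    threshold: float
    expected_cost_s1: float
    expected_cost_s2: float
    verdict: Verdict
    applicability: Optional[Applicability] = None


def expected_costs(inputs: DecisionInputs) -> tuple[float, float]:
    """Expected total episode cost under each strategy,
    (C0 + p1*C, C0 + dC + p2*C)."""
    e_s1 = inputs.c0 + inputs.p1 * inputs.c
    e_s2 = inputs.c0 + inputs.delta_c + inputs.p2 * inputs.c
    return e_s1, e_s2


def decision_threshold(p1: float, p2: float, c: float) -> float:
    """Maximum incremental cost justified by the risk reduction: dP * C."""
    if not (0.0 <= p2 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise InputError("probabilities must lie in [0, 1]")
    if p2 > p1:
        raise InputError(f"p2 ({p2}) must not exceed p1 ({p1})")
    if c < 0:
        raise InputError(f"failure trajectory cost must be non-negative, got {c}")
    return (p1 - p2) * c


def decide(
    delta_c: float,
    threshold: float,
    rel_tol: float = REL_TOL,
    abs_tol: float = ABS_TOL,
) -> Verdict:
    """Three-way verdict: dC below / at / above the threshold dP * C."""
    if rel_tol < 0 or abs_tol < 0:
        raise InputError("tolerances must be non-negative")
    tol = max(rel_tol * abs(threshold), abs_tol)
    if abs(delta_c - threshold) <= tol:
        return Verdict.INDETERMINATE
    if delta_c < threshold:
        return Verdict.RECONSTRUCTION_FAVORED
    return Verdict.CLOSURE_FAVORED


def evaluate(
    inputs: DecisionInputs,
    applicability: Optional[Applicability] = None,
    rel_tol: float = REL_TOL,
    abs_tol: float = ABS_TOL,
) -> DecisionResult:
    """Full decision for one case: expected costs, threshold, verdict.

    An inapplicable case (low-risk wound environment) still computes — the
    applicability annotation travels with the result.
    """
    e_s1, e_s2 = expected_costs(inputs)
    threshold = decision_threshold(inputs.p1, inputs.p2, inputs.c)
    verdict = decide(inputs.delta_c, threshold, rel_tol=rel_tol, abs_tol=abs_tol)
    return DecisionResult(
        threshold=threshold,
        expected_cost_s1=e_s1,
        expected_cost_s2=e_s2,
        verdict=verdict,
        applicability=applicability,
    )
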