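"""Case-file schema, validation, end-to-end case evaluation, and reports.

A case file is a small JSON or YAML document describing one patient-case:
which risk factors are present, explicit applicability flags, the selected
failure cost tier (1-4), the incremental reconstruction cost, the bound
policy used to resolve ranges, and optional explicit overrides for the
probability and cost inputs. Validation is total and collects every schema
violation, not just the first; unknown keys are rejected by name.

Currency values are unit-less USD numbers: exact decimals in I/O, float64
internally, rounded to cents only at display.
"""

from __future__ import annotations

import json
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .decision import DecisionInputs, DecisionResult, evaluate
from .errors import CaseValidationError, InputError
from .parameters import (
    DEFAULT_COST_TIERS,
    DEFAULT_PROBABILITY_TABLE,
    BoundPolicy,
    ProbabilityTierTable,
    resolve_cost,
    resolve_probabilities,
)
from .risk import (
    DEFAULT_CATALOG,
    Applicability,
    ApplicabilityFlags,
    CRSResult,
    RiskFactorCatalog,
    check_applicability,
    compute_crs,
)

__all__ = [
    "Overrides",
    "DocumentationChecklist",
    "CaseFile",
    "CaseProfile",
    "validate_case",
    "evaluate_case",
    "documentation_report",
    "case_to_json",
]


class Overrides(BaseModel):
    """Optional explicit point values that bypass policy-based resolution."""

    model_config = {"frozen": True, "extra": "forbid"}

    p1: Optional[float] = Field(default=None, ge=0, le=1)
    p2: Optional[float] = Field(default=None, ge=0, le=1)
    c: Optional[float] = Field(default=None, ge=0)
    c0: Optional[float] = Field(default=None, ge=0)


class DocumentationChecklist(BaseModel):
    """The five documentation elements linking the clinical record to model
    inputs. Purely informational: the decision computes regardless."""

    model_config = {"frozen": True, "extra": "forbid"}

    crs_drivers_documented: bool = False
    expected_failure_trajectory_documented: bool = False
    reason_routine_closure_inadequate: bool = False
    reconstructive_mechanism_selected: bool = False
    anticipated_prevented_events_documented: bool = False


#: Model function each documentation element feeds.
DOCUMENTATION_MODEL_FUNCTIONS = {
    "crs_drivers_documented": (
        "Defines baseline risk tier and assigns failure probability inputs (P1, P2, dP)"
    ),
    "expected_failure_trajectory_documented": (
        "Defines failure cost tier (FCT) and associated total episode cost range (C)"
    ),
    "reason_routine_closure_inadequate": (
        "Establishes clinical necessity for reconstruction (debridement, vascularized "
        "coverage, tension-free closure requirements)"
    ),
    "reconstructive_mechanism_selected": (
        "Defines incremental intervention (dC) and confirms strategy"
    ),
    "anticipated_prevented_events_documented": (
        "Links intervention to reduction in failure trajectory and expected total "
        "episode cost differential"
    ),
}


class CaseFile(BaseModel):
    """Validated description of one patient-case."""

    model_config = {"frozen": True, "extra": "forbid"}

    case_id: str = "case"
    factors: tuple[str, ...] = ()
    applicability_flags: ApplicabilityFlags = ApplicabilityFlags()
    fct: int = Field(ge=1, le=4, description="failure cost tier, 1-4")
    delta_c: float = Field(ge=0)
    bound_policy: str = "midpoint"
    overrides: Overrides = Overrides()
    documentation: DocumentationChecklist = DocumentationChecklist()

    @model_validator(mode="after")
    def _known_policy(self) -> "CaseFile":
        if self.bound_policy not in ("lower", "midpoint", "upper"):
            raise ValueError(
                f"bound_policy must be lower/midpoint/upper, got {self.bound_policy!r} "
                "(use overrides for explicit values)"
            )
        return self


#: A generated or in-memory case is the same object as a validated case file.
CaseProfile = CaseFile


def _format_violation(err: dict[str, Any]) -> str:
    loc = ".".join(str(p) for p in err["loc"]) or "<root>"
    return f"{loc}: {err['msg']}"


def validate_case(raw: str) -> CaseFile:
    """Parse and validate a JSON or YAML case document.

    Raises :class:`~cascade.errors.CaseValidationError` carrying the full
    list of violations; malformed documents raise an input error with the
    parser's position information.
    """
    try:
        data = yaml.safe_load(raw)  # YAML is a superset of JSON
    except yaml.YAMLError as e:
        raise InputError(f"case file is not valid JSON/YAML: {e}") from e
    if not isinstance(data, dict):
        raise CaseValidationError(["<root>: case file must be a mapping of fields"])
    try:
        return CaseFile.model_validate(data)
    except ValidationError as e:
        raise CaseValidationError([_format_violation(err) for err in e.errors()]) from e


class CaseEvaluation(BaseModel):
    """Everything computed for one case, ready for JSON emission."""

    model_config = {"frozen": True}

    case_id: str
    crs: CRSResult
    applicability: Applicability
    p1: float
    p2: float
    dp: float
    c: float
    decision: DecisionResult


def evaluate_case(
    case: CaseFile,
    catalog: RiskFactorCatalog = DEFAULT_CATALOG,
    probability_table: ProbabilityTierTable = DEFAULT_PROBABILITY_TABLE,
) -> CaseEvaluation:
    """Run the full pipeline for one case: score, gate, resolve, decide."""
    crs = compute_crs(case.factors, catalog)
    applicability = check_applicability(crs, case.applicability_flags)
    policy = BoundPolicy(kind=case.bound_policy)
    p1, p2, dp = resolve_probabilities(
        crs.tier,
        probability_table,
        policy,
        p1_override=case.overrides.p1,
        p2_override=case.overrides.p2,
    )
    c = resolve_cost(DEFAULT_COST_TIERS[case.fct], policy, override=case.overrides.c)
    inputs = DecisionInputs(
        delta_c=case.delta_c,
        p1=p1,
        p2=p2,
        c=c,
        c0=case.overrides.c0 if case.overrides.c0 is not None else 0.0,
    )
    result = evaluate(inputs, applicability=applicability)
    return CaseEvaluation(
        case_id=case.case_id,
        crs=crs,
        applicability=applicability,
        p1=p1,
        p2=p2,
        dp=dp,
        c=c,
        decision=result,
    )


def documentation_report(case: CaseFile, result: Optional[DecisionResult] = None) -> dict:
    """Map each documentation element to present/missing with the model
    input it feeds. Informational only — never blocks a decision."""
    checklist = case.documentation
    elements = {}
    n_present = 0
    for name, function in DOCUMENTATION_MODEL_FUNCTIONS.items():
        present = getattr(checklist, name)
        n_present += present
        elements[name] = {"present": present, "model_function": function}
    report = {
        "case_id": case.case_id,
        "elements_present": n_present,
        "elements_total": len(DOCUMENTATION_MODEL_FUNCTIONS),
        "elements": elements,
    }
    if result is not None:
        report["verdict"] = result.verdict.value
    return report


def _round_cents(obj: Any) -> Any:
    if isinstance(obj, float):
        return round(obj, 2)
    if isinstance(obj, dict):
        return {k: _round_cents(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_cents(v) for v in obj]
    return obj


def case_to_json(evaluation: CaseEvaluation, indent: int = 2) -> str:
    """Stable-ordered JSON for a case evaluation, cents precision at display."""
    data = evaluation.model_dump(mode="json")
    d = data.pop("decision")
    flat = {
        "case_id": data["case_id"],
        "crs": data["crs"]["score"],
        "tier": data["crs"]["tier"],
        "contributing_factors": data["crs"]["contributing_factors"],
        "applicability": data["applicability"],
        "p1": data["p1"],
        "p2": data["p2"],
        "dp": data["dp"],
        "c": data["c"],
        "threshold": d["threshold"],
        "e_s1": d["expected_cost_s1"],
        "e_s2": d["expected_cost_s2"],
        "verdict": d["verdict"],
    }
    return json.dumps(_round_cents(flat), indent=indent)
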