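"""Clinical Risk Score (CRS): additive risk-factor scoring and tier assignment.

The CRS translates the presence of wound- and patient-level risk factors into
a single additive score that indexes failure-probability ranges downstream.
Wound- or reconstruction-specific features that directly affect mechanical
stability, perfusion, implant exposure risk, or prior failure biology carry
two points; broader contextual or systemic risk amplifiers carry one point.
The score is a stratification tool, not a statistically derived predictor:
it models cumulative risk burden only and deliberately ignores interaction
effects between factors.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import InputError

__all__ = [
    "Tier",
    "RiskFactorDefinition",
    "RiskFactorCatalog",
    "CRSResult",
    "ApplicabilityFlags",
    "Applicability",
    "DEFAULT_CATALOG",
    "compute_crs",
    "assign_tier",
    "check_applicability",
]


class Tier(str, Enum):
    """Risk tier bands of the cumulative CRS."""

    LOW = "Low"
    MODERATE = "Moderate"
    HIGH = "High"
    EXTREME = "Extreme"


class RiskFactorDefinition(BaseModel):
    """One scored risk factor: an identifier, a display label, the clinical
    criteria that qualify a case for it, and its point weight (1 or 2)."""

    model_config = {"frozen": True, "extra": "forbid"}

    id: str
    label: str
    criteria: str = ""
    points: int

    @field_validator("points")
    @classmethod
    def _points_in_catalog_weights(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError(f"points must be 1 or 2, got {v}")
        return v


# Default catalog. Five 2-point wound/reconstruction-specific factors and
# three 1-point systemic amplifiers; maximum attainable score 13.
_DEFAULT_FACTORS = (
    RiskFactorDefinition(
        id="perfusion",
        label="Perfusion compromise",
        criteria="Ischemia, radiation history, tenuous tissue",
        points=2,
    ),
    RiskFactorDefinition(
        id="hardware",
        label="Hardware present",
        criteria="Instrumentation, prosthetics, implants",
        points=2,
    ),
    RiskFactorDefinition(
        id="tension",
        label="Closure tension",
        criteria="Inability to achieve tension-free closure",
        points=2,
    ),
    RiskFactorDefinition(
        id="soft_tissue",
        label="Soft tissue destruction",
        criteria="Dead space, muscle loss, tissue deficit",
        points=2,
    ),
    RiskFactorDefinition(
        id="prior_failure",
        label="Prior failure",
        criteria="Prior wound breakdown or revision",
        points=2,
    ),
    RiskFactorDefinition(
        id="contamination",
        label="Contamination",
        criteria="Non-sterile field, colonization, open wound",
        points=1,
    ),
    RiskFactorDefinition(
        id="operative",
        label="Operative factors",
        criteria="Prolonged surgery, reoperation field",
        points=1,
    ),
    RiskFactorDefinition(
        id="comorbidity",
        label="Comorbidity",
        criteria="Diabetes, obesity, immunosuppression, malnutrition",
        points=1,
    ),
)


class RiskFactorCatalog(BaseModel):
    """Ordered collection of risk-factor definitions.

    The catalog is data, not code: the default weights can be replaced by
    loading an alternative catalog from YAML/JSON without code changes
    (anticipating future re-weighting of the score).
    """

    model_config = {"frozen": True, "extra": "forbid"}

    factors: tuple[RiskFactorDefinition, ...] = _DEFAULT_FACTORS

    @model_validator(mode="after")
    def _ids_unique(self) -> "RiskFactorCatalog":
        ids = [f.id for f in self.factors]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate factor ids in catalog: {dupes}")
        return self

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.factors)

    @property
    def max_score(self) -> int:
        """Maximum attainable score (13 for the default catalog)."""
        return sum(f.points for f in self.factors)

    def points_for(self, factor_id: str) -> int:
        for f in self.factors:
            if f.id == factor_id:
                return f.points
        raise InputError(f"unknown risk factor id: {factor_id!r}")

    @classmethod
    def from_yaml(cls, text: str) -> "RiskFactorCatalog":
        return cls.model_validate(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


DEFAULT_CATALOG = RiskFactorCatalog()


class CRSResult(BaseModel):
    """Outcome of scoring one case: the additive score, its tier, and the
    factor ids that contributed."""

    model_config = {"frozen": True}

    score: int = Field(ge=0)
    tier: Tier
    contributing_factors: tuple[str, ...] = ()


def assign_tier(score: int) -> Tier:
    """Map a cumulative score to its risk tier.

    Bands: 0-2 Low, 3-5 Moderate, 6-8 High, 9+ Extreme. The top band is
    open-ended, so scores above the nominal table range (e.g. the default
    catalog's maximum of 13) are valid and map to Extreme.
    """
    if score < 0:
        raise InputError(f"score must be non-negative, got {score}")
    if score <= 2:
        return Tier.LOW
    if score <= 5:
        return Tier.MODERATE
    if score <= 8:
        return Tier.HIGH
    return Tier.EXTREME


def compute_crs(
    present_factor_ids: Iterable[str],
    catalog: RiskFactorCatalog = DEFAULT_CATALOG,
) -> CRSResult:
    """Score a case from its present risk factors.

    Scoring is additive over the catalog's point weights; duplicate ids in
    the input are deduplicated (set semantics). Unknown ids raise
    :class:`~cascade.errors.InputError` naming the offending id.
    """
    present = set(present_factor_ids)
    known = set(catalog.ids)
    unknown = sorted(present - known)
    if unknown:
        raise InputError(f"unknown risk factor id(s): {unknown}")
    # preserve catalog order in the contributing list
    contributing = tuple(i for i in catalog.ids if i in present)
    score = sum(catalog.points_for(i) for i in contributing)
    return CRSResult(score=score, tier=assign_tier(score), contributing_factors=contributing)


class ApplicabilityFlags(BaseModel):
    """Explicit clinical-judgment exclusions, independent of the scored factors.

    "Tension-free closure achievable" is a judgment about the wound, not the
    negation of the closure-tension factor, so these are declared explicitly
    in the case file rather than inferred from factor absence.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    tension_free_closure_achievable: bool = False
    no_contamination_hardware_or_perfusion: bool = False
    standard_comorbidity_burden: bool = False


_FLAG_REASONS: Mapping[str, str] = {
    "tension_free_closure_achievable": "reliable tension-free closure achievable without advanced technique",
    "no_contamination_hardware_or_perfusion": "no contamination, hardware, or perfusion compromise present",
    "standard_comorbidity_burden": "standard comorbidity burden with no additional risk amplifiers",
}


class Applicability(BaseModel):
    """Whether expected-value analysis is indicated for this wound environment.

    A "not applicable" verdict annotates the downstream computation; it never
    blocks it.
    """

    model_config = {"frozen": True}

    applicable: bool
    reasons: tuple[str, ...] = ()


def check_applicability(
    crs: CRSResult,
    flags: Optional[ApplicabilityFlags] = None,
) -> Applicability:
    """Gate the analysis to high-risk wound environments.

    Not applicable when the tier is Low (CRS 0-2) or any explicit exclusion
    flag is set; in those settings routine closure is ordinarily the
    clinically and economically appropriate strategy and the model does not
    support a different conclusion.
    """
    flags = flags or ApplicabilityFlags()
    reasons: list[str] = []
    if crs.tier is Tier.LOW:
        reasons.append("CRS 0-2 (low-risk wound environment)")
    for name, reason in _FLAG_REASONS.items():
        if getattr(flags, name):
            reasons.append(reason)
    return Applicability(applicable=not reasons, reasons=tuple(reasons))
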