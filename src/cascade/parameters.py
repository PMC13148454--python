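"""Tier-conditional parameter tables and bounded-range resolution.

Failure probabilities are literature-informed ranges stratified by risk tier:
P1 is the probability of wound failure under routine closure, P2 under
definitive reconstruction, and the absolute risk reduction dP = P1 - P2 is
always computed from the resolved point values (the published dP ranges are
carried as reference data only, since they are not the elementwise
differences of the P1/P2 ranges).

Failure trajectory cost C is organized into four Failure Cost Tiers (FCTs),
limited through catastrophic, each a bounded episode-cost range in USD with a
representative midpoint. Tier 4's range is open above ("$1,000,000+"); its
"+" affects display and Monte Carlo sampling defaults only — deterministic
arithmetic uses $1,000,000 as the upper bound.

Ranges resolve to point values under a bound policy: midpoint for typical
cases, upper bound for clustered high-risk features, lower bound for
borderline presentations, or an explicit override. Midpoints are exact
arithmetic means with no rounding.
"""

from __future__ import annotations

import logging
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import InputError
from .risk import Tier

__all__ = [
    "BoundedRange",
    "TierProbabilities",
    "ProbabilityTierTable",
    "FailureCostTier",
    "BoundPolicy",
    "DEFAULT_PROBABILITY_TABLE",
    "DEFAULT_COST_TIERS",
    "resolve_probabilities",
    "resolve_cost",
]

logger = logging.getLogger(__name__)


class BoundedRange(BaseModel):
    """Closed numeric interval; ``open_upper`` marks a '+' display suffix
    (e.g. a cost range quoted as open above its printed upper bound)."""

    model_config = {"frozen": True, "extra": "forbid"}

    lower: float
    upper: float
    open_upper: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "BoundedRange":
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) must be <= upper ({self.upper})")
        return self

    @property
    def midpoint(self) -> float:
        """Exact arithmetic mean of the bounds (the '+' is ignored)."""
        return (self.lower + self.upper) / 2.0

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def __str__(self) -> str:
        suffix = "+" if self.open_upper else ""
        return f"{self.lower:g}-{self.upper:g}{suffix}"


class TierProbabilities(BaseModel):
    """Failure-probability ranges for one risk tier.

    ``dp_range`` is the published absolute-risk-reduction range, reference
    data only: resolved dP is always P1 - P2.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    p1_range: BoundedRange
    p2_range: BoundedRange
    dp_range: BoundedRange

    @model_validator(mode="after")
    def _valid_probabilities(self) -> "TierProbabilities":
        for name in ("p1_range", "p2_range", "dp_range"):
            r = getattr(self, name)
            if not (0.0 <= r.lower and r.upper <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.p2_range.upper > self.p1_range.upper:
            raise ValueError("p2 range upper bound exceeds p1 range upper bound")
        return self


def _tp(p1: tuple, p2: tuple, dp: tuple) -> TierProbabilities:
    return TierProbabilities(
        p1_range=BoundedRange(lower=p1[0], upper=p1[1]),
        p2_range=BoundedRange(lower=p2[0], upper=p2[1]),
        dp_range=BoundedRange(lower=dp[0], upper=dp[1]),
    )


class ProbabilityTierTable(BaseModel):
    """Per-tier failure-probability ranges under each strategy."""

    model_config = {"frozen": True, "extra": "forbid"}

    tiers: dict[Tier, TierProbabilities] = Field(
        default_factory=lambda: {
            Tier.LOW: _tp((0.05, 0.10), (0.02, 0.05), (0.03, 0.05)),
            Tier.MODERATE: _tp((0.10, 0.15), (0.03, 0.07), (0.05, 0.10)),
            Tier.HIGH: _tp((0.15, 0.25), (0.05, 0.10), (0.10, 0.15)),
            Tier.EXTREME: _tp((0.25, 0.40), (0.07, 0.15), (0.15, 0.25)),
        }
    )

    @model_validator(mode="after")
    def _monotone_across_tiers(self) -> "ProbabilityTierTable":
        order = [t for t in (Tier.LOW, Tier.MODERATE, Tier.HIGH, Tier.EXTREME) if t in self.tiers]
        for a, b in zip(order, order[1:]):
            ra, rb = self.tiers[a].p1_range, self.tiers[b].p1_range
            if rb.lower < ra.lower or rb.upper < ra.upper:
                raise ValueError(f"p1 ranges must be non-decreasing across tiers ({a} -> {b})")
        return self

    def for_tier(self, tier: Tier) -> TierProbabilities:
        try:
            return self.tiers[tier]
        except KeyError:
            raise InputError(f"no probability ranges for tier {tier!r}") from None

    @classmethod
    def from_yaml(cls, text: str) -> "ProbabilityTierTable":
        return cls.model_validate(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


DEFAULT_PROBABILITY_TABLE = ProbabilityTierTable()


class FailureCostTier(BaseModel):
    """One failure-trajectory cost scenario: a bounded episode-cost range in
    USD and its representative (midpoint) value."""

    model_config = {"frozen": True, "extra": "forbid"}

    tier: int = Field(ge=1, le=4)
    scenario: str
    cost_range: BoundedRange
    representative: float

    @model_validator(mode="after")
    def _representative_in_range(self) -> "FailureCostTier":
        if not self.cost_range.contains(self.representative):
            raise ValueError(
                f"representative {self.representative} outside cost range {self.cost_range}"
            )
        return self


DEFAULT_COST_TIERS: dict[int, FailureCostTier] = {
    1: FailureCostTier(
        tier=1,
        scenario="Limited failure",
        cost_range=BoundedRange(lower=100_000, upper=250_000),
        representative=175_000,
    ),
    2: FailureCostTier(
        tier=2,
        scenario="Moderate failure trajectory",
        cost_range=BoundedRange(lower=250_000, upper=400_000),
        representative=325_000,
    ),
    3: FailureCostTier(
        tier=3,
        scenario="Severe failure trajectory",
        cost_range=BoundedRange(lower=400_000, upper=800_000),
        representative=600_000,
    ),
    4: FailureCostTier(
        tier=4,
        scenario="Catastrophic failure trajectory",
        cost_range=BoundedRange(lower=800_000, upper=1_000_000, open_upper=True),
        representative=900_000,
    ),
}


class BoundPolicy(BaseModel):
    """How a bounded range resolves to a point value.

    ``lower`` / ``midpoint`` / ``upper`` select the corresponding bound;
    ``explicit`` uses ``value`` as given. An explicit value outside the range
    logs a warning rather than failing, since actual costs and rates vary by
    year, geography and payer mix.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    kind: Literal["lower", "midpoint", "upper", "explicit"] = "midpoint"
    value: Optional[float] = None

    @model_validator(mode="after")
    def _explicit_needs_value(self) -> "BoundPolicy":
        if self.kind == "explicit" and self.value is None:
            raise ValueError("explicit policy requires a value")
        if self.kind != "explicit" and self.value is not None:
            raise ValueError(f"policy {self.kind!r} does not take a value")
        return self

    def resolve(self, rng: BoundedRange, what: str = "parameter") -> float:
        if self.kind == "lower":
            return rng.lower
        if self.kind == "upper":
            return rng.upper
        if self.kind == "midpoint":
            return rng.midpoint
        assert self.value is not None
        if not rng.contains(self.value):
            logger.warning("explicit %s %.6g outside range %s", what, self.value, rng)
        return self.value


MIDPOINT = BoundPolicy(kind="midpoint")


def resolve_probabilities(
    tier: Tier,
    table: ProbabilityTierTable = DEFAULT_PROBABILITY_TABLE,
    policy: BoundPolicy = MIDPOINT,
    p1_override: Optional[float] = None,
    p2_override: Optional[float] = None,
) -> tuple[float, float, float]:
    """Resolve (p1, p2, dp) for a risk tier.

    Overrides take precedence over policy resolution; dp = p1 - p2 exactly.
    An override pair with p2 >= p1 is rejected: the model requires an
    absolute risk reduction from reconstruction.
    """
    ranges = table.for_tier(tier)
    for name, v in (("p1", p1_override), ("p2", p2_override)):
        if v is not None and not (0.0 <= v <= 1.0):
            raise InputError(f"{name} override must be in [0, 1], got {v}")
    if policy.kind == "explicit":
        raise InputError("use p1_override/p2_override rather than an explicit bound policy")
    p1 = p1_override if p1_override is not None else policy.resolve(ranges.p1_range, "p1")
    p2 = p2_override if p2_override is not None else policy.resolve(ranges.p2_range, "p2")
    if p1_override is not None and not ranges.p1_range.contains(p1):
        logger.warning("p1 override %.4g outside %s-tier range %s", p1, tier.value, ranges.p1_range)
    if p2_override is not None and not ranges.p2_range.contains(p2):
        logger.warning("p2 override %.4g outside %s-tier range %s", p2, tier.value, ranges.p2_range)
    if p2 >= p1:
        raise InputError(
            f"no absolute risk reduction: p2 ({p2}) must be < p1 ({p1})"
        )
    return p1, p2, p1 - p2


def resolve_cost(
    fct: FailureCostTier,
    policy: BoundPolicy = MIDPOINT,
    override: Optional[float] = None,
) -> float:
    """Resolve the failure trajectory cost C for a cost tier.

    The midpoint policy returns the tier's representative value. An override
    outside the tier's range warns but is honored.
    """
    if override is not None:
        if override < 0:
            raise InputError(f"cost override must be non-negative, got {override}")
        if not fct.cost_range.contains(override):
            logger.warning(
                "cost override %.6g outside tier %d range %s", override, fct.tier, fct.cost_range
            )
        return float(override)
    if policy.kind == "midpoint":
        return float(fct.representative)
    return float(policy.resolve(fct.cost_range, "cost"))
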