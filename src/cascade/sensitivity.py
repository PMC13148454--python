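"""Deterministic and probabilistic sensitivity analysis of the decision rule.

Deterministic: a two-way threshold grid (failure cost x absolute risk
reduction, each cell the maximum justified incremental cost dP * C), and
one-way sweeps that recompute the full decision while varying a single
input.

Probabilistic: a seeded Monte Carlo analysis that propagates the published
parameter ranges through the rule. Each draw samples (p1, p2, C) from
configurable distributions — uniform over the range by default, triangular
with mode at the midpoint to reflect midpoint-typical guidance, a point
mass, or an equal-weight discrete support — computes the verdict at a fixed
dC, and reports the fraction of draws in which reconstruction is favored
with its Monte Carlo standard error. p1 and p2 are sampled jointly: p1 from
its range, then p2 from its range truncated above at p1 by rejection, which
preserves both marginals and the p2 < p1 ordering; the rejection rate is
reported.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .decision import DecisionInputs, Verdict, decide, decision_threshold, expected_costs
from .errors import CascadeError, InputError
from .parameters import BoundedRange

__all__ = [
    "DEFAULT_GRID_COSTS",
    "DEFAULT_GRID_DPS",
    "ThresholdGrid",
    "two_way_grid",
    "one_way",
    "Distribution",
    "PSAConfig",
    "PSAResult",
    "run_psa",
    "enumerate_psa_exact",
]

#: Default grid axes: the four representative failure-cost-tier values and
#: the canonical absolute-risk-reduction column values.
DEFAULT_GRID_COSTS: tuple[float, ...] = (175_000.0, 325_000.0, 600_000.0, 900_000.0)
DEFAULT_GRID_DPS: tuple[float, ...] = (0.05, 0.10, 0.13, 0.20, 0.25)

_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


class ThresholdGrid:
    """Outer-product threshold table: rows are failure costs (ascending),
    columns are dP values (ascending), cells are dP * C in USD."""

    def __init__(self, costs: Sequence[float], dps: Sequence[float]):
        if len(costs) == 0 or len(dps) == 0:
            raise InputError("grid axes must be non-empty")
        if any(c < 0 for c in costs):
            raise InputError("costs must be non-negative")
        if any(not (0.0 <= d <= 1.0) for d in dps):
            raise InputError("dP values must lie in [0, 1]")
        self.costs = tuple(sorted(float(c) for c in costs))
        self.dps = tuple(sorted(float(d) for d in dps))
        cells = np.outer(self.costs, self.dps)
        self.table = pd.DataFrame(
            cells,
            index=pd.Index([f"{c:,.0f}" for c in self.costs], name="cost"),
            columns=pd.Index([f"{d:g}" for d in self.dps], name="dP"),
        )

    def cell(self, cost: float, dp: float) -> float:
        i = self.costs.index(float(cost))
        j = self.dps.index(float(dp))
        return float(self.table.iat[i, j])

    def to_csv(self) -> str:
        return self.table.to_csv()


def two_way_grid(
    costs: Sequence[float] = DEFAULT_GRID_COSTS,
    dps: Sequence[float] = DEFAULT_GRID_DPS,
) -> ThresholdGrid:
    """Two-way deterministic sensitivity analysis over cost and dP axes."""
    return ThresholdGrid(costs, dps)


_SWEEPABLE = ("p1", "p2", "c", "delta_c")


def one_way(inputs: DecisionInputs, parameter: str, values: Sequence[float]) -> pd.DataFrame:
    """One-way sweep: recompute the full decision with a single input varied.

    Returns a tidy frame with one row per value: the substituted value, the
    threshold, both expected costs, and the verdict.
    """
    if parameter not in _SWEEPABLE:
        raise InputError(f"unknown parameter {parameter!r}; choose from {_SWEEPABLE}")
    rows = []
    for v in values:
        varied = inputs.model_copy(update={parameter: float(v)})
        varied = DecisionInputs.model_validate(varied.model_dump())  # re-check invariants
        e1, e2 = expected_costs(varied)
        thr = decision_threshold(varied.p1, varied.p2, varied.c)
        rows.append(
            {
                "parameter": parameter,
                "value": float(v),
                "threshold": thr,
                "expected_cost_s1": e1,
                "expected_cost_s2": e2,
                "verdict": decide(varied.delta_c, thr).value,
            }
        )
    return pd.DataFrame(rows)


class Distribution(BaseModel):
    """Sampling distribution for one PSA parameter.

    kinds: ``uniform`` over ``range``; ``triangular`` over ``range`` with
    mode at the midpoint; ``point`` mass at ``value``; ``discrete`` with
    equal weight on ``values``.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    kind: Literal["uniform", "triangular", "point", "discrete"]
    range: Optional[BoundedRange] = None
    value: Optional[float] = None
    values: Optional[tuple[float, ...]] = None

    @model_validator(mode="after")
    def _fields_match_kind(self) -> "Distribution":
        if self.kind in ("uniform", "triangular") and self.range is None:
            raise ValueError(f"{self.kind} distribution requires a range")
        if self.kind == "point" and self.value is None:
            raise ValueError("point distribution requires a value")
        if self.kind == "discrete" and not self.values:
            raise ValueError("discrete distribution requires values")
        return self

    @classmethod
    def point(cls, value: float) -> "Distribution":
        return cls(kind="point", value=value)

    @classmethod
    def uniform(cls, lower: float, upper: float) -> "Distribution":
        return cls(kind="uniform", range=BoundedRange(lower=lower, upper=upper))

    @classmethod
    def triangular(cls, lower: float, upper: float) -> "Distribution":
        return cls(kind="triangular", range=BoundedRange(lower=lower, upper=upper))

    @classmethod
    def discrete(cls, values: Sequence[float]) -> "Distribution":
        return cls(kind="discrete", values=tuple(values))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, float(self.value))
        if self.kind == "discrete":
            return rng.choice(np.asarray(self.values, dtype=float), size=n)
        assert self.range is not None
        lo, hi = self.range.lower, self.range.upper
        if lo == hi:
            return np.full(n, float(lo))
        if self.kind == "uniform":
            return rng.uniform(lo, hi, size=n)
        return rng.triangular(lo, (lo + hi) / 2.0, hi, size=n)

    @property
    def support(self) -> Optional[tuple[float, ...]]:
        """Finite support, if the distribution has one (point/discrete)."""
        if self.kind == "point":
            return (float(self.value),)
        if self.kind == "discrete":
            return tuple(float(v) for v in self.values)
        return None


class PSAConfig(BaseModel):
    """Configuration of one probabilistic sensitivity analysis run."""

    model_config = {"frozen": True, "extra": "forbid"}

    p1: Distribution
    p2: Distribution
    c: Distribution
    delta_c: float = Field(ge=0)
    n_samples: int = Field(ge=1)
    seed: int


class PSAResult(BaseModel):
    """Summary of a PSA run.

    ``probability_favored`` is the fraction of draws with dC strictly below
    the sampled threshold; its Monte Carlo standard error is
    sqrt(p(1-p)/n). Quantiles are reported for the threshold and for the
    expected-cost difference E[S2] - E[S1] = dC - dP*C.
    """

    model_config = {"frozen": True}

    probability_favored: float = Field(ge=0, le=1)
    mc_standard_error: float
    threshold_mean: float
    threshold_quantiles: dict[str, float]
    cost_diff_mean: float
    cost_diff_quantiles: dict[str, float]
    n_effective: int
    rejection_rate: float


_MAX_REJECTION_ROUNDS = 1000


def _sample_joint_probabilities(
    config: PSAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw (p1, p2) pairs with p2 < p1 via per-draw rejection on p2."""
    n = config.n_samples
    p1 = config.p1.sample(rng, n)
    p2 = config.p2.sample(rng, n)
    total_p2_draws = n
    rejected = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = p2 >= p1
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        rejected += n_bad
        total_p2_draws += n_bad
        p2[bad] = config.p2.sample(rng, n_bad)
    else:
        rate = rejected / total_p2_draws
        raise CascadeError(
            f"could not enforce p2 < p1: rejection rate {rate:.3f} after "
            f"{_MAX_REJECTION_ROUNDS} resampling rounds (p2 support may sit at "
            "or above p1)"
        )
    return p1, p2, rejected / total_p2_draws


def run_psa(config: PSAConfig) -> PSAResult:
    """Run a seeded Monte Carlo PSA; bit-identical results per (config, seed)."""
    rng = np.random.default_rng(config.seed)
    p1, p2, rejection_rate = _sample_joint_probabilities(config, rng)
    c = config.c.sample(rng, config.n_samples)
    threshold = (p1 - p2) * c
    cost_diff = config.delta_c - threshold  # E[S2] - E[S1], c0-free
    favored = config.delta_c < threshold
    p_fav = float(favored.mean())
    n = config.n_samples
    se = math.sqrt(p_fav * (1.0 - p_fav) / n)

    def _q(x: np.ndarray) -> dict[str, float]:
        qs = np.quantile(x, _QUANTILES)
        return {f"q{int(1000 * q) / 10:g}": float(v) for q, v in zip(_QUANTILES, qs)}

    return PSAResult(
        probability_favored=p_fav,
        mc_standard_error=se,
        threshold_mean=float(threshold.mean()),
        threshold_quantiles=_q(threshold),
        cost_diff_mean=float(cost_diff.mean()),
        cost_diff_quantiles=_q(cost_diff),
        n_effective=n,
        rejection_rate=rejection_rate,
    )


def enumerate_psa_exact(config: PSAConfig) -> float:
    """Exhaustive probability_favored for finite-support distributions.

    Independent brute-force oracle for :func:`run_psa`: enumerates the joint
    support of (p1, p2, c), conditions on p2 < p1, and returns the exact
    probability that dC < dP * C. Requires all three distributions to have
    finite support.
    """
    supports = [config.p1.support, config.p2.support, config.c.support]
    if any(s is None for s in supports):
        raise InputError("exact enumeration requires point or discrete distributions")
    s1, s2, sc = supports
    # The sampler conditions p2 on the drawn p1 (resampling p2 until p2 < p1),
    # so each p1 value carries equal mass and p2 is uniform over its valid
    # sub-support; mirror that weighting here.
    prob = 0.0
    for a in s1:
        valid_b = [b for b in s2 if b < a]
        if not valid_b:
            raise CascadeError(f"p2 support has no value below p1 = {a}")
        inner = 0.0
        for b in valid_b:
            inner += sum(1.0 for cc in sc if config.delta_c < (a - b) * cc) / len(sc)
        prob += inner / len(valid_b)
    return prob / len(s1)
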