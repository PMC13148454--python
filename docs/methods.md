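# Methods

## Model

The package compares two index strategies for a complex wound on expected
total episode cost. Failure is modeled as a Bernoulli event per episode:
probability P₁ under routine closure, P₂ under definitive reconstruction,
with P₂ < P₁ required (the model is only meaningful when reconstruction
buys an absolute risk reduction ΔP = P₁ − P₂). A failure costs C, the
expected total episode expenditure conditional on failure — facility,
perioperative, and post-acute, with physician professional fees excluded by
construction since they shift both strategies equally. Reconstruction adds
ΔC at the index operation. Expected costs are E[S₁] = C₀ + P₁C and
E[S₂] = C₀ + ΔC + P₂C; the verdict is the sign of ΔC − ΔP·C. The baseline
cost C₀ is retained so expected costs can be reported as totals, but it
cancels from the comparison and the verdict provably never depends on it
(enforced by a property test).

Assumptions worth stating: failure is binary (no partial trajectories);
probabilities and costs are independent inputs (no correlation between how
likely a failure is and how much it costs, within a tier); and intermediate
strategies (staged debridement, NPWT bridging, delayed closure) are not
separate strategy objects — they are expressed by choosing ΔC, P₂, and C
accordingly.

## Risk score and applicability

The Clinical Risk Score is additive over eight factors: five 2-point
wound/reconstruction-specific features (perfusion compromise, hardware,
closure tension, soft tissue destruction, prior failure) and three 1-point
systemic amplifiers (contamination, operative factors, comorbidity). Tier
bands are 0–2 Low, 3–5 Moderate, 6–8 High, 9+ Extreme. The catalog's
nominal score range is quoted as 0–12 in places, but the point weights sum
to 13; the implementation accepts 13 and maps it to the open-ended Extreme
band rather than capping, since rejecting a valid factor combination would
be wrong. The catalog is data, not code: alternative weights load from
YAML/JSON without code changes, anticipating future re-weighting by
regression or Delphi methods. Interaction effects between factors are
deliberately not modeled.

Applicability is an annotation, never a gate on computation: Low-tier cases
and cases carrying an explicit exclusion flag (tension-free closure
achievable; no contamination/hardware/perfusion compromise; standard
comorbidity burden) are marked not-applicable but still evaluate. The
flags are explicit booleans in the case file rather than inferences from
factor absence, because "tension-free closure achievable" is a clinical
judgment, not the negation of the scored closure-tension factor.

## Parameters and range resolution

Probability ranges per tier (P₁ / P₂): Low 0.05–0.10 / 0.02–0.05, Moderate
0.10–0.15 / 0.03–0.07, High 0.15–0.25 / 0.05–0.10, Extreme 0.25–0.40 /
0.07–0.15. Failure cost tiers: 1 limited $100k–$250k, 2 moderate
$250k–$400k, 3 severe $400k–$800k, 4 catastrophic $800k–$1M+ with
representatives at the midpoints (175k / 325k / 600k / 900k).

Two numerical choices here:

- **ΔP is always computed as resolved P₁ − P₂.** The published ΔP ranges
  are not the elementwise differences of the P₁/P₂ ranges (High: quoted
  0.10–0.15, interval arithmetic gives 0.05–0.20), so treating ΔP as an
  independent input would break the algebraic identity the whole model
  rests on. The quoted ΔP ranges ship as reference data (`dp_range`) and
  participate in no arithmetic.
- **Midpoints are exact arithmetic means, never rounded.** The canonical
  worked examples round some midpoints (High-tier P₂ printed as 0.07 where
  the mean is 0.075; Low-tier 0.04 vs 0.035). Reproducing those examples
  therefore uses explicit overrides at the printed values; the default
  midpoint policy keeps the exact means. An explicit value outside its
  tier's range logs a warning rather than failing, since real costs vary
  by year, geography, and payer mix.
- **Tier 4's "+"** affects display and sampling defaults only;
  deterministic arithmetic uses $1,000,000 as the upper bound, and PSA
  samples on [800k, 1M] (an unbounded range cannot be sampled without
  inventing a tail; an override exists).

## Decision tolerance

The three-way rule defines "indeterminate" on real-valued equality
ΔC = ΔP·C, which is meaningless in floating point. The implementation uses
a configurable band: |ΔC − threshold| ≤ max(10⁻⁹·threshold, $0.005). The
defaults are our choice (tight enough that no realistic dollar input is
indeterminate by accident, wide enough to absorb float error); no rounding
convention is prescribed by the framework itself.

## Sensitivity analysis

The deterministic two-way grid is the outer product of the four
representative tier costs and ΔP ∈ {0.05, 0.10, 0.13, 0.20, 0.25}; every
cell equals the decision threshold on the same inputs (tested). The
directional-robustness claim — thresholds exceed $50,000 whenever CRS ≥ 6
and ΔP ≥ 0.10 — is checked for the Tier 3–4 cost rows only: the Tier 2 row
contains $32,500 at ΔP = 0.10, so the claim evidently presumes high-risk
cases select severe-or-worse cost tiers, and we assert it exactly there.

The PSA propagates parameter ranges through the rule by seeded Monte Carlo
(numpy `default_rng`). Distributions per parameter: uniform over the range
(default), triangular with mode at the midpoint (reflecting
midpoint-for-typical-cases guidance), point mass, or equal-weight discrete
support. No joint distribution for (P₁, P₂) is prescribed anywhere, so we
sample P₁ from its range and then P₂ from its range truncated above at the
drawn P₁ by rejection (resampling P₂ only). This preserves the P₁ marginal
and the ordering constraint; the P₂ marginal is conditioned, and the
rejection rate is reported so users can see how much. If the constraint is
unsatisfiable the run fails with the rejection rate after 1,000 resampling
rounds rather than looping. `probability_favored` counts draws with
ΔC strictly below the sampled threshold; its Monte Carlo standard error is
√(p(1−p)/n). An exhaustive-enumeration oracle (`enumerate_psa_exact`)
computes the exact probability for finite supports, mirroring the
conditional weighting of the sampler, and the test suite checks the
sampler against it.

## Cohort arithmetic

Avoided-event bounds use interval-style corner pairing, not a confidence
interval: lower bound = n·(baseline.lower − intervention.lower), upper
bound = n·(baseline.upper − intervention.lower), the widest corner. With
baseline 15–25% and intervention 5–10% per 100 cases this yields the
canonical 10–20 avoided events; note the upper bound pairs the high
baseline with the *low* intervention rate — elementwise upper-minus-upper
would give 15. Exposure bounds pair low events with the low cost bound and
high with high, then normalize per case. Institutional exposure is the
plain product n · rate · cost at each cost bound.

`simulate_cohort` realizes the same identities stochastically: Bernoulli
failure per episode, uniform cost draw on failure, ΔC up front in the
reconstruction arm. Its empirical per-episode cost difference converges to
ΔP·E[C] − ΔC; the acceptance test checks recovery within 3 Monte Carlo
standard errors at 100,000 episodes per arm, which runs in well under a
second and gives a standard error of roughly $900 against the $28,000
analytic difference in the reference configuration.

## Synthetic cases

The generator draws factor presence independently per factor at
configurable prevalence (default 0.3 per factor — roughly centers generated
cohorts on the Moderate/High boundary where the decision is interesting),
assigns the failure cost tier from the resulting risk tier (Low→1,
Moderate→2, High→3, Extreme→4, mirroring the worked examples), and draws
ΔC uniformly from $20k–$80k, the range the threshold grid identifies as
spanning the favored/not-favored boundary across tiers. Real risk factors
co-occur; an optional equicorrelation knob (one-factor Gaussian-copula
thresholding) exists for stress tests, but no empirical correlation
structure is represented. Generated cohorts therefore validate the
arithmetic and the plumbing, not real-world prevalence, cost, or
correlation patterns — passing tests say nothing about clinical
calibration, which the underlying framework itself has not established.

## Known limitations

The framework's inputs are literature-informed ranges, not measured data;
this package faithfully computes with them but cannot validate them. No
inflation, geography, or payer adjustment; no QALYs, value-of-information,
or acceptability curves beyond probability-favored-vs-ΔC; no interaction
terms in the risk score; readmission-penalty and documentation domains are
carried as qualitative report metadata only. The illustrative two-patient
contrast (~$560k differential) is not reproducible from any single stated
arithmetic and is deliberately not asserted anywhere.
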