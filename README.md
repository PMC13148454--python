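# cascade

Expected-value decision analysis for complex wound reconstruction.

In high-risk wounds — posterior spine instrumentation, oncologic resection,
trauma reconstruction, diabetic limb salvage — the economic consequence of
the index operative choice is not the procedure's price but the episode
trajectory it sets in motion. A failed closure can progress through
infection, reoperation, prolonged hospitalization, and post-acute care,
multiplying total episode expenditure several-fold. This package implements
a decision framework that makes that downstream exposure visible at the
point of decision, for reconstructive surgeons, health-economics analysts,
and service-line planners.

## The model

Two mutually exclusive index strategies are compared: S₁, routine closure,
and S₂, definitive reconstruction. With baseline episode cost C₀, failure
probabilities P₁ and P₂, failure trajectory cost C (total episode
expenditure conditional on failure), and incremental reconstruction cost
ΔC, the expected total episode costs are

    E[Cost | S₁] = C₀ + P₁·C
    E[Cost | S₂] = C₀ + ΔC + P₂·C

so reconstruction is favored on expected-value grounds exactly when

    ΔC < (P₁ − P₂)·C = ΔP·C

C₀ cancels from the comparison; physician professional fees are excluded by
construction. The rule is bidirectional: in low-risk environments it favors
routine closure, in high-risk ones reconstruction.

Around this rule the package provides:

- **Clinical Risk Score (CRS)** — an additive 0–13 point score over eight
  wound/patient risk factors that stratifies cases into Low / Moderate /
  High / Extreme tiers and gates applicability (the analysis is not
  indicated for low-risk wounds).
- **Parameter tables** — tier-conditional probability ranges and four
  failure cost tiers (limited → catastrophic, $100k → $1M+), resolved to
  point values by a bound policy (lower / midpoint / upper / explicit).
- **Sensitivity analysis** — the deterministic two-way threshold grid
  (cost × ΔP), one-way sweeps, and a seeded Monte Carlo probabilistic
  sensitivity analysis over the parameter ranges.
- **Cohort modeling** — avoided failure events and avoided cost exposure
  for hypothetical cohorts, institutional annual exposure, and a stochastic
  cohort simulation.
- **Synthetic case generation** — seeded case files with configurable
  factor prevalences, so everything is testable end-to-end with no
  external data.

## Worked example

A high-risk posterior spine wound: spinal instrumentation (2), compromised
perfusion (2), dead space (2), prolonged operative time (1), and
diabetes/obesity (1) give CRS 8 → High tier. The severe failure cost tier
(Tier 3) applies, with the tier's published point probabilities supplied as
overrides:

```sh
$ cat case.json
{"case_id": "hi", "factors": ["hardware", "perfusion", "soft_tissue",
 "operative", "comorbidity"], "fct": 3, "delta_c": 50000,
 "overrides": {"p1": 0.20, "p2": 0.07}}
$ cascade decide case.json
{
  "case_id": "hi",
  "crs": 8,
  "tier": "High",
  ...
  "p1": 0.2,
  "p2": 0.07,
  "dp": 0.13,
  "c": 600000.0,
  "threshold": 78000.0,
  "e_s1": 120000.0,
  "e_s2": 92000.0,
  "verdict": "reconstruction_favored"
}
```

A 13-percentage-point risk reduction against a $600,000 failure trajectory
justifies up to $78,000 of incremental reconstruction cost; at ΔC = $50,000
the expected episode cost falls from $120,000 to $92,000, so reconstruction
is favored. Raising the cost assumption to $800,000 (`cascade sensitivity
--one-way case.json --param c --values 600000,800000`) moves the threshold
to $104,000. The same case through `cascade psa case.json --n 10000 --seed
42` propagates the full High-tier and Tier-3 ranges through the rule and
reports the fraction of draws in which reconstruction remains favored.

Other entry points: `cascade score` (CRS, tier, applicability), `cascade
sensitivity --grid` (the full threshold grid as CSV), `cascade cohort`
(avoided-exposure bounds for a 100-case cohort), `cascade generate`
(synthetic case files), `cascade params` (the default tables).

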