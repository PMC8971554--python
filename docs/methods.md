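# Methods

This note documents the model implemented by `osteosim`, the
conventions chosen where the design was genuinely open, what the
synthetic parameter generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure and cycle order

The model is an individual-level state-transition (Markov
microsimulation) model with annual cycles and a lifetime horizon
(maximum age 105, configurable). Health states are no fracture, post
clinical vertebral fracture, post hip fracture, and death; hip
dominates vertebral in state assignment and long-term utility. Each
woman carries her own event history: per-site fracture counts, the
time since her last hip fracture, and her position in the treatment
course. At most one fracture occurs per cycle; hip fractures are
capped at two per lifetime; wrist and other osteoporotic fractures
recur without limit but are one-time cost/disutility events that do
not move the health state.

Within a cycle the order is: persistence decision (if on treatment) →
fracture event → cost and utility accrual → mortality → clock updates.
Fracture precedes death, so a fracture and death can co-occur in one
cycle; the first-year fracture cost is then still charged (a
conservative cost attribution) while the cycle's utility is zeroed —
a cycle's utility accrues only if the woman survives it, so with zero
discounting and unit utility, QALYs equal realized whole life-years
exactly. No half-cycle correction is applied; cycle-k quantities
discount by (1+r)^−k. These conventions are isolated in the economics
module.

## Fracture risk

Annual site-specific rates are converted to a single per-cycle event
probability by the exponential-total construction: with hazards
`h_s = incidence(age, s) × RR_s`, the fracture probability is
`1 − exp(−Σ h_s)`, allocated across sites proportionally to their
hazards (the standard rate-to-probability bridge for competing
events). Once two hip fractures have occurred the hip hazard is forced
to zero.

Incidence for the osteoporotic target population is derived from
population rates by the prevalence/relative-risk partition
`i_osteo = i·r / (p·r + 1 − p)`, which conserves the population
average when subgroup and complement are recombined (`p` osteoporosis
prevalence, `r` fracture relative risk of the osteoporotic subgroup).
The generator applies this calibration uniformly to all four sites,
including the wrist/other curves whose real-world sources are
non-Chinese registries; whether a site-restricted calibration would be
more faithful is unknowable from the available sources, so uniformity
was chosen and is flagged here.

## Mortality

Background mortality follows the life table. After a hip fracture,
mortality is multiplied by `1 + af·(RR − 1)` with the short-term RR in
the fracture year itself and the long-term RR in every later year for
life, capped at probability 1. The attributable fraction `af = 0.25`
reflects that comorbidity, not the fracture, drives most of the
observed excess. A second hip fracture resets the short-term clock (an
assumption: event recency governs risk). Vertebral, wrist and other
fractures confer no excess mortality.

## Treatment, persistence, offset

Strategies are ordered phases of (drug, duration, doses/year); the
presets are DEN/ZOL = denosumab 3y (2 doses/y) then zoledronic acid 3y
(1 dose/y), ZOL mono = zoledronic acid 3y, and the empty no-treatment
strategy. Sequential gating is strict: only completers of a phase
enter the next.

Persistence is evaluated once per treatment year at the cycle start,
from the cumulative schedule via conditional probabilities
`p[y]/p[y−1]` — even for biannual denosumab, whose sub-annual
discontinuation appears only through the one-dose cost rule. A
persisting year confers the drug's full site-specific relative risk;
a discontinuation year confers none. The "persistence 10% higher"
scenario multiplies each cumulative value by 1.10 capped at 1
(simplest reading of the label).

After stopping — by discontinuation or completion — the relative risk
rises **linearly** from the drug's on-treatment value to 1 across the
offset duration (the prevailing convention in osteoporosis CEA; the
published sources state a residual period but not a shape). Offset
durations: denosumab fixed 1 year; zoledronic acid equal to its years
taken. The waning curve is evaluated at cycle midpoints: a
discontinuer stops at the cycle start (her discontinuation cycle sits
at elapsed time 0.5), a completer at the cycle end (her first
post-treatment cycle sits at 0.5). With offset 0 the relative risk is
exactly 1 in every post-treatment cycle. The offset applies uniformly
across fracture sites per drug, and only the most recent drug's effect
wanes — re-initiation and the denosumab-discontinuation rebound are
not modelled (the latter motivates sequencing but is not parameterized
in the sources).

## Costs and utilities

Per-cycle cost components: drug doses × cost/dose × compliance in a
persisting year (exactly one dose plus its administration for a
discontinuer, mirroring the one-dose charging rule); per-dose
administration plus annual physician visit and DXA scan while on
treatment; the first-year cost of any fracture event; and the annual
long-term care cost in every post-hip year except the event year
itself — charged for life, as the duration is unstated in the sources
(config-exposed).

Utility in a cycle is the age-band EQ-5D baseline times the event
site's first-year multiplier (hip or vertebral event), otherwise the
subsequent-year multiplier of the worst prior fracture (hip below
vertebral); wrist/other events subtract an absolute one-time QALY
decrement (the sources distinguish "multipliers" from "one-time
disutility"); the result is floored at 0.

## Comparison summaries

ΔC, ΔE, ICER = ΔC/ΔE with dominance codes ("dominant" cheaper and no
less effective; "dominated" costlier and no more effective), NMB =
λ·ΔE − ΔC and NHB = ΔE − ΔC/λ. The identity NHB·λ = NMB is enforced to
1e−9 relative. Published base-case tables in this literature
occasionally print NHB values inconsistent with NMB/λ at the stated
threshold; `osteosim` always reports the identity-consistent value.
Numbers are stored at full precision; `--paper-rounding` renders
2-decimal tables.

## Random numbers and common-random-number design

Every cycle consumes exactly four uniforms per individual
(persistence, fracture occurrence, site allocation, mortality),
whether or not each is needed, and the stream depends only on the
master seed and the problem shape — never on the strategy. Strategies
evaluated with the same seed therefore share common random numbers,
which makes paired contrasts (scenario deltas, efficacy monotonicity,
null-efficacy identity) exact rather than statistical. The scalar
reference path (`simulate_individual`) and the vectorized population
path are bit-identical for a shared generator; the test suite asserts
this, so the fast path is validated against the readable one.

A caveat on monotonicity: lowering treatment relative risks can, for
rare individual trajectories, *increase* a fracture count through
feedback channels — surviving a prevented hip fracture leaves more
years at risk, and the two-hip cap silences hazards for the
higher-risk arm. The elementwise monotonicity guarantee is therefore
exact (and tested) in configurations without those feedbacks, and
holds as a mean-level direction on the full model.

## Synthetic parameter generation

No machine-readable parameter supplement accompanies the published
Chinese analyses, so the generator produces the full input set from a
seeded profile, emulating structure rather than copying values:

- **Mortality**: Gompertz `m(a) = m0·e^{b(a−50)}` with m0 ∈
  [0.002, 0.003], b ∈ [0.105, 0.115], forced to 1 at age 105 — life
  expectancy at 65 of roughly two decades, survival to 105 well under
  1%, mortality ≥ 0.5 by age 104.
- **Incidence**: exponential age curves (strictly increasing for hip
  and clinical vertebral, nearly flat for wrist/other), calibrated to
  the osteoporotic subgroup with prevalence ~0.28–0.36 and subgroup
  relative risk ~1.8–2.2, sized so lifetime hip risk from 65 lands
  near 10–20% and clinical vertebral near 35–50% — the ranges
  reported for osteoporotic Chinese women.
- **Efficacy**: trial-network-style relative risks (e.g. denosumab
  vertebral ~0.32, zoledronic hip ~0.59) jittered within their 95%
  bounds, always < 1.
- **Persistence**: injection-grade cumulative schedules (~0.95→0.80
  denosumab, ~0.92→0.75 zoledronic acid over 3 years), non-increasing
  by construction; compliance 1.0 for both injectables.
- **Costs (2020 USD)**: denosumab ~$160/dose, zoledronic acid
  ~$430/dose, hip fracture ~$4,800 first year, vertebral ~$2,600,
  long-term hip care ~$500/year, ±10% lognormal jitter.
- **Utilities**: baseline ~0.88 at 50 declining ~0.022 per 5-year
  band; first-year multipliers ~0.55 (hip) / 0.68 (vertebral);
  subsequent ~0.84 / 0.93; one-time decrements 0.03 (wrist) / 0.05
  (other).

The same profile always regenerates the identical set, and every
generated set passes the full validator. What the generator does
*not* emulate: real Chinese surveillance data, correlations between
parameters, secular trends, or heterogeneity between women beyond
stochastic realization. Passing tests therefore demonstrate the
correctness and internal consistency of the machinery under realistic
conditions — not the empirical cost-effectiveness of the drugs, whose
published headline numbers depend on inputs that are not openly
available.

## Probabilistic sensitivity analysis

PSA distributions are auto-derived by moment matching: lognormal for
relative risks (median at the point estimate, sigma from the 95%
bound ratio), gamma for costs (15% coefficient of variation), beta for
utility multipliers and disutilities. Persistence schedules and the
baseline utility age-curve are excluded from sampling — drawing them
independently per-element would break their monotone structure, and
the sources give no joint distribution. Draws failing validation are
rejected and redrawn (bounded retries). Zero spread denotes a point
mass, which makes degenerate-PSA collapse tests exact. A net monetary
benefit of exactly zero counts as *not* cost-effective on the CEAC
(strict inequality).

The outer/inner defaults are 200 parameter draws × 5,000 individuals
— the package's desk-scale sizing; cluster-scale runs
(1,000 × 100,000) are a matter of arguments, not code changes.

## Cohort oracle

The validation oracle is a forward recursion over the exact state
distribution of the model under deterministic treatment: states are
(hip count 0/1/2, vertebral-ever), which — because the short-term
mortality excess coincides with the event cycle and long-term
accruals depend only on history flags — reproduces the
microsimulation's expected costs, QALYs and fracture counts exactly,
wrist/other events included. An optional "ever had site s" flag
yields cumulative fracture probabilities with death as a competing
risk. The only rejected feature is stochastic persistence (the error
names it); equivalence tests force persistence to 1. Occupancy is
reported aggregated to the five conventional states and must sum to
1 at every cycle to 1e−12.

## Numerical conventions and degenerate inputs

Discount factors use exact integer powers; scalar and vectorized
paths use identical operation order so they agree bitwise. Zero total
hazard yields a certain no-event cycle; zero offset yields an
immediate return to RR 1; a zero-width PSA distribution consumes no
randomness; utilities are floored at 0; mortality is capped at 1.
Ages are integer years with no interpolation — parameters are stored
per integer age, and an age outside a grid is an error, never an
extrapolation.

## Known limitations

- Adverse events, re-initiation after discontinuation, and the
  denosumab rebound effect are out of scope.
- Costs are treated as pre-converted 2020 USD constants (¥6.8974/$ is
  a documented constant, not a runtime feature); no CPI machinery.
- The one-dose rule charges a discontinuer one dose regardless of
  drug, although an annual zoledronic infusion arguably delivers a
  full treatment year; the sources state the rule without resolving
  this, and the charge-one-dose reading is implemented.
- Pairwise comparisons only; no efficiency frontier across more than
  two strategies, no EVPI/EVPPI, no two-way DSA.
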