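# osteosim

Individual-level Markov microsimulation for the health-economic
evaluation of anti-osteoporosis treatment sequences in postmenopausal
women, built around the comparison of sequential denosumab/zoledronic
acid (biannual subcutaneous denosumab for 3 years followed by annual
intravenous zoledronic acid for 3 years) against zoledronic acid
monotherapy for 3 years and against no treatment, from a healthcare
payer perspective in 2020 USD.

It is written for health-economics researchers and methodologists who
need a transparent, fully scriptable alternative to GUI decision-tree
tools: every parameter is an inspectable YAML document, every analysis
is reproducible from a seed, and the simulation engine is validated
against an exact cohort recursion.

## The model

Women enter at an initiation age (65, 70, 75 or 80) with no fracture
history and are simulated in annual cycles until death or age 105
through four health states — no fracture, post clinical vertebral
fracture, post hip fracture, death — with at most one fracture per
cycle, at most two hip fractures per lifetime, and unlimited clinical
vertebral, wrist and other osteoporotic fractures (the latter two are
one-time cost/disutility events that leave the state unchanged).

Per cycle, competing fracture hazards are combined as

    h_s = i(a, s) · RR_s(t),   P(fracture) = 1 − exp(−Σ_s h_s),

with the event allocated across sites s proportionally to `h_s`.
`i(a, s)` is the age- and site-specific incidence of the osteoporotic
population, obtained from population rates by the prevalence/relative-
risk partition `i_osteo = i · r / (p·r + 1 − p)`. The treatment
relative risk `RR_s(t)` applies in full during each persisting
treatment year and, after stopping, rises linearly back to 1 over the
offset period (1 year for denosumab; time-on-treatment for zoledronic
acid). Persistence is sampled once per treatment year from the
cumulative persistence schedule; only completers of the denosumab
course proceed to zoledronic acid. A hip fracture raises mortality to
`m(a)·(1 + af·(RR_excess − 1))` with a short-term excess in the
fracture year and a long-term excess thereafter, of which only a
fraction `af = 0.25` is attributed to the fracture itself.

Costs (drug × persistence × compliance with a one-dose charge for
first-dose discontinuers, administration and monitoring, first-year
fracture costs, lifelong annual care after hip fracture) and utilities
(age-specific EQ-5D baseline, first-year and subsequent-year
multipliers for hip/vertebral, one-time decrements for wrist/other)
accrue per cycle and discount at 3%/year. Strategies are compared by

    ICER = ΔC/ΔE,   NMB = λ·ΔE − ΔC,   NHB = ΔE − ΔC/λ,

at willingness-to-pay thresholds λ of $31,512/QALY (3× China 2020 per
capita GDP) and $10,504/QALY (1×).

Because the numeric inputs of published Chinese analyses are not
openly deposited, the package generates realistic synthetic parameter
sets (seeded, validated, written to the same config format); the
science of the engine is independent of which parameter set it runs.

## Worked example

```python
import osteosim as o

ps = o.generate_parameter_set(o.GeneratorProfile(seed=0))   # synthetic inputs
seed = 1
den = o.run_strategy(ps, o.DEN_ZOL, 80, 100_000, seed)      # common random numbers
zol = o.run_strategy(ps, o.ZOL_MONO, 80, 100_000, seed)
c = o.compare_strategies(den, zol, ps.analysis.wtp_primary)
print(f"ICER={c.icer:.2f} NMB={c.nmb:.2f} NHB={c.nhb:.4f}")
```

prints

```
ICER=7657.04 NMB=600.83 NHB=0.0191
```

i.e. at initiation age 80 under these synthetic inputs, the sequential
strategy costs $7,657 per QALY gained versus zoledronic acid
monotherapy — far below the $31,512 threshold, hence the positive net
monetary benefit ($600.83 per woman) and net health benefit (0.0191
QALYs). The same run reports per-strategy means, e.g. `den.mean_cost`
$3,352.15, `den.mean_qalys` 4.2033, `den.mean_fractures` 0.6012
versus 0.8219 untreated.

The command line mirrors the library:

```
osteosim base-case --age 65 --age 80 --n 100000 --seed 1 --out results/
osteosim one-way  --age 65 --n 100000 --seed 1 --out results/
osteosim psa      --age 80 --n-outer 200 --n-inner 5000 --seed 1 --out results/
osteosim generate-params --seed 0 --out parameters.yaml
osteosim validate --config parameters.yaml
```

## Layout

- `osteosim.params` — parameter model, YAML/JSON I/O, validation, overrides
- `osteosim.synthetic` — seeded synthetic parameter generation, incidence calibration
- `osteosim.treatment` — strategies, persistence, sequential gating, offset effects
- `osteosim.engine` — the microsimulation (scalar reference + vectorized population path)
- `osteosim.economics` — accrual, discounting, ICER/NMB/NHB
- `osteosim.cohort` — exact cohort recursion used as validation oracle
- `osteosim.sensitivity` — one-way scenarios, PSA, CEAC
- `osteosim.cli` — the `osteosim` command

See `docs/methods.md` for modelling assumptions, parameter defaults,
numerical conventions and known limitations.
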