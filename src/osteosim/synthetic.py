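"""Synthetic parameter-set generation and risk-group incidence calibration.

The microsimulation needs a complete numeric parameter set: a life
table, age- and site-specific fracture incidence for osteoporotic
postmenopausal women, treatment relative risks, persistence schedules,
unit costs and utilities.  This module generates realistic, internally
consistent sets from a seeded :class:`GeneratorProfile`, so the whole
pipeline — base case, one-way scenarios, probabilistic sensitivity —
is exercisable and replayable without any proprietary inputs.

Shapes emulated: Gompertz-style background mortality closing to 1 near
the maximum age; hip and clinical vertebral incidence rising
exponentially with age (wrist and other nearly flat); treatment
relative risks below 1 with lognormal-style 95% bounds; right-skewed
cost uncertainty; utilities inside [0,1].  Population incidence is
allocated to the osteoporotic subgroup with the standard
prevalence/relative-risk partition (:func:`calibrate_incidence`),
applied uniformly across all four sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import uncertainty
from .params import (Analysis, Costs, ExcessMortality, OffsetRule,
                     ParameterSet, RelativeRisk, Utilities)

_AGE_LO = 50


@dataclass(frozen=True)
class GeneratorProfile:
    """Seeded recipe for a synthetic parameter set.

    The severity knobs rescale whole parameter blocks (incidence level,
    log-efficacy, cost level); ``uncertainty_scale`` widens or narrows
    every PSA distribution.  The same profile always yields a
    value-identical ParameterSet.
    """

    seed: int = 0
    incidence_scale: float = 1.0
    efficacy_strength: float = 1.0
    cost_scale: float = 1.0
    uncertainty_scale: float = 1.0


def calibrate_incidence(general_rate: float, rr_osteoporotic: float,
                        prevalence: float) -> float:
    """Fracture rate in the osteoporotic subgroup from the population rate.

    With subgroup prevalence p and relative risk r versus the
    non-osteoporotic complement, the subgroup rate is
    ``general_rate * r / (p * r + (1 - p))``, which preserves the
    population-average rate when the two groups are recombined.
    """
    if not 0.0 < prevalence <= 1.0:
        raise ValueError(f"prevalence must be in (0,1], got {prevalence}")
    if rr_osteoporotic < 1.0:
        raise ValueError(f"relative risk must be >= 1, got {rr_osteoporotic}")
    if general_rate < 0.0:
        raise ValueError(f"rate must be >= 0, got {general_rate}")
    return general_rate * rr_osteoporotic / (
        prevalence * rr_osteoporotic + (1.0 - prevalence))


# Base 95% intervals for fracture relative risks (trial-network style).
_EFFICACY_BASE = {
    "denosumab": {
        "hip": (0.60, 0.37, 0.97),
        "clinical_vertebral": (0.32, 0.26, 0.41),
        "wrist": (0.84, 0.66, 0.98),
        "other": (0.80, 0.67, 0.95),
    },
    "zoledronic_acid": {
        "hip": (0.59, 0.42, 0.83),
        "clinical_vertebral": (0.30, 0.24, 0.38),
        "wrist": (0.75, 0.56, 0.96),
        "other": (0.75, 0.64, 0.87),
    },
}


def _jitter(rng, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def generate_parameter_set(profile: GeneratorProfile | None = None,
                           max_age: int = 105) -> ParameterSet:
    """Generate a validated synthetic ParameterSet from ``profile``."""
    profile = profile or GeneratorProfile()
    rng = np.random.default_rng(profile.seed)
    ages = range(_AGE_LO, max_age + 1)

    # --- background mortality: Gompertz, forced to 1 at the maximum age
    m0 = _jitter(rng, 0.0020, 0.0030)
    slope = _jitter(rng, 0.105, 0.115)
    life = {a: min(1.0, m0 * math.exp(slope * (a - _AGE_LO))) for a in ages}
    life[max_age] = 1.0

    # --- fracture incidence: population curves, calibrated to the
    #     osteoporotic subgroup (prevalence ~32% over 65 in China)
    prevalence = _jitter(rng, 0.28, 0.36)
    rr_osteo = _jitter(rng, 1.8, 2.2)
    curves = {
        "hip": (_jitter(rng, 0.00040, 0.00070), _jitter(rng, 0.080, 0.095)),
        "clinical_vertebral": (_jitter(rng, 0.0045, 0.0065), _jitter(rng, 0.050, 0.065)),
        "wrist": (_jitter(rng, 0.0020, 0.0030), _jitter(rng, 0.003, 0.008)),
        "other": (_jitter(rng, 0.0030, 0.0050), _jitter(rng, 0.010, 0.020)),
    }
    incidence = {}
    for site, (i0, g) in curves.items():
        incidence[site] = {
            a: calibrate_incidence(
                profile.incidence_scale * i0 * math.exp(g * (a - _AGE_LO)),
                rr_osteo, prevalence)
            for a in ages
        }

    # --- excess mortality after hip fracture
    excess = ExcessMortality(short_term_rr=_jitter(rng, 4.0, 6.0),
                             long_term_rr=_jitter(rng, 1.6, 2.0),
                             attributable_fraction=0.25)

    # --- treatment efficacy, jittered within bounds, strength-rescaled
    efficacy = {}
    for drug, site_map in _EFFICACY_BASE.items():
        efficacy[drug] = {}
        for site, (pt, lo, hi) in site_map.items():
            pt = pt ** profile.efficacy_strength
            lo = min(lo ** profile.efficacy_strength, pt)
            hi = min(max(hi ** profile.efficacy_strength, pt), 0.99)
            pt_j = float(np.clip(pt * math.exp(rng.normal(0.0, 0.03)),
                                 lo * 1.02, hi * 0.98))
            efficacy[drug][site] = RelativeRisk(point=pt_j, low=lo, high=hi)

    # --- persistence: cumulative schedules built from jittered annual
    #     conditional retention (guarantees non-increasing)
    persistence = {}
    for drug, conds in (("denosumab", (0.95, 0.92, 0.92)),
                        ("zoledronic_acid", (0.92, 0.90, 0.90))):
        cum, sched = 1.0, []
        for c in conds:
            cum *= min(1.0, c * math.exp(rng.normal(0.0, 0.02)))
            sched.append(cum)
        persistence[drug] = sched
    compliance = {"denosumab": 1.0, "zoledronic_acid": 1.0}

    offset = {"denosumab": OffsetRule("fixed", 1.0),
              "zoledronic_acid": OffsetRule("equal_to_treatment")}

    # --- unit costs, 2020 USD
    cs = profile.cost_scale

    def _cost(base: float, rel: float = 0.10) -> float:
        return cs * base * math.exp(rng.normal(0.0, rel / 2))

    costs = Costs(
        drug_cost_per_dose={"denosumab": _cost(160.0),
                            "zoledronic_acid": _cost(430.0)},
        admin_cost_per_dose={"denosumab": _cost(8.0),
                             "zoledronic_acid": _cost(30.0)},
        physician_visit_annual=_cost(15.0),
        dxa_scan_annual=_cost(40.0),
        fracture_first_year={"hip": _cost(4800.0),
                             "clinical_vertebral": _cost(2600.0),
                             "wrist": _cost(1300.0),
                             "other": _cost(1600.0)},
        hip_longterm_annual=_cost(500.0),
    )

    # --- utilities: declining age bands, fracture multipliers/decrements
    u0 = _jitter(rng, 0.86, 0.90)
    step = _jitter(rng, 0.020, 0.026)
    baseline = {band: round(max(0.5, u0 - step * i), 4)
                for i, band in enumerate(range(_AGE_LO, max_age + 1, 5))}
    utilities = Utilities(
        baseline=baseline,
        first_year_multiplier={
            "hip": float(np.clip(0.55 * math.exp(rng.normal(0, 0.02)), 0.4, 0.7)),
            "clinical_vertebral": float(np.clip(0.68 * math.exp(rng.normal(0, 0.02)), 0.5, 0.8)),
        },
        subsequent_multiplier={
            "hip": float(np.clip(0.84 * math.exp(rng.normal(0, 0.015)), 0.7, 0.92)),
            "clinical_vertebral": float(np.clip(0.93 * math.exp(rng.normal(0, 0.01)), 0.85, 0.98)),
        },
        one_time_disutility={"wrist": 0.03, "other": 0.05},
    )

    ps = ParameterSet(
        life_table=life, incidence=incidence, excess_mortality=excess,
        treatment_efficacy=efficacy, persistence=persistence,
        compliance=compliance, offset=offset, costs=costs,
        utilities=utilities, analysis=Analysis(max_age=max_age),
    )
    ps.psa_spec = _derive_psa_spec(ps, profile.uncertainty_scale)
    return ps


def _derive_psa_spec(ps: ParameterSet, width: float) -> dict:
    """Moment-matched PSA distributions from point estimates and bounds.

    Relative risks: lognormal with the median at the point estimate and
    sigma from the 95% bound ratio.  Costs: gamma with a 15% coefficient
    of variation.  Utility multipliers and disutilities: beta.
    ``width`` rescales every spread.
    """
    spec = {}
    for drug, site_map in ps.treatment_efficacy.items():
        for site, rr in site_map.items():
            d = uncertainty.lognormal_from_bounds(rr.point, rr.low, rr.high)
            d.params["sigma"] *= width
            spec[f"treatment_efficacy.{drug}.{site}.point"] = d
    for site, c in ps.costs.fracture_first_year.items():
        spec[f"costs.fracture_first_year.{site}"] = \
            uncertainty.gamma_from_mean_sd(c, 0.15 * c * width)
    spec["costs.hip_longterm_annual"] = uncertainty.gamma_from_mean_sd(
        ps.costs.hip_longterm_annual, 0.15 * ps.costs.hip_longterm_annual * width)
    for name, mult_map in (("first_year_multiplier", ps.utilities.first_year_multiplier),
                           ("subsequent_multiplier", ps.utilities.subsequent_multiplier)):
        for site, m in mult_map.items():
            spec[f"utilities.{name}.{site}"] = \
                uncertainty.beta_from_mean_sd(m, min(0.04 * width, 0.3 * math.sqrt(m * (1 - m))))
    for site, d in ps.utilities.one_time_disutility.items():
        spec[f"utilities.one_time_disutility.{site}"] = \
            uncertainty.beta_from_mean_sd(d, 0.25 * d * width)
    return spec
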