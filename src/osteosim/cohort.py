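"""Deterministic expected-value oracle for validating the microsimulation.

Forward recursion over the exact state distribution of the annual-cycle
model under deterministic treatment (full persistence).  The chain
tracks hip count (0, 1, 2), vertebral history, and optionally an
"ever had an event at one site" flag, which is enough to reproduce the
microsimulation's per-cycle costs, utilities and mortality exactly in
expectation — wrist/other one-time events included, since they leave
the state unchanged and enter linearly.

Stochastic persistence is the one feature the recursion cannot
express; parameter sets using it are rejected by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .economics import discount_factor, treatment_cycle_cost
from .params import SITES, ParameterSet
from .treatment import NO_TREATMENT, Strategy, deterministic_rr_trace

#: Reporting states for the occupancy trace.
OCCUPANCY_STATES = ("no_fracture", "post_vertebral", "post_hip_year1",
                    "post_hip_later", "dead")


class OracleIncompatibleError(ValueError):
    """The ParameterSet uses a feature the recursion cannot express."""


@dataclass
class CohortResult:
    """Exact expectations from the forward recursion."""

    expected_cost: float          # discounted USD
    expected_qalys: float         # discounted
    expected_fractures: float     # undiscounted event count
    occupancy: np.ndarray         # (n_cycles, 5) over OCCUPANCY_STATES
    cumulative_event_probability: float | None = None


def _check_compatible(ps: ParameterSet, strategy: Strategy) -> None:
    for phase in strategy.phases:
        sched = ps.persistence[phase.drug]
        if any(p != 1.0 for p in sched[:phase.duration]):
            raise OracleIncompatibleError(
                f"stochastic persistence for {phase.drug} "
                "(schedule below 1) is not expressible in the cohort recursion")


def _recurse(ps: ParameterSet, strategy: Strategy, init_age: int,
             horizon: int | None, track_site: str | None,
             n_cycles: int | None = None) -> CohortResult:
    _check_compatible(ps, strategy)
    a = ps.analysis
    if init_age not in ps.life_table:
        raise KeyError(f"initiation age {init_age} outside the life table")
    T = a.max_age - init_age + 1
    if n_cycles is not None:
        T = min(T, n_cycles)
    rr_trace = deterministic_rr_trace(ps, strategy, T)

    # deterministic treatment cost per cycle under full persistence
    treat_cost = np.zeros(T)
    k = 0
    for phase in strategy.phases:
        c = treatment_cycle_cost(ps, phase.drug, phase.doses_per_year, True, False)
        for _ in range(phase.duration):
            if k < T:
                treat_cost[k] = c
            k += 1

    em = ps.excess_mortality
    fy = ps.utilities.first_year_multiplier
    sub = ps.utilities.subsequent_multiplier
    dis = ps.utilities.one_time_disutility
    frac_cost = ps.costs.fracture_first_year
    ltc = ps.costs.hip_longterm_annual

    # alive states: (hip_count, vert_ever, flag); dead states: flag only
    pi: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
    dead = {0: 0.0, 1: 0.0}
    occupancy = np.zeros((T, 5))
    e_cost = e_qaly = e_frac = 0.0
    dfc = [discount_factor(k, a.discount_rate_costs) for k in range(T)]
    dfe = [discount_factor(k, a.discount_rate_effects) for k in range(T)]

    for k in range(T):
        age = init_age + k
        m_bg = ps.life_table[age]
        u_b = ps.baseline_utility(age)
        accrue = horizon is None or k < horizon
        new_pi: dict[tuple[int, int, int], float] = {}
        occ = np.zeros(5)

        for (h, v, f), p_state in pi.items():
            if p_state == 0.0:
                continue
            hazards = []
            for j, site in enumerate(SITES):
                hz = ps.incidence[site][age] * rr_trace[k, j]
                if site == "hip" and h >= 2:
                    hz = 0.0
                hazards.append(hz)
            total = sum(hazards)
            p_frac = -math.expm1(-total) if total > 0 else 0.0

            events = [(None, 1.0 - p_frac)]
            for site, hz in zip(SITES, hazards):
                events.append((site, p_frac * hz / total if total > 0 else 0.0))

            for event, p_e in events:
                if p_e == 0.0:
                    continue
                w = p_state * p_e
                # post-event history
                h2 = h + 1 if event == "hip" else h
                v2 = 1 if event == "clinical_vertebral" else v
                f2 = 1 if (track_site is not None and event == track_site) else f
                # mortality (short-term excess in the hip-event cycle)
                if event == "hip":
                    rr_ex = em.short_term_rr
                    q = min(1.0, m_bg * (1.0 + em.attributable_fraction * (rr_ex - 1.0)))
                elif h >= 1:
                    q = min(1.0, m_bg * (1.0 + em.attributable_fraction
                                         * (em.long_term_rr - 1.0)))
                else:
                    q = m_bg
                # cost: treatment + fracture + long-term hip care
                cost = treat_cost[k]
                if event is not None:
                    cost += frac_cost[event]
                if h >= 1 and event != "hip":
                    cost += ltc
                # utility
                if event == "hip":
                    util = u_b * fy["hip"]
                elif event == "clinical_vertebral":
                    util = u_b * fy["clinical_vertebral"]
                else:
                    if h >= 1:
                        util = u_b * sub["hip"]
                    elif v >= 1:
                        util = u_b * sub["clinical_vertebral"]
                    else:
                        util = u_b
                    if event in ("wrist", "other"):
                        util -= dis[event]
                util = max(util, 0.0)

                if accrue:
                    e_cost += w * cost * dfc[k]
                    e_qaly += w * (1.0 - q) * util * dfe[k]
                    if event is not None:
                        e_frac += w
                surv = w * (1.0 - q)
                key = (h2, v2, f2)
                new_pi[key] = new_pi.get(key, 0.0) + surv
                dead[f2] += w * q
                # end-of-cycle occupancy (reporting aggregation)
                if event == "hip":
                    occ[2] += surv
                elif h2 >= 1:
                    occ[3] += surv
                elif v2 >= 1:
                    occ[1] += surv
                else:
                    occ[0] += surv

        occ[4] = dead[0] + dead[1]
        occupancy[k] = occ
        pi = new_pi

    cum = None
    if track_site is not None:
        cum = sum(p for (h, v, f), p in pi.items() if f == 1) + dead[1]
    return CohortResult(expected_cost=e_cost, expected_qalys=e_qaly,
                        expected_fractures=e_frac, occupancy=occupancy,
                        cumulative_event_probability=cum)


def cohort_expected_values(ps: ParameterSet, strategy: Strategy,
                           init_age: int,
                           horizon: int | None = None) -> tuple[float, float]:
    """Exact expected (discounted cost, discounted QALYs) by forward recursion."""
    r = _recurse(ps, strategy, init_age, horizon, track_site=None)
    return r.expected_cost, r.expected_qalys


def cohort_run(ps: ParameterSet, strategy: Strategy, init_age: int,
               horizon: int | None = None) -> CohortResult:
    """Full recursion output: cost, QALYs, fracture count, occupancy trace."""
    return _recurse(ps, strategy, init_age, horizon, track_site=None)


def cumulative_event_probability(ps: ParameterSet, site: str, init_age: int,
                                 horizon: int,
                                 strategy: Strategy = NO_TREATMENT) -> float:
    """P(at least one fracture at ``site``) within ``horizon`` cycles.

    Death acts as a competing risk: individuals dying event-free never
    contribute.
    """
    if site not in SITES:
        raise KeyError(f"unknown site {site!r}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    r = _recurse(ps, strategy, init_age, horizon=None, track_site=site,
                 n_cycles=horizon)
    return float(r.cumulative_event_probability)
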