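"""Cost and utility accrual, discounting, and cost-effectiveness summaries.

Costs are 2020 USD; effects are QALYs.  Per-cycle quantities discount by
(1+r)^-k for cycle index k (no half-cycle correction).  Strategy
comparisons report incremental cost and effect, the ICER (with dominance
codes), and net monetary / net health benefit at a stated
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .params import SITES, ParameterSet

_FRACTURE_EVENTS = frozenset(SITES)

#: ICER dominance codes.
DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


def discount_factor(cycle_index: int, rate: float) -> float:
    """(1 + rate)^-cycle_index; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-cycle_index)


def treatment_cycle_cost(ps: ParameterSet, drug: str, doses_per_year: int,
                         persisted: bool, discontinued_at_first_dose: bool) -> float:
    """Drug + administration/monitoring cost for one treatment year.

    A persisting year is charged the full schedule of doses (scaled by
    compliance) plus per-dose administration and the annual physician
    visit and DXA scan.  An individual who discontinues is charged
    exactly one dose (and its administration) for that year.
    """
    c = ps.costs
    if persisted:
        doses = doses_per_year * ps.compliance[drug]
        return (doses * c.drug_cost_per_dose[drug]
                + doses * c.admin_cost_per_dose[drug]
                + c.physician_visit_annual + c.dxa_scan_annual)
    if discontinued_at_first_dose:
        return c.drug_cost_per_dose[drug] + c.admin_cost_per_dose[drug]
    return 0.0


def accrue_cycle_cost(ps: ParameterSet, state, event: str | None,
                      persisted_this_cycle: bool = False,
                      discontinued_at_first_dose: bool = False) -> float:
    """Undiscounted cost of one cycle for an individual alive at its start.

    ``state`` carries the pre-event history (``hip_count``, treatment
    position); ``event`` is a fracture site or None.  Components: drug and
    administration costs per the persistence flags, the first-year cost of
    any fracture event, and the annual long-term care cost in every
    post-hip year other than the event year itself.
    """
    total = 0.0
    if persisted_this_cycle or discontinued_at_first_dose:
        phase = state.treatment.current_phase
        total += treatment_cycle_cost(ps, phase.drug, phase.doses_per_year,
                                      persisted_this_cycle,
                                      discontinued_at_first_dose)
    if event in _FRACTURE_EVENTS:
        total += ps.costs.fracture_first_year[event]
    if state.hip_count >= 1 and event != "hip":
        total += ps.costs.hip_longterm_annual
    return total


def accrue_cycle_utility(ps: ParameterSet, state, event: str | None) -> float:
    """Undiscounted QALYs accrued over one cycle (alive throughout).

    Baseline utility at the current age times: the event site's
    first-year multiplier for a hip/vertebral event, otherwise the
    subsequent-year multiplier of the worst prior fracture (hip worse
    than vertebral).  Wrist/other events subtract a one-time absolute
    disutility.  Floored at 0.
    """
    u = ps.baseline_utility(state.age)
    fy = ps.utilities.first_year_multiplier
    sub = ps.utilities.subsequent_multiplier
    if event == "hip":
        value = u * fy["hip"]
    elif event == "clinical_vertebral":
        value = u * fy["clinical_vertebral"]
    else:
        if state.hip_count >= 1:
            value = u * sub["hip"]
        elif state.vertebral_count >= 1:
            value = u * sub["clinical_vertebral"]
        else:
            value = u
        if event in ("wrist", "other"):
            value -= ps.utilities.one_time_disutility[event]
    return max(value, 0.0)


def summarize_trajectory(records: Iterable, discount_rate_costs: float,
                         discount_rate_effects: float) -> tuple[float, float, int]:
    """Discounted (cost, QALYs, fracture count) over one trajectory."""
    cost = 0.0
    qalys = 0.0
    fractures = 0
    for rec in records:
        cost += rec.cost * discount_factor(rec.cycle, discount_rate_costs)
        qalys += rec.utility * discount_factor(rec.cycle, discount_rate_effects)
        if rec.event in _FRACTURE_EVENTS:
            fractures += 1
    return cost, qalys, fractures


@dataclass
class CEAComparison:
    """Incremental comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None        # None when a dominance code applies
    icer_code: str            # "ratio", "dominant", "dominated", "equivalent"
    nmb: float
    nhb: float
    wtp: float


def cea_compare(cost_i: float, qaly_i: float, cost_c: float, qaly_c: float,
                wtp: float, intervention: str = "intervention",
                comparator: str = "comparator") -> CEAComparison:
    """Compute ΔC, ΔE, ICER (with dominance codes), NMB and NHB.

    NMB = λ·ΔE − ΔC and NHB = ΔE − ΔC/λ, so NHB·λ = NMB identically.
    Dominance: "dominant" when the intervention is cheaper and no less
    effective (strictly better on at least one axis), "dominated" when it
    is costlier and no more effective.
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    d_cost = cost_i - cost_c
    d_qaly = qaly_i - qaly_c
    nmb = wtp * d_qaly - d_cost
    nhb = d_qaly - d_cost / wtp
    if d_cost == 0.0 and d_qaly == 0.0:
        icer, code = None, EQUIVALENT
    elif d_qaly > 0.0 and d_cost < 0.0:
        icer, code = None, DOMINANT
    elif d_qaly <= 0.0 and d_cost > 0.0:
        icer, code = None, DOMINATED
    elif d_qaly == 0.0:   # cheaper, equally effective
        icer, code = None, DOMINANT
    else:
        icer, code = d_cost / d_qaly, "ratio"
    return CEAComparison(intervention=intervention, comparator=comparator,
                         delta_cost=d_cost, delta_qalys=d_qaly,
                         icer=icer, icer_code=code, nmb=nmb, nhb=nhb, wtp=wtp)


def compare_strategies(a, b, wtp: float) -> CEAComparison:
    """Compare two :class:`~osteosim.engine.StrategyResult` objects (a vs b)."""
    if getattr(a, "init_age", None) != getattr(b, "init_age", None):
        raise ValueError("strategies must share the initiation age")
    return cea_compare(a.mean_cost, a.mean_qalys, b.mean_cost, b.mean_qalys,
                       wtp, intervention=a.strategy_name, comparator=b.strategy_name)
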