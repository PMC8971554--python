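"""Treatment strategies, persistence, and residual (offset) effects.

A :class:`Strategy` is an ordered list of phases (drug, intended duration
in years, doses per year); the empty list is the no-treatment comparator.
Sequential regimens gate strictly: only individuals who complete a phase
in full ever start the next one.

Persistence is evaluated once per annual cycle, at the cycle start, from
the cumulative persistence schedule (probability of still being on the
drug through the end of each treatment year).  An individual who persists
through a cycle acquires that cycle's full fracture-risk reduction; one
who discontinues gets none for that cycle and enters the offset period.

After stopping, the drug's relative risk rises linearly from its
on-treatment value back to 1 across the offset duration (fixed for
denosumab, equal to time on treatment for zoledronic acid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import SITES, ParameterSet


@dataclass(frozen=True)
class Phase:
    drug: str
    duration: int          # intended years on this drug
    doses_per_year: int


@dataclass(frozen=True)
class Strategy:
    """An ordered treatment course; no phases means no treatment."""

    name: str
    phases: tuple[Phase, ...] = ()

    @property
    def total_duration(self) -> int:
        return sum(p.duration for p in self.phases)


NO_TREATMENT = Strategy("No treatment")
DEN_ZOL = Strategy("DEN/ZOL", (Phase("denosumab", 3, 2),
                               Phase("zoledronic_acid", 3, 1)))
ZOL_MONO = Strategy("ZOL mono", (Phase("zoledronic_acid", 3, 1),))

#: The three canonical strategies, by name.
STRATEGY_PRESETS: dict[str, Strategy] = {
    s.name: s for s in (NO_TREATMENT, DEN_ZOL, ZOL_MONO)
}


@dataclass
class TreatmentStatus:
    """Position within a treatment course.

    ``state`` is ``"never"`` (no-treatment strategy), ``"on"``,
    ``"discontinued"`` (left mid-course; later phases permanently
    skipped) or ``"completed"``.  For stopped courses, ``last_drug`` /
    ``years_taken`` record the final exposure and ``years_since_stop``
    the elapsed offset time (fractional values allowed: the engine
    evaluates the waning effect at cycle midpoints).
    """

    strategy: Strategy
    phase_index: int = 0
    years_in_phase: int = 0
    state: str = "on"
    last_drug: str | None = None
    years_taken: int = 0
    years_since_stop: float = 0.0

    @classmethod
    def start(cls, strategy: Strategy) -> "TreatmentStatus":
        if not strategy.phases:
            return cls(strategy=strategy, state="never")
        return cls(strategy=strategy, state="on")

    @property
    def current_phase(self) -> Phase:
        return self.strategy.phases[self.phase_index]


def conditional_persistence(ps: ParameterSet, drug: str, year: int) -> float:
    """P(still on through treatment year ``year`` | on at its start).

    ``year`` is 1-based.  Derived from the cumulative schedule
    p_cum[year] / p_cum[year-1], with p_cum[0] = 1.
    """
    sched = ps.persistence[drug]
    if year < 1 or year > len(sched):
        raise KeyError(f"persistence schedule for {drug} has no year {year}")
    prev = 1.0 if year == 1 else sched[year - 2]
    if prev == 0.0:
        return 0.0
    return sched[year - 1] / prev


def sample_persistence(ps: ParameterSet, status: TreatmentStatus, rng) -> str:
    """Draw the persistence decision for the upcoming treatment year.

    Consumes exactly one uniform from ``rng``; returns ``"continue"`` or
    ``"discontinue"``.
    """
    if status.state != "on":
        raise ValueError("persistence is only sampled while on treatment")
    phase = status.current_phase
    cond = conditional_persistence(ps, phase.drug, status.years_in_phase + 1)
    u = rng.random()
    return "continue" if u < cond else "discontinue"


def advance_treatment(status: TreatmentStatus, decision: str) -> TreatmentStatus:
    """Advance the course by one treatment year.

    Completing the final year of a phase moves to the next phase (or to
    ``completed``, starting the offset clock); ``discontinue`` stops the
    course immediately and permanently skips any later phase.
    """
    if status.state != "on":
        raise ValueError(f"cannot advance a course in state {status.state!r}")
    phase = status.current_phase
    if decision == "discontinue":
        return replace(status, state="discontinued", last_drug=phase.drug,
                       years_taken=status.years_in_phase, years_since_stop=0.0)
    if decision != "continue":
        raise ValueError(f"unknown decision {decision!r}")
    years = status.years_in_phase + 1
    if years < phase.duration:
        return replace(status, years_in_phase=years)
    if status.phase_index + 1 < len(status.strategy.phases):
        return replace(status, phase_index=status.phase_index + 1, years_in_phase=0)
    return replace(status, state="completed", last_drug=phase.drug,
                   years_taken=phase.duration, years_since_stop=0.0,
                   years_in_phase=years)


def offset_duration(ps: ParameterSet, drug: str, years_taken: float) -> float:
    """Residual-effect duration after stopping ``drug``."""
    if years_taken < 0:
        raise ValueError("years_taken must be >= 0")
    if drug not in ps.offset:
        raise KeyError(f"no offset rule for drug {drug!r}")
    rule = ps.offset[drug]
    if rule.kind == "fixed":
        return rule.years
    return float(years_taken)


def _offset_rr(rr: float, offset: float, elapsed: float) -> float:
    """Relative risk ``elapsed`` years after stopping: linear rise to 1."""
    if elapsed >= offset or offset <= 0.0:
        return 1.0
    return rr + (1.0 - rr) * (elapsed / offset)


def relative_risk(ps: ParameterSet, status: TreatmentStatus, site: str) -> float:
    """Fracture relative risk for ``site`` given the treatment position.

    On treatment (a persisting year): the drug's RR for that site.  After
    stopping: linear interpolation from the last drug's RR up to 1 over
    the offset duration.  Never treated, or offset expired: 1.
    """
    if status.state == "never":
        return 1.0
    if status.state == "on":
        return ps.treatment_efficacy[status.current_phase.drug][site].point
    rr = ps.treatment_efficacy[status.last_drug][site].point
    off = offset_duration(ps, status.last_drug, status.years_taken)
    return _offset_rr(rr, off, status.years_since_stop)


def deterministic_rr_trace(ps: ParameterSet, strategy: Strategy,
                           n_cycles: int) -> np.ndarray:
    """Per-cycle, per-site RR under full persistence, shape (n_cycles, 4).

    Cycle k of an on-treatment phase carries the phase drug's RR; after
    the course, the waning effect is evaluated at the cycle midpoint
    (elapsed = full off-years + 0.5).  Column order follows ``SITES``.
    """
    trace = np.ones((n_cycles, len(SITES)))
    k = 0
    for phase in strategy.phases:
        for _ in range(phase.duration):
            if k >= n_cycles:
                return trace
            for j, site in enumerate(SITES):
                trace[k, j] = ps.treatment_efficacy[phase.drug][site].point
            k += 1
    if strategy.phases and k < n_cycles:
        last = strategy.phases[-1]
        off = offset_duration(ps, last.drug, last.duration)
        for j, site in enumerate(SITES):
            rr = ps.treatment_efficacy[last.drug][site].point
            for kk in range(k, n_cycles):
                trace[kk, j] = _offset_rr(rr, off, (kk - k) + 0.5)
    return trace
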