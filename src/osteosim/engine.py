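"""Individual-level annual-cycle microsimulation of fracture trajectories.

Each simulated woman starts at the initiation age with no fracture
history and is followed in annual cycles until death or until the year
at the maximum age.  Within a cycle: the persistence decision is drawn
(if on treatment), at most one fracture event occurs (competing sites
combined through the exponential total / proportional-allocation
construction), costs and utilities accrue, and finally mortality is
drawn — so a fracture and death can co-occur in one cycle, with the
first-year fracture cost still charged and the cycle's utility zeroed.

Hip fractures are capped at two per lifetime; wrist and other fractures
are one-time cost/disutility events that leave the health state
unchanged.  A hip fracture elevates mortality via the short-term excess
relative risk in the event year and the long-term excess thereafter for
life, damped by the attributable fraction.

Two implementations share one random-number layout (four uniforms per
individual per cycle: persistence, fracture occurrence, site allocation,
mortality — always consumed, so strategies can share common random
numbers): a per-individual reference path (:func:`simulate_individual`)
and the vectorized population path used by :func:`run_strategy`.  For a
shared generator the two are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import economics
from .params import SITES, ParameterSet
from .treatment import (Strategy, TreatmentStatus, advance_treatment,
                        conditional_persistence, relative_risk)

_N_STREAMS = 4  # uniforms per cycle: persistence, fracture, site, mortality


@dataclass
class IndividualState:
    """One woman's current position in the model."""

    age: int
    alive: bool = True
    hip_count: int = 0
    vertebral_count: int = 0
    wrist_count: int = 0
    other_count: int = 0
    years_since_hip: int | None = None
    fracture_events: list[tuple[int, str]] = field(default_factory=list)
    treatment: TreatmentStatus = None  # type: ignore[assignment]

    @property
    def health_state(self) -> str:
        if not self.alive:
            return "dead"
        if self.hip_count >= 1:
            return "post_hip"
        if self.vertebral_count >= 1:
            return "post_vertebral"
        return "no_fracture"


@dataclass
class CycleRecord:
    """One cycle's outcome: the event (if any) and undiscounted accruals.

    When a fracture and death co-occur the fracture site is recorded
    (the trajectory simply ends afterwards); ``"death"`` marks an
    event-free cycle ending in death.
    """

    cycle: int
    event: str          # none | hip | clinical_vertebral | wrist | other | death
    cost: float
    utility: float


@dataclass
class StrategyResult:
    """Monte-Carlo means over individuals for one strategy at one age."""

    strategy_name: str
    init_age: int
    n: int
    mean_cost: float
    mean_qalys: float
    mean_fractures: float
    se_cost: float
    se_qalys: float
    se_fractures: float
    master_seed: int | None = None


@dataclass
class PopulationOutcome:
    """Per-individual discounted outcomes from one population run."""

    cost: np.ndarray
    qalys: np.ndarray
    fractures: np.ndarray
    reached_max_age: np.ndarray   # alive at the start of the final cycle


# ---------------------------------------------------------------------------
# single-cycle probability operations (scalar)

def annual_event_probabilities(ps: ParameterSet, state: IndividualState) -> dict[str, float]:
    """Per-site fracture probabilities for the coming cycle, plus ``"none"``.

    Site hazards are incidence(age, site) times the treatment relative
    risk, with the hip hazard forced to zero once two hip fractures have
    occurred.  The total fracture probability is 1 − exp(−Σ hazards),
    allocated across sites proportionally to their hazards.
    """
    if not state.alive:
        raise ValueError("event probabilities are defined for living individuals")
    hazards = {}
    for site in SITES:
        try:
            inc = ps.incidence[site][state.age]
        except KeyError:
            raise KeyError(f"age {state.age} outside the {site} incidence grid") from None
        h = inc * relative_risk(ps, state.treatment, site)
        if site == "hip" and state.hip_count >= 2:
            h = 0.0
        hazards[site] = h
    total = sum(hazards.values())
    p_frac = -math.expm1(-total)
    out = {site: (p_frac * h / total if total > 0 else 0.0)
           for site, h in hazards.items()}
    out["none"] = 1.0 - p_frac
    return out


def mortality_probability(ps: ParameterSet, state: IndividualState) -> float:
    """Annual death probability given age and hip-fracture history.

    Background mortality m(age), inflated after a hip fracture to
    m·(1 + af·(RR−1)) with the short-term RR in the fracture year and the
    long-term RR in all later years, capped at 1.  Vertebral, wrist and
    other fractures confer no excess mortality.
    """
    if not state.alive:
        raise ValueError("mortality is defined for living individuals")
    m = ps.life_table[state.age]
    if state.hip_count >= 1:
        em = ps.excess_mortality
        rr = em.short_term_rr if state.years_since_hip == 0 else em.long_term_rr
        m = min(1.0, m * (1.0 + em.attributable_fraction * (rr - 1.0)))
    return m


# ---------------------------------------------------------------------------
# scalar reference trajectory

def simulate_individual(ps: ParameterSet, strategy: Strategy, init_age: int,
                        rng: np.random.Generator,
                        horizon: int | None = None) -> list[CycleRecord]:
    """Simulate one trajectory; returns the per-cycle records.

    Consumes exactly one ``rng.random((T, 4))`` block, T being the number
    of cycles to the maximum age, regardless of when death occurs — this
    fixed consumption is what lets strategies share random numbers.
    ``horizon`` truncates accrual (records) after that many cycles
    without altering the draws.
    """
    if init_age not in ps.life_table:
        raise KeyError(f"initiation age {init_age} outside the life table")
    T = ps.analysis.max_age - init_age + 1
    u = rng.random((T, _N_STREAMS))
    state = IndividualState(age=init_age, treatment=TreatmentStatus.start(strategy))
    records: list[CycleRecord] = []

    for k in range(T):
        state.age = init_age + k
        tr = state.treatment
        persisted = False
        disc_now = False
        if tr.state == "on":
            cond = conditional_persistence(ps, tr.current_phase.drug,
                                           tr.years_in_phase + 1)
            if u[k, 0] < cond:
                persisted = True
                rr_status = tr
            else:
                disc_now = True
                stopped = advance_treatment(tr, "discontinue")
                rr_status = replace(stopped, years_since_stop=0.5)
        elif tr.state in ("discontinued", "completed"):
            rr_status = replace(tr, years_since_stop=tr.years_since_stop + 0.5)
        else:
            rr_status = tr

        # fracture event
        hazards = []
        for site in SITES:
            h = ps.incidence[site][state.age] * relative_risk(ps, rr_status, site)
            if site == "hip" and state.hip_count >= 2:
                h = 0.0
            hazards.append(h)
        total = sum(hazards)
        event: str | None = None
        if total > 0 and u[k, 1] < -math.expm1(-total):
            x = u[k, 2] * total
            cum = 0.0
            for site, h in zip(SITES, hazards):
                cum += h
                if x < cum:
                    event = site
                    break
            else:
                event = SITES[-1]

        cost = economics.accrue_cycle_cost(ps, state, event, persisted, disc_now)
        utility = economics.accrue_cycle_utility(ps, state, event)

        if event == "hip":
            state.hip_count += 1
            state.years_since_hip = 0
        elif event == "clinical_vertebral":
            state.vertebral_count += 1
        elif event == "wrist":
            state.wrist_count += 1
        elif event == "other":
            state.other_count += 1
        if event is not None:
            state.fracture_events.append((k, event))

        died = u[k, 3] < mortality_probability(ps, state)
        if died:
            utility = 0.0
        if horizon is None or k < horizon:
            records.append(CycleRecord(k, event or ("death" if died else "none"),
                                       cost, utility))
        if died:
            state.alive = False
            break

        # end-of-cycle clock updates
        if state.years_since_hip is not None:
            state.years_since_hip += 1
        if persisted:
            state.treatment = advance_treatment(tr, "continue")
        elif disc_now:
            state.treatment = replace(stopped, years_since_stop=1.0)
        elif tr.state in ("discontinued", "completed"):
            state.treatment = replace(tr, years_since_stop=tr.years_since_stop + 1.0)

    return records


# ---------------------------------------------------------------------------
# vectorized population run

def simulate_population(ps: ParameterSet, strategy: Strategy, init_age: int,
                        n: int, rng: np.random.Generator,
                        horizon: int | None = None) -> PopulationOutcome:
    """Vectorized simulation of ``n`` trajectories sharing one generator.

    Bit-identical to calling :func:`simulate_individual` ``n`` times with
    the same generator and discounting the records.
    """
    if init_age not in ps.life_table:
        raise KeyError(f"initiation age {init_age} outside the life table")
    a = ps.analysis
    T = a.max_age - init_age + 1
    U = rng.random((n, T, _N_STREAMS))
    n_sites = len(SITES)

    inc = np.array([[ps.incidence[s][init_age + k] for s in SITES]
                    for k in range(T)])                       # (T, 4)
    m_bg = np.array([ps.life_table[init_age + k] for k in range(T)])
    u_base = np.array([ps.baseline_utility(init_age + k) for k in range(T)])
    dfc = np.array([economics.discount_factor(k, a.discount_rate_costs)
                    for k in range(T)])
    dfe = np.array([economics.discount_factor(k, a.discount_rate_effects)
                    for k in range(T)])
    frac_cost = np.array([ps.costs.fracture_first_year[s] for s in SITES])
    em = ps.excess_mortality
    fy_hip = ps.utilities.first_year_multiplier["hip"]
    fy_vert = ps.utilities.first_year_multiplier["clinical_vertebral"]
    sub_hip = ps.utilities.subsequent_multiplier["hip"]
    sub_vert = ps.utilities.subsequent_multiplier["clinical_vertebral"]
    dis = np.array([ps.utilities.one_time_disutility.get(s, 0.0) for s in SITES])

    phases = strategy.phases
    drugs = sorted({p.drug for p in phases})
    rr_drug = {d: np.array([ps.treatment_efficacy[d][s].point for s in SITES])
               for d in drugs}
    cost_persist = [economics.treatment_cycle_cost(ps, p.drug, p.doses_per_year,
                                                   True, False) for p in phases]
    cost_onedose = [economics.treatment_cycle_cost(ps, p.drug, p.doses_per_year,
                                                   False, True) for p in phases]
    cond_tab = {(i, y): conditional_persistence(ps, p.drug, y + 1)
                for i, p in enumerate(phases) for y in range(p.duration)}

    ON, OFF = 1, 2
    tstate = np.full(n, ON if phases else 0, dtype=np.int8)
    phase_idx = np.zeros(n, dtype=np.int16)
    years_in_phase = np.zeros(n, dtype=np.int16)
    last_drug = np.full(n, -1, dtype=np.int16)   # index into `drugs`
    years_taken = np.zeros(n, dtype=np.float64)
    yss = np.zeros(n, dtype=np.float64)
    hip_count = np.zeros(n, dtype=np.int16)
    vert_ever = np.zeros(n, dtype=bool)
    ysh = np.full(n, -1, dtype=np.int32)         # -1: no hip yet
    alive = np.ones(n, dtype=bool)

    out_cost = np.zeros(n)
    out_qaly = np.zeros(n)
    out_frac = np.zeros(n, dtype=np.int64)
    reached = np.zeros(n, dtype=bool)

    for k in range(T):
        if not alive.any():
            break
        if k == T - 1:
            reached[:] = alive
        on = alive & (tstate == ON)
        cond = np.ones(n)
        for (i, y), c in cond_tab.items():
            cond[on & (phase_idx == i) & (years_in_phase == y)] = c
        persisted = on & (U[:, k, 0] < cond)
        disc_now = on & ~persisted

        rr = np.ones((n, n_sites))
        for i, p in enumerate(phases):
            rr[persisted & (phase_idx == i)] = rr_drug[p.drug]
        was_off = alive & (tstate == OFF)
        if was_off.any() or disc_now.any():
            eff_last = last_drug.copy()
            eff_taken = years_taken.copy()
            for i, p in enumerate(phases):
                sel = disc_now & (phase_idx == i)
                eff_last[sel] = drugs.index(p.drug)
                eff_taken[sel] = years_in_phase[sel]
            elapsed = np.where(disc_now, 0.5, yss + 0.5)
            for di, d in enumerate(drugs):
                sel = (was_off | disc_now) & (eff_last == di)
                if not sel.any():
                    continue
                rule = ps.offset[d]
                if rule.kind == "fixed":
                    off_dur = np.full(int(sel.sum()), rule.years)
                else:
                    off_dur = eff_taken[sel]
                frac = np.divide(elapsed[sel], off_dur,
                                 out=np.ones_like(off_dur), where=off_dur > 0)
                expired = frac >= 1.0
                rr_off = rr_drug[d] + (1.0 - rr_drug[d]) * frac[:, None]
                rr_off[expired] = 1.0
                rr[sel] = rr_off

        hz = inc[k] * rr
        hz[hip_count >= 2, 0] = 0.0
        total = hz.sum(axis=1)
        p_frac = -np.expm1(-total)
        ev = alive & (total > 0) & (U[:, k, 1] < p_frac)
        cs = np.cumsum(hz, axis=1)
        x = U[:, k, 2] * total
        site_idx = np.minimum((x[:, None] >= cs).sum(axis=1), n_sites - 1)
        hip_ev = ev & (site_idx == 0)
        vert_ev = ev & (site_idx == 1)

        cost = np.zeros(n)
        for i in range(len(phases)):
            cost[persisted & (phase_idx == i)] += cost_persist[i]
            cost[disc_now & (phase_idx == i)] += cost_onedose[i]
        cost[ev] += frac_cost[site_idx[ev]]
        cost[alive & (hip_count >= 1) & ~hip_ev] += ps.costs.hip_longterm_annual

        mult = np.where(hip_count >= 1, sub_hip, np.where(vert_ever, sub_vert, 1.0))
        util = u_base[k] * mult
        util[hip_ev] = u_base[k] * fy_hip
        util[vert_ev] = u_base[k] * fy_vert
        one_time = ev & (site_idx >= 2)
        util[one_time] -= dis[site_idx[one_time]]
        util = np.maximum(util, 0.0)

        hip_count[hip_ev] += 1
        ysh[hip_ev] = 0
        vert_ever[vert_ev] = True

        hip_hist = hip_count >= 1
        rr_ex = np.where(ysh == 0, em.short_term_rr, em.long_term_rr)
        q = np.where(hip_hist,
                     np.minimum(1.0, m_bg[k] * (1.0 + em.attributable_fraction * (rr_ex - 1.0))),
                     m_bg[k])
        die = alive & (U[:, k, 3] < q)
        util[die] = 0.0

        if horizon is None or k < horizon:
            out_cost[alive] += cost[alive] * dfc[k]
            out_qaly[alive] += util[alive] * dfe[k]
            out_frac[ev] += 1
        alive = alive & ~die

        ysh[alive & (ysh >= 0)] += 1
        # treatment clocks (survivors; dead values are never read again)
        inc_years = persisted & alive
        years_in_phase[inc_years] += 1
        for i, p in enumerate(phases):
            done = inc_years & (phase_idx == i) & (years_in_phase == p.duration)
            if i + 1 < len(phases):
                phase_idx[done] = i + 1
                years_in_phase[done] = 0
            else:
                tstate[done] = OFF
                last_drug[done] = drugs.index(p.drug)
                years_taken[done] = p.duration
                yss[done] = 0.0
            stop = disc_now & alive & (phase_idx == i) & (tstate == ON)
            tstate[stop] = OFF
            last_drug[stop] = drugs.index(p.drug)
            years_taken[stop] = years_in_phase[stop]
            yss[stop] = 1.0
        yss[was_off & alive] += 1.0

    return PopulationOutcome(cost=out_cost, qalys=out_qaly, fractures=out_frac,
                             reached_max_age=reached)


def write_event_log(records: list[CycleRecord], init_age: int, path) -> None:
    """Write one trajectory's event log as CSV (debugging/fixtures)."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cycle", "age", "event", "cost", "utility"])
        for r in records:
            w.writerow([r.cycle, init_age + r.cycle, r.event, r.cost, r.utility])


def run_strategy(ps: ParameterSet, strategy: Strategy, init_age: int,
                 n_individuals: int, master_seed: int,
                 horizon: int | None = None) -> StrategyResult:
    """Monte-Carlo means over ``n_individuals`` trajectories.

    The random stream depends only on ``master_seed`` and the problem
    shape (never on the strategy), so strategies evaluated with the same
    seed share common random numbers.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(master_seed)
    pop = simulate_population(ps, strategy, init_age, n_individuals, rng, horizon)
    n = n_individuals

    def se(x):
        return float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    return StrategyResult(
        strategy_name=strategy.name, init_age=init_age, n=n,
        mean_cost=float(pop.cost.mean()), mean_qalys=float(pop.qalys.mean()),
        mean_fractures=float(pop.fractures.mean()),
        se_cost=se(pop.cost), se_qalys=se(pop.qalys), se_fractures=se(pop.fractures),
        master_seed=master_seed,
    )
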