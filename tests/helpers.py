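"""Shared constructors for hand-built parameter sets used across tests."""

from __future__ import annotations

from osteosim.params import (Analysis, Costs, ExcessMortality, OffsetRule,
                             OverrideItem, ParameterOverride, ParameterSet,
                             RelativeRisk, Utilities)

SITES = ("hip", "clinical_vertebral", "wrist", "other")
DRUGS = ("denosumab", "zoledronic_acid")


def make_ps(*, mortality=0.02, incidence=None, max_age=105,
            rr_den=0.6, rr_zol=0.6, persistence=(1.0, 1.0, 1.0),
            baseline_utility=0.8, fy_hip=0.55, fy_vert=0.68,
            sub_hip=0.84, sub_vert=0.93, dis_wrist=0.03, dis_other=0.05,
            discount=0.03, short_rr=5.0, long_rr=1.8, af=0.25,
            drug_cost=None, frac_cost=None, ltc=500.0,
            admin=0.0, monitor=0.0) -> ParameterSet:
    """A fully controllable parameter set for engine/economics tests.

    Deliberately NOT required to pass validation (e.g. zero mortality is
    allowed) — the engine itself never validates.
    """
    incidence = incidence or {s: 0.0 for s in SITES}
    drug_cost = drug_cost or {"denosumab": 160.0, "zoledronic_acid": 430.0}
    frac_cost = frac_cost or {"hip": 4800.0, "clinical_vertebral": 2600.0,
                              "wrist": 1300.0, "other": 1600.0}
    ages = range(50, max_age + 1)
    mort = mortality if isinstance(mortality, dict) else {a: mortality for a in ages}
    return ParameterSet(
        life_table=dict(mort),
        incidence={s: {a: (incidence[s] if isinstance(incidence[s], float)
                           else incidence[s][a]) for a in ages}
                   for s in SITES},
        excess_mortality=ExcessMortality(short_rr, long_rr, af),
        treatment_efficacy={
            "denosumab": {s: RelativeRisk(rr_den, rr_den * 0.8, min(1.0, rr_den * 1.2))
                          for s in SITES},
            "zoledronic_acid": {s: RelativeRisk(rr_zol, rr_zol * 0.8, min(1.0, rr_zol * 1.2))
                                for s in SITES},
        },
        persistence={d: list(persistence) for d in DRUGS},
        compliance={d: 1.0 for d in DRUGS},
        offset={"denosumab": OffsetRule("fixed", 1.0),
                "zoledronic_acid": OffsetRule("equal_to_treatment")},
        costs=Costs(drug_cost_per_dose=dict(drug_cost),
                    admin_cost_per_dose={d: admin for d in DRUGS},
                    physician_visit_annual=monitor, dxa_scan_annual=0.0,
                    fracture_first_year=dict(frac_cost),
                    hip_longterm_annual=ltc),
        utilities=Utilities(
            baseline={b: baseline_utility for b in range(50, max_age + 1, 5)},
            first_year_multiplier={"hip": fy_hip, "clinical_vertebral": fy_vert},
            subsequent_multiplier={"hip": sub_hip, "clinical_vertebral": sub_vert},
            one_time_disutility={"wrist": dis_wrist, "other": dis_other},
        ),
        analysis=Analysis(discount_rate_costs=discount,
                          discount_rate_effects=discount, max_age=max_age),
    )


def full_persistence_override() -> ParameterOverride:
    return ParameterOverride("full persistence", [
        OverrideItem("persistence.denosumab", set=[1.0, 1.0, 1.0]),
        OverrideItem("persistence.zoledronic_acid", set=[1.0, 1.0, 1.0]),
    ])
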