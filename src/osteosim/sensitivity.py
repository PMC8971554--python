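"""One-way deterministic scenarios, probabilistic sensitivity analysis,
and cost-effectiveness acceptability curves.

The ten canonical one-way scenarios (residual effect removed, 10-year
horizon, persistence 10% higher per drug, discount rates 0 and 0.05,
fracture costs ±30%, excess mortality +50% and 0%) are shipped as
presets; each re-runs both strategies under the perturbed parameters
with the same master seed, so scenario deltas are not confounded by
Monte-Carlo noise.

The PSA redraws every uncertain parameter from its moment-matched
distribution (beta for utilities, gamma for costs, lognormal for
relative risks) in an outer loop, runs the microsimulation with common
random numbers across strategies in an inner loop, and summarises
cost-effectiveness probabilities on a willingness-to-pay grid.  A net
monetary benefit of exactly zero counts as not cost-effective.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import params as _p
from .economics import cea_compare
from .engine import run_strategy
from .params import (OverrideItem, ParameterOverride, ParameterSet,
                     RelativeRisk, to_dict)
from .treatment import Strategy
from .uncertainty import sample_distribution


@dataclass
class DSAScenario:
    """A labelled one-way scenario: a parameter override plus optional
    engine-setting changes (accrual horizon)."""

    label: str
    override: ParameterOverride
    horizon: int | None = None


def one_way_presets() -> list[DSAScenario]:
    """The ten canonical one-way scenarios."""

    def ov(label, *items):
        return ParameterOverride(label, list(items))

    return [
        DSAScenario("No residual effect", ov(
            "No residual effect",
            OverrideItem("offset.denosumab", set=_p.OffsetRule("fixed", 0.0)),
            OverrideItem("offset.zoledronic_acid", set=_p.OffsetRule("fixed", 0.0)))),
        DSAScenario("10-years time horizon",
                    ov("10-years time horizon"), horizon=10),
        DSAScenario("DEN persistence rate 10% higher", ov(
            "DEN persistence rate 10% higher",
            OverrideItem("persistence.denosumab", scale=1.10, cap=1.0))),
        DSAScenario("ZOL persistence rate 10% higher", ov(
            "ZOL persistence rate 10% higher",
            OverrideItem("persistence.zoledronic_acid", scale=1.10, cap=1.0))),
        DSAScenario("Discount rates: 0", ov(
            "Discount rates: 0",
            OverrideItem("analysis.discount_rate_costs", set=0.0),
            OverrideItem("analysis.discount_rate_effects", set=0.0))),
        DSAScenario("Discount rates: 0.05", ov(
            "Discount rates: 0.05",
            OverrideItem("analysis.discount_rate_costs", set=0.05),
            OverrideItem("analysis.discount_rate_effects", set=0.05))),
        DSAScenario("Fracture costs 30% higher", ov(
            "Fracture costs 30% higher",
            OverrideItem("costs.fracture_first_year", scale=1.30))),
        DSAScenario("Fracture costs 30% lower", ov(
            "Fracture costs 30% lower",
            OverrideItem("costs.fracture_first_year", scale=0.70))),
        DSAScenario("Excess mortality 50% higher", ov(
            "Excess mortality 50% higher",
            OverrideItem("excess_mortality.short_term_rr", excess_scale=1.5),
            OverrideItem("excess_mortality.long_term_rr", excess_scale=1.5))),
        DSAScenario("Excess mortality 0%", ov(
            "Excess mortality 0%",
            OverrideItem("excess_mortality.attributable_fraction", set=0.0))),
    ]


def run_one_way(ps: ParameterSet, scenarios: list[DSAScenario],
                intervention: Strategy, comparator: Strategy,
                init_age: int, n: int, seed: int,
                wtp: float | None = None) -> pd.DataFrame:
    """Re-run both strategies under each scenario with a shared seed.

    Returns one row per scenario with per-strategy costs and QALYs,
    increments, and the ICER/NMB/NHB at ``wtp`` (default: the primary
    threshold of the parameter set).
    """
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique within a run")
    rows = []
    for sc in scenarios:
        try:
            ps_sc = _p.apply_override(ps, sc.override)
            w = wtp if wtp is not None else ps_sc.analysis.wtp_primary
            res_i = run_strategy(ps_sc, intervention, init_age, n, seed,
                                 horizon=sc.horizon)
            res_c = run_strategy(ps_sc, comparator, init_age, n, seed,
                                 horizon=sc.horizon)
        except Exception as exc:
            raise type(exc)(f"[scenario {sc.label!r}] {exc}") from exc
        cmpn = cea_compare(res_i.mean_cost, res_i.mean_qalys,
                           res_c.mean_cost, res_c.mean_qalys, w,
                           intervention.name, comparator.name)
        rows.append({
            "scenario": sc.label,
            "cost_intervention": res_i.mean_cost,
            "cost_comparator": res_c.mean_cost,
            "delta_cost": cmpn.delta_cost,
            "qalys_intervention": res_i.mean_qalys,
            "qalys_comparator": res_c.mean_qalys,
            "delta_qalys": cmpn.delta_qalys,
            "icer": cmpn.icer if cmpn.icer is not None else float("nan"),
            "icer_code": cmpn.icer_code,
            "nmb": cmpn.nmb,
            "nhb": cmpn.nhb,
            "wtp": w,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _set_path(root, path: str, value) -> None:
    segments = path.split(".")
    parent = root
    for seg in segments[:-1]:
        kind, key = _p._resolve(parent, seg)
        parent = getattr(parent, key) if kind == "attr" else parent[key]
    kind, key = _p._resolve(parent, segments[-1])
    if kind == "attr":
        setattr(parent, key, value)
    else:
        parent[key] = value
    # a redrawn relative-risk point must stay bracketed by its bounds
    if segments[-1] == "point" and isinstance(parent, RelativeRisk):
        parent.low = min(parent.low, value)
        parent.high = max(parent.high, value)


def sample_psa_parameters(ps: ParameterSet, rng: np.random.Generator,
                          max_retries: int = 100) -> ParameterSet:
    """Draw one parameter set from the joint PSA distribution.

    Each uncertain parameter is drawn independently from its family in
    a fixed (sorted-path) order.  A drawn set that fails validation is
    rejected and redrawn, up to ``max_retries`` attempts.  An empty PSA
    spec returns the input unchanged.
    """
    if not ps.psa_spec:
        return ps
    for _ in range(max_retries):
        out = ps.copy()
        for path in sorted(ps.psa_spec):
            _set_path(out, path, sample_distribution(ps.psa_spec[path], rng))
        if not _p.validate_parameter_set(out):
            return out
    raise RuntimeError(f"no valid PSA draw within {max_retries} attempts")


@dataclass
class PSASample:
    """One outer PSA draw: the sampled-parameter digest and per-strategy
    (discounted cost, discounted QALYs)."""

    draw_index: int
    digest: str
    outcomes: dict[str, tuple[float, float]]


@dataclass
class CEACPoint:
    wtp: float
    probability: float


def psa_streams(seed: int, draw_index: int) -> tuple[np.random.SeedSequence,
                                                     np.random.SeedSequence]:
    """(parameter stream, simulation stream) seeds for one outer draw.

    Both strategies of a draw share the simulation stream, giving common
    random numbers within the draw.
    """
    return (np.random.SeedSequence(seed, spawn_key=(draw_index, 0)),
            np.random.SeedSequence(seed, spawn_key=(draw_index, 1)))


def _digest(ps: ParameterSet) -> str:
    doc = yaml.safe_dump(to_dict(ps), sort_keys=True)
    return hashlib.sha1(doc.encode()).hexdigest()[:12]


def run_psa(ps: ParameterSet, strategies: list[Strategy], init_age: int,
            n_outer: int, n_inner: int, seed: int,
            horizon: int | None = None) -> list[PSASample]:
    """Outer parameter draws × inner microsimulation runs."""
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    samples = []
    for j in range(n_outer):
        param_ss, sim_ss = psa_streams(seed, j)
        ps_j = sample_psa_parameters(ps, np.random.default_rng(param_ss))
        outcomes = {}
        for strat in strategies:
            res = run_strategy(ps_j, strat, init_age, n_inner, sim_ss,
                               horizon=horizon)
            outcomes[strat.name] = (res.mean_cost, res.mean_qalys)
        samples.append(PSASample(draw_index=j, digest=_digest(ps_j),
                                 outcomes=outcomes))
    return samples


def ceac(samples: list[PSASample], intervention: str, comparator: str,
         wtp_grid) -> list[CEACPoint]:
    """P(intervention cost-effective) at each willingness-to-pay.

    At each λ the probability is the fraction of PSA draws with
    λ·ΔE − ΔC strictly positive (a tie counts as not cost-effective).
    """
    wtp_grid = list(wtp_grid)
    if not samples:
        raise ValueError("samples must be non-empty")
    if not wtp_grid:
        raise ValueError("the WTP grid must be non-empty")
    d_cost = np.array([s.outcomes[intervention][0] - s.outcomes[comparator][0]
                       for s in samples])
    d_qaly = np.array([s.outcomes[intervention][1] - s.outcomes[comparator][1]
                       for s in samples])
    return [CEACPoint(wtp=float(l),
                      probability=float(np.mean(l * d_qaly - d_cost > 0)))
            for l in wtp_grid]
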