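"""Parameter model for the osteoporosis treatment microsimulation.

A :class:`ParameterSet` bundles every numeric input of the model: the
background life table, age- and site-specific fracture incidence for the
osteoporotic target population, post-hip-fracture excess mortality,
treatment efficacy (relative risks), persistence and compliance schedules,
residual-effect (offset) rules, unit costs in 2020 USD, EQ-5D utilities,
and the analysis settings (discount rates, willingness-to-pay thresholds,
time horizon).

Parameters are stored per integer age — no interpolation is ever applied.
Configs are read and written as a single nested YAML document (JSON is
accepted, being a YAML subset).  Named scenario overrides
(:class:`ParameterOverride`) support both replacement and multiplicative
perturbation of any parameter path, which is how the one-way sensitivity
scenarios are expressed.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Fracture sites tracked by the model.
SITES: tuple[str, ...] = ("hip", "clinical_vertebral", "wrist", "other")

#: Drugs available to treatment strategies.
DRUGS: tuple[str, ...] = ("denosumab", "zoledronic_acid")

#: Documented conversion used when parameter sources are quoted in 2020 CNY.
CNY_PER_USD_2020: float = 6.8974


class SchemaError(ValueError):
    """A required config field is missing or has the wrong shape."""


class ParseError(ValueError):
    """A config entry could not be interpreted as a number."""


class OverridePathError(KeyError):
    """An override path does not resolve to a ParameterSet field."""


@dataclass
class RelativeRisk:
    """Treatment efficacy as a relative risk with 95% uncertainty bounds."""

    point: float
    low: float
    high: float


@dataclass
class ExcessMortality:
    """Post-hip-fracture excess mortality.

    ``short_term_rr`` applies during the year of a hip fracture,
    ``long_term_rr`` in every subsequent year for life.  Only
    ``attributable_fraction`` of the excess is causally ascribed to the
    fracture itself (the remainder reflects comorbidity).
    """

    short_term_rr: float
    long_term_rr: float
    attributable_fraction: float = 0.25


@dataclass
class OffsetRule:
    """Residual-effect duration after stopping a drug.

    ``kind`` is ``"fixed"`` (use ``years``) or ``"equal_to_treatment"``
    (offset equals the completed years on that drug).
    """

    kind: str
    years: float = 0.0


@dataclass
class Costs:
    """Unit costs in 2020 USD."""

    drug_cost_per_dose: dict[str, float]
    admin_cost_per_dose: dict[str, float]
    physician_visit_annual: float
    dxa_scan_annual: float
    fracture_first_year: dict[str, float]
    hip_longterm_annual: float


@dataclass
class Utilities:
    """EQ-5D baseline utilities and fracture-related decrements.

    ``baseline`` maps the lower edge of a 5-year age band to the baseline
    utility.  Hip and clinical vertebral fractures act multiplicatively
    (first-year and subsequent-year multipliers); wrist and other
    fractures carry a one-time absolute QALY decrement.
    """

    baseline: dict[int, float]
    first_year_multiplier: dict[str, float]
    subsequent_multiplier: dict[str, float]
    one_time_disutility: dict[str, float]


@dataclass
class Analysis:
    """Evaluation settings: discounting, WTP thresholds, horizon."""

    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp_primary: float = 31512.0
    wtp_secondary: float = 10504.0
    max_age: int = 105
    initiation_ages: tuple[int, ...] = (65, 70, 75, 80)
    cycle_length: float = 1.0


@dataclass
class PsaDistribution:
    """Sampling distribution of one uncertain parameter.

    ``family`` is ``beta``, ``gamma`` or ``lognormal``; ``params`` holds
    the family's hyperparameters (``alpha``/``beta``, ``shape``/``scale``,
    or ``mu``/``sigma``).
    """

    family: str
    params: dict[str, float]


@dataclass
class ParameterSet:
    """Every numeric input of the model, with PSA uncertainty descriptors."""

    life_table: dict[int, float]
    incidence: dict[str, dict[int, float]]
    excess_mortality: ExcessMortality
    treatment_efficacy: dict[str, dict[str, RelativeRisk]]
    persistence: dict[str, list[float]]
    compliance: dict[str, float]
    offset: dict[str, OffsetRule]
    costs: Costs
    utilities: Utilities
    analysis: Analysis = field(default_factory=Analysis)
    psa_spec: dict[str, PsaDistribution] = field(default_factory=dict)

    def baseline_utility(self, age: int) -> float:
        """Baseline EQ-5D utility for ``age`` via 5-year-band lookup."""
        edges = [e for e in self.utilities.baseline if e <= age]
        if not edges:
            raise KeyError(f"no utility band covers age {age}")
        return self.utilities.baseline[max(edges)]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


@dataclass
class OverrideItem:
    """One edit: replace (``set``), rescale (``scale``, optionally capped
    at ``cap``), or rescale the excess over 1 (``excess_scale``)."""

    path: str
    set: Any = None
    scale: float | None = None
    cap: float | None = None
    excess_scale: float | None = None


@dataclass
class ParameterOverride:
    """A named scenario: an ordered list of parameter edits."""

    label: str
    items: list[OverrideItem] = field(default_factory=list)


# ---------------------------------------------------------------------------
# serialization

def _rr_to_dict(rr: RelativeRisk) -> dict:
    return {"point": rr.point, "low": rr.low, "high": rr.high}


def to_dict(ps: ParameterSet) -> dict:
    """Render a ParameterSet as a plain nested dict (YAML/JSON-ready)."""
    return {
        "life_table": {int(a): float(m) for a, m in sorted(ps.life_table.items())},
        "incidence": {
            s: {int(a): float(r) for a, r in sorted(ps.incidence[s].items())}
            for s in ps.incidence
        },
        "excess_mortality": dataclasses.asdict(ps.excess_mortality),
        "treatment_efficacy": {
            d: {s: _rr_to_dict(rr) for s, rr in site_map.items()}
            for d, site_map in ps.treatment_efficacy.items()
        },
        "persistence": {d: [float(p) for p in v] for d, v in ps.persistence.items()},
        "compliance": dict(ps.compliance),
        "offset": {d: dataclasses.asdict(r) for d, r in ps.offset.items()},
        "costs": dataclasses.asdict(ps.costs),
        "utilities": {
            "baseline": {int(a): float(u) for a, u in sorted(ps.utilities.baseline.items())},
            "first_year_multiplier": dict(ps.utilities.first_year_multiplier),
            "subsequent_multiplier": dict(ps.utilities.subsequent_multiplier),
            "one_time_disutility": dict(ps.utilities.one_time_disutility),
        },
        "analysis": {
            **dataclasses.asdict(ps.analysis),
            "initiation_ages": list(ps.analysis.initiation_ages),
        },
        "psa_spec": {
            path: {"family": d.family, "params": dict(d.params)}
            for path, d in ps.psa_spec.items()
        },
    }


def _num(value: Any, where: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParseError(f"non-numeric entry at {where}: {value!r}")
    return float(value)


def _int_keyed(d: Mapping, where: str) -> dict[int, float]:
    out = {}
    for k, v in d.items():
        try:
            age = int(k)
        except (TypeError, ValueError):
            raise ParseError(f"non-integer age key at {where}: {k!r}") from None
        out[age] = _num(v, f"{where}[{k}]")
    return out


_REQUIRED = (
    "life_table", "incidence", "excess_mortality", "treatment_efficacy",
    "persistence", "offset", "costs", "utilities",
)


def from_dict(doc: Mapping) -> ParameterSet:
    """Build a ParameterSet from a plain nested dict.

    Optional fields take documented defaults: compliance 1.0 for every
    drug, attributable fraction 0.25, the standard analysis settings, and
    an empty PSA spec.
    """
    if not isinstance(doc, Mapping):
        raise SchemaError("config root must be a mapping")
    for name in _REQUIRED:
        if name not in doc:
            raise SchemaError(f"missing required field: {name}")

    em = doc["excess_mortality"]
    for name in ("short_term_rr", "long_term_rr"):
        if name not in em:
            raise SchemaError(f"missing required field: excess_mortality.{name}")
    excess = ExcessMortality(
        short_term_rr=_num(em["short_term_rr"], "excess_mortality.short_term_rr"),
        long_term_rr=_num(em["long_term_rr"], "excess_mortality.long_term_rr"),
        attributable_fraction=_num(em.get("attributable_fraction", 0.25),
                                   "excess_mortality.attributable_fraction"),
    )

    efficacy: dict[str, dict[str, RelativeRisk]] = {}
    for drug, site_map in doc["treatment_efficacy"].items():
        efficacy[drug] = {}
        for site, rr in site_map.items():
            where = f"treatment_efficacy.{drug}.{site}"
            efficacy[drug][site] = RelativeRisk(
                point=_num(rr["point"], where + ".point"),
                low=_num(rr["low"], where + ".low"),
                high=_num(rr["high"], where + ".high"),
            )

    c = doc["costs"]
    for name in ("drug_cost_per_dose", "admin_cost_per_dose",
                 "physician_visit_annual", "dxa_scan_annual",
                 "fracture_first_year", "hip_longterm_annual"):
        if name not in c:
            raise SchemaError(f"missing required field: costs.{name}")
    costs = Costs(
        drug_cost_per_dose={d: _num(v, f"costs.drug_cost_per_dose.{d}")
                            for d, v in c["drug_cost_per_dose"].items()},
        admin_cost_per_dose={d: _num(v, f"costs.admin_cost_per_dose.{d}")
                             for d, v in c["admin_cost_per_dose"].items()},
        physician_visit_annual=_num(c["physician_visit_annual"], "costs.physician_visit_annual"),
        dxa_scan_annual=_num(c["dxa_scan_annual"], "costs.dxa_scan_annual"),
        fracture_first_year={s: _num(v, f"costs.fracture_first_year.{s}")
                             for s, v in c["fracture_first_year"].items()},
        hip_longterm_annual=_num(c["hip_longterm_annual"], "costs.hip_longterm_annual"),
    )

    u = doc["utilities"]
    for name in ("baseline", "first_year_multiplier", "subsequent_multiplier",
                 "one_time_disutility"):
        if name not in u:
            raise SchemaError(f"missing required field: utilities.{name}")
    utilities = Utilities(
        baseline=_int_keyed(u["baseline"], "utilities.baseline"),
        first_year_multiplier={s: _num(v, f"utilities.first_year_multiplier.{s}")
                               for s, v in u["first_year_multiplier"].items()},
        subsequent_multiplier={s: _num(v, f"utilities.subsequent_multiplier.{s}")
                               for s, v in u["subsequent_multiplier"].items()},
        one_time_disutility={s: _num(v, f"utilities.one_time_disutility.{s}")
                             for s, v in u["one_time_disutility"].items()},
    )

    a = dict(doc.get("analysis", {}))
    if "initiation_ages" in a:
        a["initiation_ages"] = tuple(int(x) for x in a["initiation_ages"])
    if "max_age" in a:
        a["max_age"] = int(a["max_age"])
    analysis = Analysis(**a)

    drugs = list(doc["persistence"].keys())
    compliance = {d: _num(v, f"compliance.{d}")
                  for d, v in doc.get("compliance", {}).items()}
    for d in drugs:
        compliance.setdefault(d, 1.0)

    offset = {}
    for d, rule in doc["offset"].items():
        if "kind" not in rule:
            raise SchemaError(f"missing required field: offset.{d}.kind")
        offset[d] = OffsetRule(kind=str(rule["kind"]),
                               years=_num(rule.get("years", 0.0), f"offset.{d}.years"))

    psa_spec = {
        path: PsaDistribution(family=str(spec["family"]),
                              params={k: _num(v, f"psa_spec.{path}.{k}")
                                      for k, v in spec["params"].items()})
        for path, spec in doc.get("psa_spec", {}).items()
    }

    return ParameterSet(
        life_table=_int_keyed(doc["life_table"], "life_table"),
        incidence={s: _int_keyed(m, f"incidence.{s}")
                   for s, m in doc["incidence"].items()},
        excess_mortality=excess,
        treatment_efficacy=efficacy,
        persistence={d: [_num(p, f"persistence.{d}[{i}]")
                         for i, p in enumerate(v)]
                     for d, v in doc["persistence"].items()},
        compliance=compliance,
        offset=offset,
        costs=costs,
        utilities=utilities,
        analysis=analysis,
        psa_spec=psa_spec,
    )


def load_parameter_set(path) -> ParameterSet:
    """Read a YAML (or JSON) config file into a validated-shape ParameterSet."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return from_dict(doc)


def default_config_path() -> str:
    """Path of the packaged annotated default configuration."""
    from importlib.resources import files
    return str(files("osteosim") / "data" / "default_config.yaml")


def load_default_parameter_set() -> ParameterSet:
    """The packaged default synthetic parameter set."""
    return load_parameter_set(default_config_path())


def save_parameter_set(ps: ParameterSet, path) -> None:
    """Write ``ps`` to ``path`` as canonical YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation

def _prob_ok(x: float) -> bool:
    return 0.0 <= x <= 1.0


def validate_parameter_set(ps: ParameterSet) -> list[str]:
    """Check every ParameterSet invariant; return a list of violations.

    An empty list means the set is valid.  Violations are data, not
    exceptions: each entry names the offending field and the broken rule.
    """
    v: list[str] = []
    ages_needed = range(min(ps.analysis.initiation_ages), ps.analysis.max_age + 1)

    for age, m in ps.life_table.items():
        if not _prob_ok(m):
            v.append(f"life_table[{age}]={m} outside [0,1]")
    missing = [a for a in ages_needed if a not in ps.life_table]
    if missing:
        v.append(f"life table does not reach max_age: missing ages {missing[0]}..{missing[-1]}")
    else:
        surv = 1.0
        for a in range(65, ps.analysis.max_age + 1):
            surv *= 1.0 - ps.life_table[a]
        if surv >= 0.01:
            v.append(f"implied survival from 65 to max_age is {surv:.4f}, not < 1%")

    for site in SITES:
        if site not in ps.incidence:
            v.append(f"incidence missing site {site}")
            continue
        for a in ages_needed:
            if a not in ps.incidence[site]:
                v.append(f"incidence.{site} missing age {a}")
                break
        for a, r in ps.incidence[site].items():
            if r < 0:
                v.append(f"incidence.{site}[{a}]={r} negative")

    em = ps.excess_mortality
    if em.short_term_rr < 1:
        v.append(f"excess_mortality.short_term_rr={em.short_term_rr} < 1")
    if em.long_term_rr < 1:
        v.append(f"excess_mortality.long_term_rr={em.long_term_rr} < 1")
    if not _prob_ok(em.attributable_fraction):
        v.append(f"excess_mortality.attributable_fraction={em.attributable_fraction} outside [0,1]")

    for drug, site_map in ps.treatment_efficacy.items():
        for site, rr in site_map.items():
            where = f"treatment_efficacy.{drug}.{site}"
            if rr.point <= 0:
                v.append(f"{where}.point={rr.point} not positive")
            if not (rr.low <= rr.point <= rr.high):
                v.append(f"{where}: point {rr.point} outside bounds [{rr.low}, {rr.high}]")

    for drug, sched in ps.persistence.items():
        prev = 1.0
        for i, p in enumerate(sched):
            if not _prob_ok(p):
                v.append(f"persistence.{drug}[{i}]={p} outside [0,1]")
            if p > prev + 1e-12:
                v.append(f"persistence.{drug} not non-increasing at year {i + 1}")
            prev = p

    for drug, c in ps.compliance.items():
        if not _prob_ok(c):
            v.append(f"compliance.{drug}={c} outside [0,1]")

    for drug, rule in ps.offset.items():
        if rule.kind not in ("fixed", "equal_to_treatment"):
            v.append(f"offset.{drug}.kind={rule.kind!r} unknown")
        if rule.years < 0:
            v.append(f"offset.{drug}.years={rule.years} negative")

    for d, c in ps.costs.drug_cost_per_dose.items():
        if c < 0:
            v.append(f"costs.drug_cost_per_dose.{d}={c} negative")
    for d, c in ps.costs.admin_cost_per_dose.items():
        if c < 0:
            v.append(f"costs.admin_cost_per_dose.{d}={c} negative")
    for s, c in ps.costs.fracture_first_year.items():
        if c < 0:
            v.append(f"costs.fracture_first_year.{s}={c} negative")
    if ps.costs.physician_visit_annual < 0:
        v.append("costs.physician_visit_annual negative")
    if ps.costs.dxa_scan_annual < 0:
        v.append("costs.dxa_scan_annual negative")
    if ps.costs.hip_longterm_annual < 0:
        v.append("costs.hip_longterm_annual negative")

    for band, u in ps.utilities.baseline.items():
        if not _prob_ok(u):
            v.append(f"utilities.baseline[{band}]={u} outside [0,1]")
    if not any(e <= min(ps.analysis.initiation_ages) for e in ps.utilities.baseline):
        v.append("utilities.baseline has no band covering the youngest initiation age")
    for name, mult_map in (("first_year_multiplier", ps.utilities.first_year_multiplier),
                           ("subsequent_multiplier", ps.utilities.subsequent_multiplier)):
        for site, m in mult_map.items():
            if not (0.0 < m <= 1.0):
                v.append(f"utilities.{name}.{site}={m} outside (0,1]")
    for site, d in ps.utilities.one_time_disutility.items():
        if not _prob_ok(d):
            v.append(f"utilities.one_time_disutility.{site}={d} outside [0,1]")

    a = ps.analysis
    if a.discount_rate_costs < 0 or a.discount_rate_effects < 0:
        v.append("analysis discount rates must be >= 0")
    if a.wtp_primary <= 0 or a.wtp_secondary <= 0:
        v.append("analysis WTP thresholds must be positive")

    return v


# ---------------------------------------------------------------------------
# overrides

def _resolve(parent: Any, key: str):
    """Resolve one path segment against a dataclass or a dict."""
    if dataclasses.is_dataclass(parent) and not isinstance(parent, type):
        if not hasattr(parent, key):
            raise OverridePathError(key)
        return ("attr", key)
    if isinstance(parent, dict):
        if key in parent:
            return ("key", key)
        try:
            ik = int(key)
        except ValueError:
            raise OverridePathError(key) from None
        if ik in parent:
            return ("key", ik)
        raise OverridePathError(key)
    raise OverridePathError(key)


def _transform(old: Any, item: OverrideItem) -> Any:
    if item.set is not None:
        return copy.deepcopy(item.set)
    if item.excess_scale is not None:
        return 1.0 + (old - 1.0) * item.excess_scale
    if item.scale is None:
        raise ValueError(f"override item {item.path!r} has no operation")

    def scaled(x):
        y = x * item.scale
        return min(y, item.cap) if item.cap is not None else y

    if isinstance(old, dict):
        return {k: _transform(v, item) for k, v in old.items()}
    if isinstance(old, list):
        return [_transform(v, item) for v in old]
    return scaled(old)


def apply_override(ps: ParameterSet, ov: ParameterOverride) -> ParameterSet:
    """Return a new ParameterSet with the override applied; ``ps`` unchanged.

    A multiplicative ``scale`` on a mapped field (dict or list) applies to
    every element.  Unknown paths raise :class:`OverridePathError` naming
    the offending segment.
    """
    out = ps.copy()
    for item in ov.items:
        segments = item.path.split(".")
        parent: Any = out
        for seg in segments[:-1]:
            kind, key = _resolve(parent, seg)
            parent = getattr(parent, key) if kind == "attr" else parent[key]
        try:
            kind, key = _resolve(parent, segments[-1])
        except OverridePathError:
            raise OverridePathError(
                f"override path {item.path!r} does not resolve (segment {segments[-1]!r})"
            ) from None
        old = getattr(parent, key) if kind == "attr" else parent[key]
        new = _transform(old, item)
        if kind == "attr":
            setattr(parent, key, new)
        else:
            parent[key] = new
    return out
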