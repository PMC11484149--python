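"""Model input parameters: definition, validation, and YAML serialization.

The cost-effectiveness model consumes only aggregate inputs: 16-week and
52-week response probabilities, discontinuation and waning assumptions,
response-based utilities, unit costs and resource frequencies, adverse-event
rates, productivity inputs, and economic settings (discount rate, cycle
length, willingness-to-pay threshold, perspective).

Probabilities and percentage-type inputs are stored internally as
proportions; the on-disk config mirrors the published input table and
therefore uses percent fields (suffixed ``_pct``), converted on load/save.

Every parameter that carries uncertainty (a printed standard error, or the
20%-of-mean convention when none is available) is addressable by a dotted
path (e.g. ``"utilities.abrocitinib.responder"``) so that one-way and
probabilistic sensitivity analyses can vary it generically.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

ARMS = ("abrocitinib", "soc")
PERSPECTIVES = ("societal", "payer")
FAMILIES = ("beta", "beta_pct", "gamma", "normal", "fixed")


class ParameterError(ValueError):
    """Raised when a config cannot be parsed or fails validation."""


@dataclass
class Violation:
    parameter: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.parameter} = {self.value!r} violates: {self.rule}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EconSettings:
    discount_rate_annual: float = 0.02
    cycle_length_years: float = 0.5
    start_age: float = 38.0
    max_age: float = 110.0
    retirement_age: float = 65.0
    wtp_threshold: float = 5_000_000.0
    perspective: str = "societal"
    yen_per_usd: float = 131.498
    days_per_year: float = 365.25


@dataclass
class ArmClinicalInputs:
    p_response_16w: float
    p_disc_16_52w: float
    p_sustained_52w: float
    annual_disc_post52w: float
    waning_horizon_years: float
    longterm_response_rate: float


@dataclass
class ClinicalInputs:
    abrocitinib: ArmClinicalInputs
    soc: ArmClinicalInputs

    def for_arm(self, arm: str) -> ArmClinicalInputs:
        return getattr(self, arm)


@dataclass
class ArmUtilities:
    responder: float
    non_responder: float


@dataclass
class UtilitySet:
    abrocitinib: ArmUtilities
    soc: ArmUtilities

    def for_arm(self, arm: str) -> ArmUtilities:
        return getattr(self, arm)


@dataclass
class HcruUnitCosts:
    hospitalization: float
    primary_care_visit: float


@dataclass
class HcruFrequencies:
    hospitalization: float
    primary_care_visit: float


@dataclass
class HcruFrequencySet:
    responder: HcruFrequencies
    non_responder: HcruFrequencies


@dataclass
class MonitoringTest:
    name: str
    unit_cost: float
    count_year1: int
    count_year2plus: int


@dataclass
class AERates:
    abrocitinib: float
    soc: float


@dataclass
class AEItem:
    name: str
    cost_per_event: float
    annual_rate: AERates


@dataclass
class CostInputs:
    drug_unit_cost: float
    doses_per_day: float
    hcru_unit_costs: HcruUnitCosts
    hcru_annual_freq: HcruFrequencySet
    monitoring_tests: list[MonitoringTest]
    ae_items: list[AEItem]
    subsequent_monthly_cost: float


@dataclass
class ProductivityInputs:
    employment_rate: float
    hours_per_week: float
    hourly_wage: float
    baseline_pct_hours_lost: float       # percent of working hours, 0-100
    responder_effect_lsm: float          # percentage-point reduction for responders
    weeks_per_year: float = 52.0


@dataclass
class UncertainParameter:
    """Uncertainty annotation for one model input.

    ``se`` is in the parameter's internal units; ``None`` means no standard
    error is available and sensitivity analyses fall back to
    ``owsa_fraction`` of the mean (and, for sampling, a standard error of
    ``owsa_fraction`` times the mean).
    """

    name: str
    family: str
    se: float | None = None
    owsa_fraction: float = 0.20


@dataclass
class ModelParameters:
    settings: EconSettings
    clinical: ClinicalInputs
    utilities: UtilitySet
    costs: CostInputs
    productivity: ProductivityInputs
    uncertainty: list[UncertainParameter] = field(default_factory=list)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# dotted-path access (used by OWSA / PSA)
# ---------------------------------------------------------------------------

_INDEX_RE = re.compile(r"^(\w+)\[(\d+)\]$")


def _resolve(obj: Any, parts: list[str]) -> tuple[Any, str]:
    """Walk all but the last path segment; return (parent, final attr)."""
    for part in parts[:-1]:
        m = _INDEX_RE.match(part)
        if m:
            obj = getattr(obj, m.group(1))[int(m.group(2))]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    m = _INDEX_RE.match(last)
    if m:
        return getattr(obj, m.group(1)), f"[{m.group(2)}]"
    return obj, last


def get_param(p: ModelParameters, path: str) -> float:
    parent, last = _resolve(p, path.split("."))
    if last.startswith("["):
        return parent[int(last[1:-1])]
    return getattr(parent, last)


def set_param(p: ModelParameters, path: str, value: float) -> None:
    parent, last = _resolve(p, path.split("."))
    if last.startswith("["):
        parent[int(last[1:-1])] = value
    else:
        setattr(parent, last, value)


def with_param(p: ModelParameters, path: str, value: float) -> ModelParameters:
    q = p.copy()
    set_param(q, path, value)
    return q


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check(cond: bool, out: list[Violation], name: str, value: Any, rule: str) -> None:
    if not cond:
        out.append(Violation(name, value, rule))


def validate_parameters(p: ModelParameters) -> list[Violation]:
    """Return all invariant violations (empty list means the set is valid)."""
    v: list[Violation] = []
    s = p.settings
    _check(0 <= s.discount_rate_annual < 1, v, "settings.discount_rate_annual",
           s.discount_rate_annual, "0 <= rate < 1")
    _check(0 < s.cycle_length_years <= 1, v, "settings.cycle_length_years",
           s.cycle_length_years, "0 < cycle length <= 1 year")
    _check(s.start_age < s.retirement_age <= s.max_age, v, "settings.start_age",
           (s.start_age, s.retirement_age, s.max_age),
           "start_age < retirement_age <= max_age")
    _check(s.wtp_threshold > 0, v, "settings.wtp_threshold", s.wtp_threshold, "> 0")
    _check(s.perspective in PERSPECTIVES, v, "settings.perspective", s.perspective,
           f"one of {PERSPECTIVES}")
    _check(s.days_per_year > 0, v, "settings.days_per_year", s.days_per_year, "> 0")
    _check(s.yen_per_usd > 0, v, "settings.yen_per_usd", s.yen_per_usd, "> 0")

    for arm in ARMS:
        c = p.clinical.for_arm(arm)
        base = f"clinical.{arm}"
        for fname in ("p_response_16w", "p_disc_16_52w", "p_sustained_52w",
                      "annual_disc_post52w", "longterm_response_rate"):
            val = getattr(c, fname)
            _check(0 <= val <= 1, v, f"{base}.{fname}", val, "probability in [0, 1]")
        _check(c.waning_horizon_years > 1, v, f"{base}.waning_horizon_years",
               c.waning_horizon_years, "> 1 year")
        _check(c.longterm_response_rate <= c.p_sustained_52w, v,
               f"{base}.longterm_response_rate",
               (c.longterm_response_rate, c.p_sustained_52w),
               "long-term response rate <= 52-week sustained-response probability")

        u = p.utilities.for_arm(arm)
        for status in ("responder", "non_responder"):
            val = getattr(u, status)
            _check(0 <= val <= 1, v, f"utilities.{arm}.{status}", val,
                   "utility in [0, 1]")
        _check(u.responder >= u.non_responder, v, f"utilities.{arm}",
               (u.responder, u.non_responder),
               "responder utility >= non-responder utility")

    co = p.costs
    _check(co.drug_unit_cost >= 0, v, "costs.drug_unit_cost", co.drug_unit_cost, ">= 0")
    _check(co.doses_per_day >= 0, v, "costs.doses_per_day", co.doses_per_day, ">= 0")
    _check(co.subsequent_monthly_cost >= 0, v, "costs.subsequent_monthly_cost",
           co.subsequent_monthly_cost, ">= 0")
    for fname in ("hospitalization", "primary_care_visit"):
        val = getattr(co.hcru_unit_costs, fname)
        _check(val >= 0, v, f"costs.hcru_unit_costs.{fname}", val, ">= 0")
        for status in ("responder", "non_responder"):
            fv = getattr(getattr(co.hcru_annual_freq, status), fname)
            _check(fv >= 0, v, f"costs.hcru_annual_freq.{status}.{fname}", fv, ">= 0")
    for i, t in enumerate(co.monitoring_tests):
        base = f"costs.monitoring_tests[{i}]"
        _check(t.unit_cost >= 0, v, f"{base}.unit_cost", t.unit_cost, ">= 0")
        for fname in ("count_year1", "count_year2plus"):
            cnt = getattr(t, fname)
            _check(isinstance(cnt, int) and cnt >= 0, v, f"{base}.{fname}", cnt,
                   "non-negative integer")
    for i, a in enumerate(co.ae_items):
        base = f"costs.ae_items[{i}]"
        _check(a.cost_per_event >= 0, v, f"{base}.cost_per_event", a.cost_per_event,
               ">= 0")
        for arm in ARMS:
            rate = getattr(a.annual_rate, arm)
            _check(rate >= 0, v, f"{base}.annual_rate.{arm}", rate, ">= 0")

    pr = p.productivity
    _check(0 <= pr.employment_rate <= 1, v, "productivity.employment_rate",
           pr.employment_rate, "proportion in [0, 1]")
    _check(pr.hours_per_week >= 0, v, "productivity.hours_per_week",
           pr.hours_per_week, ">= 0")
    _check(pr.hourly_wage >= 0, v, "productivity.hourly_wage", pr.hourly_wage, ">= 0")
    _check(0 <= pr.baseline_pct_hours_lost <= 100, v,
           "productivity.baseline_pct_hours_lost", pr.baseline_pct_hours_lost,
           "percent in [0, 100]")
    _check(pr.baseline_pct_hours_lost - pr.responder_effect_lsm >= 0, v,
           "productivity.responder_effect_lsm",
           (pr.baseline_pct_hours_lost, pr.responder_effect_lsm),
           "baseline hours lost minus responder effect >= 0")
    _check(pr.weeks_per_year > 0, v, "productivity.weeks_per_year",
           pr.weeks_per_year, "> 0")

    for i, u in enumerate(p.uncertainty):
        base = f"uncertainty[{i}]"
        _check(u.family in FAMILIES, v, f"{base}.family", u.family,
               f"one of {FAMILIES}")
        if u.se is not None:
            _check(u.se >= 0, v, f"{base}.se", u.se, ">= 0")
        try:
            get_param(p, u.name)
        except AttributeError:
            v.append(Violation(f"{base}.name", u.name, "unknown parameter path"))
    return v


# ---------------------------------------------------------------------------
# default uncertainty registry
# ---------------------------------------------------------------------------


def default_uncertainty(p: ModelParameters) -> list[UncertainParameter]:
    """Uncertainty annotations for every varied input.

    Standard errors are attached where the input table prints one; all other
    entries fall back to the 20%-of-mean convention. Distribution families
    follow support: beta for proportions and utilities, gamma for costs,
    frequencies and durations, normal for the (signed) productivity effect
    and retirement age.
    """
    u: list[UncertainParameter] = []

    def add(name: str, family: str, se: float | None = None) -> None:
        u.append(UncertainParameter(name=name, family=family, se=se))

    for arm in ARMS:
        add(f"clinical.{arm}.p_response_16w", "beta")
        add(f"clinical.{arm}.p_disc_16_52w", "beta")
        add(f"clinical.{arm}.p_sustained_52w", "beta")
        add(f"clinical.{arm}.annual_disc_post52w", "beta")
        add(f"clinical.{arm}.waning_horizon_years", "gamma")
        add(f"clinical.{arm}.longterm_response_rate", "beta")
        add(f"utilities.{arm}.responder", "beta")
        add(f"utilities.{arm}.non_responder", "beta")

    add("costs.drug_unit_cost", "gamma")
    add("costs.hcru_unit_costs.hospitalization", "gamma", 5719.7)
    add("costs.hcru_unit_costs.primary_care_visit", "gamma", 19.9)
    add("costs.hcru_annual_freq.responder.hospitalization", "gamma", 0.0)
    add("costs.hcru_annual_freq.responder.primary_care_visit", "gamma", 0.04)
    add("costs.hcru_annual_freq.non_responder.hospitalization", "gamma", 0.0)
    add("costs.hcru_annual_freq.non_responder.primary_care_visit", "gamma", 0.08)
    add("costs.subsequent_monthly_cost", "gamma")
    for i, _t in enumerate(p.costs.monitoring_tests):
        add(f"costs.monitoring_tests[{i}].unit_cost", "gamma")
    for i, _a in enumerate(p.costs.ae_items):
        add(f"costs.ae_items[{i}].cost_per_event", "gamma")
        for arm in ARMS:
            add(f"costs.ae_items[{i}].annual_rate.{arm}", "beta")

    add("productivity.employment_rate", "beta", 0.1666)
    add("productivity.hours_per_week", "gamma", 7.36)
    add("productivity.hourly_wage", "gamma", 471.0)
    add("productivity.baseline_pct_hours_lost", "beta_pct", 6.2)
    add("productivity.responder_effect_lsm", "normal", 0.9)
    add("settings.retirement_age", "normal", 13.0)
    return u


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------


def _pct_in(x: float) -> float:
    return x / 100.0


def _pct_out(x: float) -> float:
    return round(x * 100.0, 12)


def _reject_unknown(d: dict, allowed: set[str], path: str) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        where = ", ".join(f"{path}.{k}" if path else k for k in unknown)
        raise ParameterError(f"unknown config key(s): {where}")


def _require(d: dict, key: str, path: str) -> Any:
    if key not in d:
        full = f"{path}.{key}" if path else key
        raise ParameterError(f"missing required config key: {full}")
    return d[key]


def _arm_clinical_from_dict(d: dict, path: str) -> ArmClinicalInputs:
    _reject_unknown(d, {"response_16w_pct", "disc_16_52w_pct", "sustained_52w_pct",
                        "annual_disc_post52w_pct", "waning_horizon_years",
                        "longterm_response_pct"}, path)
    return ArmClinicalInputs(
        p_response_16w=_pct_in(_require(d, "response_16w_pct", path)),
        p_disc_16_52w=_pct_in(_require(d, "disc_16_52w_pct", path)),
        p_sustained_52w=_pct_in(_require(d, "sustained_52w_pct", path)),
        annual_disc_post52w=_pct_in(_require(d, "annual_disc_post52w_pct", path)),
        waning_horizon_years=float(_require(d, "waning_horizon_years", path)),
        longterm_response_rate=_pct_in(_require(d, "longterm_response_pct", path)),
    )


def parameters_from_dict(raw: dict) -> ModelParameters:
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    _reject_unknown(raw, {"settings", "clinical", "utilities", "costs",
                          "productivity", "uncertainty"}, "")

    s = _require(raw, "settings", "")
    _reject_unknown(s, {"discount_rate_annual_pct", "cycle_length_years",
                        "start_age", "max_age", "retirement_age", "wtp_threshold",
                        "perspective", "yen_per_usd", "days_per_year"}, "settings")
    settings = EconSettings(
        discount_rate_annual=_pct_in(_require(s, "discount_rate_annual_pct", "settings")),
        cycle_length_years=float(_require(s, "cycle_length_years", "settings")),
        start_age=float(_require(s, "start_age", "settings")),
        max_age=float(_require(s, "max_age", "settings")),
        retirement_age=float(_require(s, "retirement_age", "settings")),
        wtp_threshold=float(_require(s, "wtp_threshold", "settings")),
        perspective=str(_require(s, "perspective", "settings")),
        yen_per_usd=float(_require(s, "yen_per_usd", "settings")),
        days_per_year=float(_require(s, "days_per_year", "settings")),
    )

    c = _require(raw, "clinical", "")
    _reject_unknown(c, set(ARMS), "clinical")
    clinical = ClinicalInputs(
        abrocitinib=_arm_clinical_from_dict(_require(c, "abrocitinib", "clinical"),
                                            "clinical.abrocitinib"),
        soc=_arm_clinical_from_dict(_require(c, "soc", "clinical"), "clinical.soc"),
    )

    ud = _require(raw, "utilities", "")
    _reject_unknown(ud, set(ARMS), "utilities")
    arm_utils = {}
    for arm in ARMS:
        a = _require(ud, arm, "utilities")
        _reject_unknown(a, {"responder", "non_responder"}, f"utilities.{arm}")
        arm_utils[arm] = ArmUtilities(
            responder=float(_require(a, "responder", f"utilities.{arm}")),
            non_responder=float(_require(a, "non_responder", f"utilities.{arm}")),
        )
    utilities = UtilitySet(**arm_utils)

    cd = _require(raw, "costs", "")
    _reject_unknown(cd, {"drug_unit_cost", "doses_per_day", "hcru_unit_costs",
                         "hcru_annual_freq", "monitoring_tests", "ae_items",
                         "subsequent_monthly_cost"}, "costs")
    huc = _require(cd, "hcru_unit_costs", "costs")
    _reject_unknown(huc, {"hospitalization", "primary_care_visit"},
                    "costs.hcru_unit_costs")
    hf = _require(cd, "hcru_annual_freq", "costs")
    _reject_unknown(hf, {"responder", "non_responder"}, "costs.hcru_annual_freq")
    freq = {}
    for status in ("responder", "non_responder"):
        fd = _require(hf, status, "costs.hcru_annual_freq")
        fp = f"costs.hcru_annual_freq.{status}"
        _reject_unknown(fd, {"hospitalization", "primary_care_visit"}, fp)
        freq[status] = HcruFrequencies(
            hospitalization=float(_require(fd, "hospitalization", fp)),
            primary_care_visit=float(_require(fd, "primary_care_visit", fp)),
        )
    tests = []
    for i, td in enumerate(_require(cd, "monitoring_tests", "costs")):
        tp = f"costs.monitoring_tests[{i}]"
        _reject_unknown(td, {"name", "unit_cost", "count_year1", "count_year2plus"}, tp)
        tests.append(MonitoringTest(
            name=str(_require(td, "name", tp)),
            unit_cost=float(_require(td, "unit_cost", tp)),
            count_year1=int(_require(td, "count_year1", tp)),
            count_year2plus=int(_require(td, "count_year2plus", tp)),
        ))
    aes = []
    for i, ad in enumerate(_require(cd, "ae_items", "costs")):
        ap = f"costs.ae_items[{i}]"
        _reject_unknown(ad, {"name", "cost_per_event", "annual_rate_pct"}, ap)
        rd = _require(ad, "annual_rate_pct", ap)
        _reject_unknown(rd, set(ARMS), f"{ap}.annual_rate_pct")
        aes.append(AEItem(
            name=str(_require(ad, "name", ap)),
            cost_per_event=float(_require(ad, "cost_per_event", ap)),
            annual_rate=AERates(
                abrocitinib=_pct_in(_require(rd, "abrocitinib", f"{ap}.annual_rate_pct")),
                soc=_pct_in(_require(rd, "soc", f"{ap}.annual_rate_pct")),
            ),
        ))
    costs = CostInputs(
        drug_unit_cost=float(_require(cd, "drug_unit_cost", "costs")),
        doses_per_day=float(_require(cd, "doses_per_day", "costs")),
        hcru_unit_costs=HcruUnitCosts(
            hospitalization=float(_require(huc, "hospitalization", "costs.hcru_unit_costs")),
            primary_care_visit=float(_require(huc, "primary_care_visit", "costs.hcru_unit_costs")),
        ),
        hcru_annual_freq=HcruFrequencySet(**freq),
        monitoring_tests=tests,
        ae_items=aes,
        subsequent_monthly_cost=float(_require(cd, "subsequent_monthly_cost", "costs")),
    )

    pd_ = _require(raw, "productivity", "")
    _reject_unknown(pd_, {"employment_rate_pct", "hours_per_week", "hourly_wage",
                          "baseline_pct_hours_lost", "responder_effect_lsm",
                          "weeks_per_year"}, "productivity")
    productivity = ProductivityInputs(
        employment_rate=_pct_in(_require(pd_, "employment_rate_pct", "productivity")),
        hours_per_week=float(_require(pd_, "hours_per_week", "productivity")),
        hourly_wage=float(_require(pd_, "hourly_wage", "productivity")),
        baseline_pct_hours_lost=float(_require(pd_, "baseline_pct_hours_lost", "productivity")),
        responder_effect_lsm=float(_require(pd_, "responder_effect_lsm", "productivity")),
        weeks_per_year=float(_require(pd_, "weeks_per_year", "productivity")),
    )

    p = ModelParameters(settings=settings, clinical=clinical, utilities=utilities,
                        costs=costs, productivity=productivity)

    if "uncertainty" in raw and raw["uncertainty"] is not None:
        ulist = []
        for i, udict in enumerate(raw["uncertainty"]):
            up = f"uncertainty[{i}]"
            _reject_unknown(udict, {"name", "family", "se", "owsa_fraction"}, up)
            ulist.append(UncertainParameter(
                name=str(_require(udict, "name", up)),
                family=str(_require(udict, "family", up)),
                se=None if udict.get("se") is None else float(udict["se"]),
                owsa_fraction=float(udict.get("owsa_fraction", 0.20)),
            ))
        p.uncertainty = ulist
    else:
        p.uncertainty = default_uncertainty(p)
    return p


def parameters_to_dict(p: ModelParameters) -> dict:
    s, pr = p.settings, p.productivity

    def arm_clin(c: ArmClinicalInputs) -> dict:
        return {
            "response_16w_pct": _pct_out(c.p_response_16w),
            "disc_16_52w_pct": _pct_out(c.p_disc_16_52w),
            "sustained_52w_pct": _pct_out(c.p_sustained_52w),
            "annual_disc_post52w_pct": _pct_out(c.annual_disc_post52w),
            "waning_horizon_years": c.waning_horizon_years,
            "longterm_response_pct": _pct_out(c.longterm_response_rate),
        }

    return {
        "settings": {
            "discount_rate_annual_pct": _pct_out(s.discount_rate_annual),
            "cycle_length_years": s.cycle_length_years,
            "start_age": s.start_age,
            "max_age": s.max_age,
            "retirement_age": s.retirement_age,
            "wtp_threshold": s.wtp_threshold,
            "perspective": s.perspective,
            "yen_per_usd": s.yen_per_usd,
            "days_per_year": s.days_per_year,
        },
        "clinical": {arm: arm_clin(p.clinical.for_arm(arm)) for arm in ARMS},
        "utilities": {arm: {"responder": p.utilities.for_arm(arm).responder,
                            "non_responder": p.utilities.for_arm(arm).non_responder}
                      for arm in ARMS},
        "costs": {
            "drug_unit_cost": p.costs.drug_unit_cost,
            "doses_per_day": p.costs.doses_per_day,
            "hcru_unit_costs": {
                "hospitalization": p.costs.hcru_unit_costs.hospitalization,
                "primary_care_visit": p.costs.hcru_unit_costs.primary_care_visit,
            },
            "hcru_annual_freq": {
                status: {
                    "hospitalization": getattr(p.costs.hcru_annual_freq, status).hospitalization,
                    "primary_care_visit": getattr(p.costs.hcru_annual_freq, status).primary_care_visit,
                } for status in ("responder", "non_responder")
            },
            "monitoring_tests": [
                {"name": t.name, "unit_cost": t.unit_cost,
                 "count_year1": t.count_year1, "count_year2plus": t.count_year2plus}
                for t in p.costs.monitoring_tests
            ],
            "ae_items": [
                {"name": a.name, "cost_per_event": a.cost_per_event,
                 "annual_rate_pct": {"abrocitinib": _pct_out(a.annual_rate.abrocitinib),
                                     "soc": _pct_out(a.annual_rate.soc)}}
                for a in p.costs.ae_items
            ],
            "subsequent_monthly_cost": p.costs.subsequent_monthly_cost,
        },
        "productivity": {
            "employment_rate_pct": _pct_out(pr.employment_rate),
            "hours_per_week": pr.hours_per_week,
            "hourly_wage": pr.hourly_wage,
            "baseline_pct_hours_lost": pr.baseline_pct_hours_lost,
            "responder_effect_lsm": pr.responder_effect_lsm,
            "weeks_per_year": pr.weeks_per_year,
        },
        "uncertainty": [
            {"name": u.name, "family": u.family, "se": u.se,
             "owsa_fraction": u.owsa_fraction}
            for u in p.uncertainty
        ],
    }


def load_parameters(source: str | Path) -> ModelParameters:
    """Load and validate a parameter config.

    ``source`` is a path to a YAML file, the literal string ``"basecase"``
    for the packaged base-case fixture, or YAML text containing a newline.
    """
    text: str
    if isinstance(source, Path) or "\n" not in str(source):
        if str(source) == "basecase":
            text = _basecase_text()
        else:
            path = Path(source)
            if not path.exists():
                raise ParameterError(f"config file not found: {path}")
            text = path.read_text()
    else:
        text = str(source)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ParameterError(f"config does not parse as YAML: {e}") from e
    p = parameters_from_dict(raw)
    violations = validate_parameters(p)
    if violations:
        msg = "; ".join(str(x) for x in violations)
        raise ParameterError(f"invalid parameters: {msg}")
    return p


def save_parameters(p: ModelParameters, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(parameters_to_dict(p), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _basecase_text() -> str:
    from importlib.resources import files
    return files("adcea.data").joinpath("basecase.yaml").read_text()


def load_basecase() -> ModelParameters:
    """The packaged base-case input set."""
    return load_parameters(_basecase_text())
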