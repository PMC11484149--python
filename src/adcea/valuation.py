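"""Costing and utility valuation of cohort person-time.

Person-time is classified into three statuses:

``pre``
    Weeks 0-16, before the first response assessment. Everyone carries
    non-responder utility and non-responder resource use; the abrocitinib
    arm is on drug (acquisition, monitoring, drug-specific adverse-event
    rates), the comparator arm is not.
``resp``
    On-treatment responders: weeks 16-52 after a positive assessment, and
    the ``in_response`` Markov state. Arm-specific responder utility,
    responder resource use; the abrocitinib arm accrues drug and
    monitoring cost.
``nonresp``
    Off initial treatment (never responded, discontinued, or lost
    response). Standard-of-care non-responder utility, non-responder
    resource use, and the monthly subsequent-treatment cost.

Subsequent-treatment spend is booked under ``drug_acquisition`` and accrues
on *all* non-responder person-time (including weeks 0-16): "years receiving
subsequent treatment" then equals total life-years minus years in response,
and for the comparator arm — whose topicals cost nothing — the
drug-acquisition row is exactly the discounted subsequent-treatment spend.

All cash amounts are JPY; costs and QALYs are discounted at the annual
rate in the settings, evaluated at cycle midpoints; life-years are
reported undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ModelParameters

CATEGORIES = ("drug_acquisition", "ae", "hcru", "monitoring")
STATUSES = ("pre", "resp", "nonresp")


def discount_factor(t_years: float, rate: float) -> float:
    """(1 + rate)^(-t): present-value weight at time t from model start."""
    if t_years < 0:
        raise ValueError("discount time must be non-negative")
    return (1.0 + rate) ** (-t_years)


def annual_drug_cost(p: ModelParameters, arm: str, state: str) -> float:
    """Annual acquisition cost of the initial drug (excl. subsequent Tx)."""
    if arm == "abrocitinib" and state == "in_response":
        c = p.costs
        return c.drug_unit_cost * c.doses_per_day * p.settings.days_per_year
    return 0.0


def annual_subsequent_cost(p: ModelParameters, state: str) -> float:
    """Monthly subsequent-treatment cost annualized over non-response time."""
    if state == "non_response":
        return p.costs.subsequent_monthly_cost * 12.0
    return 0.0


def annual_hcru_cost(p: ModelParameters, status: str) -> float:
    """Hospitalization + primary-care spend per year, by response status."""
    freq = getattr(p.costs.hcru_annual_freq, status)
    unit = p.costs.hcru_unit_costs
    return (freq.hospitalization * unit.hospitalization
            + freq.primary_care_visit * unit.primary_care_visit)


def annual_monitoring_cost(p: ModelParameters, arm: str, model_year: int) -> float:
    """Laboratory-monitoring cost while on drug; year-1 vs year-2+ schedules."""
    if arm != "abrocitinib":
        return 0.0
    if model_year < 1:
        raise ValueError("model_year is 1-based")
    total = 0.0
    for t in p.costs.monitoring_tests:
        count = t.count_year1 if model_year == 1 else t.count_year2plus
        total += count * t.unit_cost
    return total


def annual_ae_cost(p: ModelParameters, arm: str) -> float:
    """Expected adverse-event management cost per year on ``arm``'s drug."""
    return sum(getattr(a.annual_rate, arm) * a.cost_per_event
               for a in p.costs.ae_items)


def lost_income_rate(p: ModelParameters, status: str) -> float:
    """Annual productivity loss (human-capital approach), working ages only."""
    pr = p.productivity
    if status == "responder":
        lost_pct = pr.baseline_pct_hours_lost - pr.responder_effect_lsm
    else:
        lost_pct = pr.baseline_pct_hours_lost
    lost_fraction = max(lost_pct, 0.0) / 100.0
    return (pr.employment_rate * pr.hours_per_week * pr.weeks_per_year
            * pr.hourly_wage * lost_fraction)


def annual_lost_income(p: ModelParameters, age: float, status: str) -> float:
    if age >= p.settings.retirement_age:
        return 0.0
    return lost_income_rate(p, status)


def working_fraction(p: ModelParameters, age_start: float, dt: float) -> float:
    """Share of the interval [age_start, age_start+dt) before retirement."""
    remaining = p.settings.retirement_age - age_start
    if remaining <= 0:
        return 0.0
    return min(remaining / dt, 1.0)


@dataclass
class StatusRates:
    """Annual accrual rates for one (arm, status, year-schedule) combination."""

    utility: float
    lost_income: float
    in_response: bool
    costs: dict[str, float]


def status_rates(p: ModelParameters, arm: str, status: str,
                 model_year: int) -> StatusRates:
    """Assemble all annual accrual rates for one status.

    This single routine is shared by the cohort engine and the
    individual-level simulation oracle, so any disagreement between the two
    isolates the Markov algebra rather than the costing constants.
    """
    if status == "pre":
        on_drug = arm == "abrocitinib"
        drug = (annual_drug_cost(p, arm, "in_response") if on_drug else 0.0) \
            + annual_subsequent_cost(p, "non_response")
        return StatusRates(
            utility=p.utilities.for_arm(arm).non_responder if on_drug
            else p.utilities.soc.non_responder,
            lost_income=lost_income_rate(p, "non_responder"),
            in_response=False,
            costs={
                "drug_acquisition": drug,
                "ae": annual_ae_cost(p, arm),
                "hcru": annual_hcru_cost(p, "non_responder"),
                "monitoring": annual_monitoring_cost(p, arm, model_year),
            },
        )
    if status == "resp":
        return StatusRates(
            utility=p.utilities.for_arm(arm).responder,
            lost_income=lost_income_rate(p, "responder"),
            in_response=True,
            costs={
                "drug_acquisition": annual_drug_cost(p, arm, "in_response"),
                "ae": annual_ae_cost(p, arm),
                "hcru": annual_hcru_cost(p, "responder"),
                "monitoring": annual_monitoring_cost(p, arm, model_year),
            },
        )
    if status == "nonresp":
        return StatusRates(
            utility=p.utilities.soc.non_responder,
            lost_income=lost_income_rate(p, "non_responder"),
            in_response=False,
            costs={
                "drug_acquisition": annual_subsequent_cost(p, "non_response"),
                "ae": annual_ae_cost(p, "soc"),
                "hcru": annual_hcru_cost(p, "non_responder"),
                "monitoring": 0.0,
            },
        )
    raise ValueError(f"unknown status: {status}")


@dataclass
class Accruals:
    """Running totals for one arm: undiscounted time, discounted value."""

    ly: float = 0.0                       # undiscounted life-years
    qaly: float = 0.0                     # discounted
    years_in_response: float = 0.0        # undiscounted
    lost_income: float = 0.0              # discounted
    costs: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CATEGORIES})

    def add(self, other: "Accruals") -> "Accruals":
        out = Accruals(
            ly=self.ly + other.ly,
            qaly=self.qaly + other.qaly,
            years_in_response=self.years_in_response + other.years_in_response,
            lost_income=self.lost_income + other.lost_income,
            costs={c: self.costs[c] + other.costs[c] for c in CATEGORIES},
        )
        return out


def accrue_interval(p: ModelParameters, arm: str, weights: dict[str, float],
                    dt: float, t_disc: float, model_year: int,
                    age_start: float, acc: Accruals,
                    rates: dict[str, StatusRates] | None = None) -> None:
    """Accrue ``dt`` years of person-time onto ``acc``.

    ``weights`` maps status -> (half-cycle-corrected) occupancy; ``t_disc``
    is the discounting time for the whole enclosing cycle (its midpoint).
    ``rates`` may carry precomputed :func:`status_rates` for this model
    year (the per-cycle loops reuse them).
    """
    df = discount_factor(t_disc, p.settings.discount_rate_annual)
    wf = working_fraction(p, age_start, dt)
    for status, w in weights.items():
        if w <= 0.0:
            continue
        r = rates[status] if rates is not None else \
            status_rates(p, arm, status, model_year)
        acc.ly += w * dt
        acc.qaly += w * r.utility * dt * df
        acc.lost_income += w * r.lost_income * wf * dt * df
        if r.in_response:
            acc.years_in_response += w * dt
        for cat in CATEGORIES:
            acc.costs[cat] += w * r.costs[cat] * dt * df
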