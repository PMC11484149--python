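"""Synthetic inputs: life tables, perturbed parameter sets, and an
individual-level simulation oracle.

The package needs an adult life table but ships no external data. A
Gompertz-Makeham hazard (constant background component plus an
exponentially age-increasing component) produces a realistic national-level
mortality schedule; the defaults are set so that remaining life expectancy
at age 38 is about 46-47 years, the scale of the Japanese adult population
the model describes.

The microsimulation oracle replays the identical event logic of the cohort
engine — response assessment, discontinuation, sustained response,
per-cycle waning/discontinuation/death — one individual at a time with
Bernoulli draws, and values person-time through the same
:mod:`~adcea.valuation` rates. It shares no cohort-trace code, so agreement
with the engine checks the Markov algebra independently of the costing
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import WEEK16_YEARS, per_cycle_exit_probability
from .mortality import LifeTable, per_cycle_probability
from .parameters import ModelParameters, load_basecase, validate_parameters
from .valuation import CATEGORIES, discount_factor, status_rates, working_fraction


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard mu(age) = makeham_a + gompertz_b * exp(gompertz_c * age)."""

    makeham_a: float = 2.0e-4      # age-independent hazard / year
    gompertz_b: float = 3.2e-6     # senescent hazard scale / year
    gompertz_c: float = 0.1180     # senescent hazard log-slope / year
    max_age: int = 110


def make_synthetic_life_table(g: GompertzMakehamParams | None = None) -> LifeTable:
    """Annual death probabilities qx = 1 - exp(-mu(age)), closed at max_age."""
    g = g or GompertzMakehamParams()
    if g.makeham_a < 0 or g.gompertz_b <= 0 or g.gompertz_c <= 0:
        raise ValueError("require a >= 0, b > 0, c > 0")
    ages = np.arange(0, g.max_age + 1)
    hazard = g.makeham_a + g.gompertz_b * np.exp(g.gompertz_c * ages)
    qx = np.minimum(1.0 - np.exp(-hazard), 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def make_test_parameters(seed: int = 0, scale: str = "base") -> ModelParameters:
    """Packaged base case (``scale="base"``) or a randomized-but-valid
    parameter set for property testing (``scale="stress"``)."""
    p = load_basecase()
    if scale == "base":
        return p
    if scale != "stress":
        raise ValueError(f"unknown scale: {scale}")
    rng = np.random.default_rng(seed)

    def prob(lo: float, hi: float) -> float:
        # construct proportions as percent/100 so the percent representation
        # used on config I/O round-trips exactly
        return round(float(rng.uniform(lo, hi)) * 100.0, 4) / 100.0

    for arm in ("abrocitinib", "soc"):
        c = p.clinical.for_arm(arm)
        c.p_response_16w = prob(0.02, 0.95)
        c.p_disc_16_52w = prob(0.0, 0.3)
        c.p_sustained_52w = prob(0.1, 0.95)
        c.annual_disc_post52w = prob(0.0, 0.3)
        c.waning_horizon_years = rng.uniform(2.0, 15.0)
        c.longterm_response_rate = min(
            round(c.p_sustained_52w * float(rng.uniform(0.0, 1.0)) * 100.0,
                  4) / 100.0,
            c.p_sustained_52w)
        u = p.utilities.for_arm(arm)
        u.non_responder = rng.uniform(0.3, 0.9)
        u.responder = rng.uniform(u.non_responder, 1.0)

    co = p.costs
    jitter = lambda x: x * rng.lognormal(0.0, 0.5)  # noqa: E731
    co.drug_unit_cost = jitter(co.drug_unit_cost)
    co.subsequent_monthly_cost = jitter(co.subsequent_monthly_cost)
    co.hcru_unit_costs.hospitalization = jitter(co.hcru_unit_costs.hospitalization)
    co.hcru_unit_costs.primary_care_visit = jitter(co.hcru_unit_costs.primary_care_visit)
    for status in ("responder", "non_responder"):
        f = getattr(co.hcru_annual_freq, status)
        f.hospitalization = jitter(f.hospitalization)
        f.primary_care_visit = jitter(f.primary_care_visit)
    for t in co.monitoring_tests:
        t.unit_cost = jitter(t.unit_cost)
    for a in co.ae_items:
        a.cost_per_event = jitter(a.cost_per_event)
        a.annual_rate.abrocitinib = prob(0.0, 0.5)
        a.annual_rate.soc = prob(0.0, 0.5)

    pr = p.productivity
    pr.employment_rate = prob(0.3, 1.0)
    pr.hours_per_week = rng.uniform(20.0, 60.0)
    pr.hourly_wage = jitter(pr.hourly_wage)
    pr.baseline_pct_hours_lost = rng.uniform(5.0, 80.0)
    pr.responder_effect_lsm = rng.uniform(0.0, pr.baseline_pct_hours_lost)

    p.settings.discount_rate_annual = prob(0.0, 0.05)
    problems = validate_parameters(p)
    assert not problems, problems  # generator must only emit valid sets
    return p


@dataclass
class OracleResult:
    """Sample means and standard errors over simulated individuals."""

    n: int
    seed: int
    mean: dict[str, float]
    se: dict[str, float]


_METRICS = ("ly", "qaly", "years_in_response", "lost_income") + CATEGORIES

_PRE, _RESP, _NONRESP = 0, 1, 2


def _rate_pack(p: ModelParameters, arm: str, model_year: int):
    """Per-status rate vectors indexed by the integer status codes."""
    packs = [status_rates(p, arm, st, model_year)
             for st in ("pre", "resp", "nonresp")]
    return {
        "utility": np.array([r.utility for r in packs]),
        "lost_income": np.array([r.lost_income for r in packs]),
        "in_response": np.array([1.0 if r.in_response else 0.0 for r in packs]),
        **{cat: np.array([r.costs[cat] for r in packs]) for cat in CATEGORIES},
    }


def microsim_oracle(p: ModelParameters, lt: LifeTable, arm: str,
                    n_individuals: int, seed: int = 0) -> OracleResult:
    """Simulate individuals through the full pathway; value as the engine does."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    n = n_individuals
    rng = np.random.default_rng(seed)
    s = p.settings
    dt = s.cycle_length_years
    c = p.clinical.for_arm(arm)
    rate1 = _rate_pack(p, arm, model_year=1)
    rate2 = _rate_pack(p, arm, model_year=2)
    acc = {m: np.zeros(n) for m in _METRICS}

    def accrue(statuses, weights, dt_i, t_disc, age_start, pack):
        df = discount_factor(t_disc, s.discount_rate_annual)
        wf = working_fraction(p, age_start, dt_i)
        acc["ly"] += weights * dt_i
        acc["qaly"] += weights * pack["utility"][statuses] * dt_i * df
        acc["lost_income"] += weights * pack["lost_income"][statuses] * wf * dt_i * df
        acc["years_in_response"] += weights * pack["in_response"][statuses] * dt_i
        for cat in CATEGORIES:
            acc[cat] += weights * pack[cat][statuses] * dt_i * df

    # --- decision tree -------------------------------------------------------
    d1 = per_cycle_probability(lt.annual_q(s.start_age), dt)
    died1 = rng.random(n) < d1
    w1 = np.where(died1, 0.5, 1.0)
    resp16 = rng.random(n) < c.p_response_16w
    disc = rng.random(n) < c.p_disc_16_52w
    keep = resp16 & ~disc
    status = np.where(keep, _RESP, _NONRESP)

    pre_dt = min(WEEK16_YEARS, dt)
    accrue(np.full(n, _PRE), w1, pre_dt, dt / 2.0, s.start_age, rate1)
    accrue(status, w1, dt - pre_dt, dt / 2.0, s.start_age + pre_dt, rate1)
    alive = ~died1

    d2 = per_cycle_probability(lt.annual_q(s.start_age + dt), dt)
    died2 = alive & (rng.random(n) < d2)
    w2 = np.where(died2, 0.5, np.where(alive, 1.0, 0.0))
    accrue(status, w2, dt, 1.5 * dt, s.start_age + dt, rate1)
    alive &= ~died2

    sustained = rng.random(n) < c.p_sustained_52w
    in_resp = alive & keep & sustained
    status = np.where(in_resp, _RESP, _NONRESP)

    # --- maintenance phase ---------------------------------------------------
    k = 0
    while alive.any():
        t = 2 * dt + k * dt
        age = s.start_age + t
        d = per_cycle_probability(lt.annual_q(age), dt)
        e = per_cycle_exit_probability(k, arm, p)
        die = alive & (rng.random(n) < d)
        exits = (rng.random(n) < e) & alive & ~die & (status == _RESP)

        w_resp = np.zeros(n)
        w_nr = np.zeros(n)
        resp_mask = alive & (status == _RESP)
        nr_mask = alive & (status == _NONRESP)
        w_resp[resp_mask & ~die & ~exits] = 1.0
        w_resp[resp_mask & die] = 0.5
        w_resp[exits] = 0.5
        w_nr[exits] = 0.5
        w_nr[nr_mask & ~die] = 1.0
        w_nr[nr_mask & die] = 0.5

        df = discount_factor(t + dt / 2.0, s.discount_rate_annual)
        wf = working_fraction(p, age, dt)
        for code, w in ((_RESP, w_resp), (_NONRESP, w_nr)):
            acc["ly"] += w * dt
            acc["qaly"] += w * rate2["utility"][code] * dt * df
            acc["lost_income"] += w * rate2["lost_income"][code] * wf * dt * df
            acc["years_in_response"] += w * rate2["in_response"][code] * dt
            for cat in CATEGORIES:
                acc[cat] += w * rate2[cat][code] * dt * df

        status[exits] = _NONRESP
        alive &= ~die
        k += 1
        if age >= lt.max_age:
            break

    mean = {m: float(np.mean(acc[m])) for m in _METRICS}
    se = {m: float(np.std(acc[m], ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
          for m in _METRICS}
    return OracleResult(n=n, seed=seed, mean=mean, se=se)
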