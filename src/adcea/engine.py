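"""Cohort engine: 52-week decision tree followed by a three-state Markov model.

Model timeline (6-month cycles, half-cycle-corrected accrual, discounting
from time 0):

* Cycle 1 (weeks 0-26): everyone starts on the assigned treatment with
  non-responder status. At week 16 (16/52 years into the cycle) response is
  assessed; responders on abrocitinib then face the 16-52-week
  discontinuation probability. Non-responders and discontinuers move to
  standard of care / subsequent treatment immediately.
* Cycle 2 (weeks 26-52): on-treatment responders vs. non-responders.
* Week 52: responders still on treatment are assessed for sustained
  response; sustainers enter the Markov ``in_response`` state, everyone
  else alive enters ``non_response``.
* Markov phase: 6-month cycles until the life-table maximum age. Each
  cycle applies background mortality to both living states first, then
  moves a fraction of ``in_response`` to ``non_response``. That exit
  combines response waning (a linear decline of the maintenance survival
  curve) with a constant annual discontinuation probability as independent
  competing risks; neither applies to the comparator arm's discontinuation
  (assumed zero) and waning stops at its horizon.

Occupancy is conserved to ~1e-12 every cycle and the dead state is
absorbing. Accrual weights are the mean of begin- and end-of-cycle
occupancy (``timing="mid"``); the ``begin``/``end`` variants exist to
bracket the half-cycle-corrected totals in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import valuation
from .mortality import LifeTable, per_cycle_probability
from .parameters import ModelParameters
from .valuation import Accruals, accrue_interval, status_rates

STATES = ("in_response", "non_response", "dead")

WEEK16_YEARS = 16.0 / 52.0   # response assessment within cycle 1


@dataclass
class InitialPhaseResult:
    """Cohort composition entering the Markov phase, plus week 0-52 accruals."""

    occupancy: dict[str, float]
    accruals: Accruals
    rows: list[dict] = field(default_factory=list)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accrual records for the maintenance phase."""

    table: pd.DataFrame
    accruals: Accruals


@dataclass
class ArmResult:
    arm: str
    init: InitialPhaseResult
    trace: CohortTrace
    accruals: Accruals   # decision tree + Markov combined


def waning_survival(p: ModelParameters, arm: str, t_years: float) -> float:
    """Fraction of week-52 maintenance entrants still in response at t.

    Mortality and post-52-week discontinuation excluded: this is the pure
    response-waning curve. It declines linearly from 1 at t = 0 (week 52)
    to the long-term response rate at t = ``waning_horizon_years``, stays
    constant afterwards, and is floored at 0. The long-term rate is read
    as the fraction of maintenance entrants still responding at the
    horizon; anchoring it on the conditional ratio to the 52-week
    sustained-response probability instead leaves response persistence
    (and with it the incremental QALY) visibly too high against the
    published deterministic results.
    """
    if t_years < 0:
        raise ValueError("time since week 52 must be non-negative")
    c = p.clinical.for_arm(arm)
    floor = c.longterm_response_rate
    span = c.waning_horizon_years
    frac = min(t_years, span) / span
    return max(1.0 + (floor - 1.0) * frac, 0.0)


def per_cycle_exit_probability(cycle_index: int, arm: str,
                               p: ModelParameters) -> float:
    """Probability of leaving ``in_response`` during one maintenance cycle.

    ``cycle_index`` counts maintenance cycles from 0 (the cycle starting at
    week 52). Waning loss and discontinuation act as independent competing
    exits.
    """
    dt = p.settings.cycle_length_years
    t = cycle_index * dt
    w0 = waning_survival(p, arm, t)
    w1 = waning_survival(p, arm, t + dt)
    wane = 1.0 - w1 / w0 if w0 > 0.0 else 0.0
    disc = per_cycle_probability(p.clinical.for_arm(arm).annual_disc_post52w, dt)
    return 1.0 - (1.0 - wane) * (1.0 - disc)


def _cycle_weight(begin: float, end: float, timing: str) -> float:
    if timing == "mid":
        return 0.5 * (begin + end)
    if timing == "begin":
        return begin
    if timing == "end":
        return end
    raise ValueError(f"unknown accrual timing: {timing}")


def run_decision_tree(p: ModelParameters, arm: str, lt: LifeTable,
                      timing: str = "mid") -> InitialPhaseResult:
    """Weeks 0-52: response assessment, discontinuation, sustained response."""
    s = p.settings
    dt = s.cycle_length_years
    c = p.clinical.for_arm(arm)
    acc = Accruals()
    rates = {st: status_rates(p, arm, st, model_year=1)
             for st in valuation.STATUSES}

    # week-16 split (applied within cycle 1, independent of that cycle's deaths)
    keep = c.p_response_16w * (1.0 - c.p_disc_16_52w)  # on-drug responders
    rows = []

    alive = 1.0
    # --- cycle 1: weeks 0-26 -------------------------------------------------
    d1 = per_cycle_probability(lt.annual_q(s.start_age), dt)
    alive1 = alive * (1.0 - d1)
    w1 = _cycle_weight(alive, alive1, timing)
    pre_dt = min(WEEK16_YEARS, dt)
    accrue_interval(p, arm, {"pre": w1}, pre_dt, t_disc=dt / 2.0, model_year=1,
                    age_start=s.start_age, acc=acc, rates=rates)
    accrue_interval(p, arm, {"resp": w1 * keep, "nonresp": w1 * (1.0 - keep)},
                    dt - pre_dt, t_disc=dt / 2.0, model_year=1,
                    age_start=s.start_age + pre_dt, acc=acc, rates=rates)
    rows.append({"cycle": -2, "time_years": 0.0,
                 "in_response": alive1 * keep,
                 "non_response": alive1 * (1.0 - keep),
                 "dead": 1.0 - alive1})

    # --- cycle 2: weeks 26-52 ------------------------------------------------
    d2 = per_cycle_probability(lt.annual_q(s.start_age + dt), dt)
    alive2 = alive1 * (1.0 - d2)
    w2 = _cycle_weight(alive1, alive2, timing)
    accrue_interval(p, arm, {"resp": w2 * keep, "nonresp": w2 * (1.0 - keep)},
                    dt, t_disc=1.5 * dt, model_year=1,
                    age_start=s.start_age + dt, acc=acc, rates=rates)

    # --- week-52 sustained-response assessment -------------------------------
    in_resp = alive2 * keep * c.p_sustained_52w
    occupancy = {"in_response": in_resp,
                 "non_response": alive2 - in_resp,
                 "dead": 1.0 - alive2}
    rows.append({"cycle": -1, "time_years": dt,
                 "in_response": in_resp,
                 "non_response": alive2 - in_resp,
                 "dead": 1.0 - alive2})
    return InitialPhaseResult(occupancy=occupancy, accruals=acc, rows=rows)


def run_markov(p: ModelParameters, arm: str, init: InitialPhaseResult,
               lt: LifeTable, timing: str = "mid") -> CohortTrace:
    """Maintenance phase from week 52 until the life-table maximum age."""
    s = p.settings
    dt = s.cycle_length_years
    tree_years = 2 * dt  # decision-tree horizon (52 weeks)
    acc = Accruals()
    # maintenance model years are >= 2: year-2+ monitoring schedule throughout
    rates = {st: status_rates(p, arm, st, model_year=2)
             for st in valuation.STATUSES}

    ir = init.occupancy["in_response"]
    nr = init.occupancy["non_response"]
    dead = init.occupancy["dead"]

    rows = []
    k = 0
    while (ir + nr) > 1e-15:
        t = tree_years + k * dt
        age = s.start_age + t
        d = per_cycle_probability(lt.annual_q(age), dt)
        ir_s = ir * (1.0 - d)          # death first, equal in both living states
        nr_s = nr * (1.0 - d)
        e = per_cycle_exit_probability(k, arm, p)
        moved = ir_s * e
        ir_end = ir_s - moved
        nr_end = nr_s + moved
        dead_end = dead + (ir + nr) * d

        w_ir = _cycle_weight(ir, ir_end, timing)
        w_nr = _cycle_weight(nr, nr_end, timing)
        accrue_interval(p, arm, {"resp": w_ir, "nonresp": w_nr}, dt,
                        t_disc=t + dt / 2.0, model_year=2, age_start=age,
                        acc=acc, rates=rates)

        ir, nr, dead = ir_end, nr_end, dead_end
        rows.append({"cycle": k, "time_years": t + dt,
                     "in_response": ir, "non_response": nr, "dead": dead})
        k += 1
        if age >= lt.max_age:
            break

    table = pd.DataFrame(rows, columns=["cycle", "time_years", "in_response",
                                        "non_response", "dead"])
    return CohortTrace(table=table, accruals=acc)


def run_arm(p: ModelParameters, arm: str, lt: LifeTable,
            timing: str = "mid") -> ArmResult:
    """Full deterministic run of one arm (decision tree then Markov)."""
    init = run_decision_tree(p, arm, lt, timing=timing)
    trace = run_markov(p, arm, init, lt, timing=timing)
    return ArmResult(arm=arm, init=init, trace=trace,
                     accruals=init.accruals.add(trace.accruals))


def full_trace(res: ArmResult) -> pd.DataFrame:
    """Initial-phase and maintenance occupancy in one exportable table."""
    tree = pd.DataFrame(res.init.rows)
    return pd.concat([tree, res.trace.table], ignore_index=True)
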