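"""Cost-effectiveness analysis layer: deterministic ICERs, start-age
calibration, one-way and probabilistic sensitivity analysis, and
cost-effectiveness acceptability curves.

Perspectives differ only in aggregation: the societal perspective adds
discounted lost income (human-capital productivity loss) to the payer
total; QALYs are identical under both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ArmResult, run_arm
from .mortality import LifeTable, life_expectancy
from .parameters import (
    ARMS,
    ModelParameters,
    UncertainParameter,
    get_param,
    set_param,
)
logger = logging.getLogger(__name__)

_EPS_QALY = 1e-12


@dataclass
class ArmSummary:
    ly: float
    qaly: float
    years_in_response: float
    years_subsequent: float
    costs: dict[str, float]
    lost_income: float

    @property
    def total_payer(self) -> float:
        return sum(self.costs.values())

    @property
    def total_societal(self) -> float:
        return self.total_payer + self.lost_income


@dataclass
class CEAResult:
    perspective: str
    arms: dict[str, ArmSummary]
    arm_results: dict[str, ArmResult] = field(repr=False, default_factory=dict)

    @property
    def inc_qaly(self) -> float:
        return self.arms["abrocitinib"].qaly - self.arms["soc"].qaly

    @property
    def inc_cost_payer(self) -> float:
        return (self.arms["abrocitinib"].total_payer
                - self.arms["soc"].total_payer)

    @property
    def inc_lost_income(self) -> float:
        return (self.arms["abrocitinib"].lost_income
                - self.arms["soc"].lost_income)

    @property
    def inc_cost_societal(self) -> float:
        return self.inc_cost_payer + self.inc_lost_income

    @property
    def inc_cost(self) -> float:
        return (self.inc_cost_societal if self.perspective == "societal"
                else self.inc_cost_payer)

    @property
    def icer(self) -> float | None:
        """Incremental cost per QALY; None when the QALY difference is nil."""
        if abs(self.inc_qaly) < _EPS_QALY:
            return None
        return self.inc_cost / self.inc_qaly


def summarize_arm(res: ArmResult) -> ArmSummary:
    a = res.accruals
    return ArmSummary(
        ly=a.ly,
        qaly=a.qaly,
        years_in_response=a.years_in_response,
        years_subsequent=a.ly - a.years_in_response,
        costs=dict(a.costs),
        lost_income=a.lost_income,
    )


def run_cea(p: ModelParameters, lt: LifeTable,
            perspective: str | None = None) -> CEAResult:
    """Deterministic pairwise analysis of both arms."""
    perspective = perspective or p.settings.perspective
    if perspective not in ("societal", "payer"):
        raise ValueError(f"unknown perspective: {perspective}")
    arm_results = {arm: run_arm(p, arm, lt) for arm in ARMS}
    arms = {arm: summarize_arm(r) for arm, r in arm_results.items()}
    return CEAResult(perspective=perspective, arms=arms, arm_results=arm_results)


def calibrate_start_age(p: ModelParameters, lt: LifeTable, target_le: float,
                        tol: float = 1e-4) -> float:
    """Start age whose undiscounted model life expectancy matches ``target_le``.

    With annual death probabilities looked up at the floor of the cohort
    age, life expectancy is a step function of start age (two plateaus per
    year of age at the 6-month cycle length); bisection therefore returns
    the *left edge* of the plateau on which life expectancy first drops to
    or below the target, so a target equal to the life expectancy at an
    integer age recovers that age.
    """
    dt = p.settings.cycle_length_years

    def le(a: float) -> float:
        return life_expectancy(lt, a, cycle_length_years=dt)

    lo, hi = float(lt.min_age), float(lt.max_age)
    le_lo, le_hi = le(lo), le(hi)
    if not (le_hi <= target_le <= le_lo):
        raise ValueError(
            f"target life expectancy {target_le} outside achievable range "
            f"[{le_hi:.4f}, {le_lo:.4f}] for this life table")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if le(mid) <= target_le:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class OWSAEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float | None
    icer_high: float | None
    range: float


_SUPPORT = {
    "beta": (0.0, 1.0),
    "beta_pct": (0.0, 100.0),
    "gamma": (0.0, math.inf),
    "normal": (-math.inf, math.inf),
    "fixed": (-math.inf, math.inf),
}


def _clamp(x: float, family: str) -> float:
    lo, hi = _SUPPORT[family]
    return min(max(x, lo), hi)


def _enforce_consistency(p: ModelParameters) -> None:
    """Repair cross-parameter invariants after varying inputs independently."""
    for arm in ARMS:
        c = p.clinical.for_arm(arm)
        c.longterm_response_rate = min(c.longterm_response_rate,
                                       c.p_sustained_52w)
        c.waning_horizon_years = max(c.waning_horizon_years, 1.001)
    pr = p.productivity
    pr.responder_effect_lsm = min(pr.responder_effect_lsm,
                                  pr.baseline_pct_hours_lost)
    s = p.settings
    s.retirement_age = min(max(s.retirement_age, s.start_age + 1e-9), s.max_age)


def owsa_bounds(u: UncertainParameter, mean: float, mode: str) -> tuple[float, float]:
    if mode == "ci" and u.se is not None:
        lo, hi = mean - 1.96 * u.se, mean + 1.96 * u.se
    elif mode in ("ci", "fixed_fraction"):
        lo, hi = mean * (1.0 - u.owsa_fraction), mean * (1.0 + u.owsa_fraction)
    else:
        raise ValueError(f"unknown OWSA mode: {mode}")
    return _clamp(lo, u.family), _clamp(hi, u.family)


def owsa(p: ModelParameters, lt: LifeTable, perspective: str = "societal",
         mode: str = "ci") -> list[OWSAEntry]:
    """Vary each annotated parameter to its bounds; rank by ICER range.

    ``mode="ci"`` uses mean +/- 1.96 SE where a standard error exists and
    the 20%-of-mean convention otherwise; ``mode="fixed_fraction"`` uses
    +/- 20% of the mean throughout (the tornado-diagram convention).
    """
    entries = []
    for u in p.uncertainty:
        mean = get_param(p, u.name)
        lo, hi = owsa_bounds(u, mean, mode)
        icers = []
        for bound in (lo, hi):
            q = p.copy()
            set_param(q, u.name, bound)
            _enforce_consistency(q)
            icers.append(run_cea(q, lt, perspective).icer)
        finite = [x for x in icers if x is not None]
        rng = max(finite) - min(finite) if len(finite) == 2 else math.inf \
            if len(finite) == 1 else 0.0
        entries.append(OWSAEntry(parameter=u.name, low_value=lo, high_value=hi,
                                 icer_low=icers[0], icer_high=icers[1],
                                 range=rng))
    entries.sort(key=lambda e: e.range, reverse=True)
    return entries


def owsa_table(entries: list[OWSAEntry], top: int | None = None) -> pd.DataFrame:
    rows = entries if top is None else entries[:top]
    return pd.DataFrame([{
        "parameter": e.parameter, "low_value": e.low_value,
        "high_value": e.high_value, "icer_low": e.icer_low,
        "icer_high": e.icer_high, "range": e.range} for e in rows])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _sample_one(rng: np.random.Generator, family: str, mean: float,
                se: float, name: str) -> float:
    if se <= 0.0 or family == "fixed":
        return mean
    if family == "beta_pct":
        return 100.0 * _sample_one(rng, "beta", mean / 100.0, se / 100.0, name)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            return mean
        var = se * se
        if var >= mean * (1.0 - mean):
            logger.warning("beta moments infeasible for %s (mean %.4g, se %.4g); "
                           "falling back to a truncated uniform", name, mean, se)
            lo = max(0.0, mean - 1.96 * se)
            hi = min(1.0, mean + 1.96 * se)
            return rng.uniform(lo, hi)
        nu = mean * (1.0 - mean) / var - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    if family == "gamma":
        if mean <= 0.0:
            return mean
        var = se * se
        shape = mean * mean / var
        scale = var / mean
        return float(rng.gamma(shape, scale))
    if family == "normal":
        return float(rng.normal(mean, se))
    raise ValueError(f"unknown distribution family: {family}")


def sample_parameters(p: ModelParameters,
                      seed: int | np.random.Generator) -> ModelParameters:
    """One joint draw of all annotated parameters from their distributions."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    q = p.copy()
    for u in p.uncertainty:
        mean = get_param(p, u.name)
        se = u.se if u.se is not None else abs(mean) * u.owsa_fraction
        set_param(q, u.name, _sample_one(rng, u.family, mean, se, u.name))
    _enforce_consistency(q)
    return q


@dataclass
class PSAResult:
    n_iterations: int
    seed: int
    draws: pd.DataFrame  # inc_qaly, inc_cost_payer, inc_cost_societal, ...

    def mean_icer(self, perspective: str = "societal",
                  method: str = "ratio_of_means") -> float:
        """Headline PSA ICER: ratio of mean increments (or mean of ratios)."""
        dc = self.draws["inc_cost_" + perspective]
        de = self.draws["inc_qaly"]
        if method == "ratio_of_means":
            return float(dc.mean() / de.mean())
        if method == "mean_of_ratios":
            ratio = dc[de.abs() > _EPS_QALY] / de[de.abs() > _EPS_QALY]
            return float(ratio.mean())
        raise ValueError(f"unknown method: {method}")


def psa(p: ModelParameters, lt: LifeTable, n_iterations: int = 1000,
        seed: int = 0) -> PSAResult:
    """Joint parameter sampling with a full model run per iteration."""
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_iterations):
        q = sample_parameters(p, rng)
        res = run_cea(q, lt, "societal")
        rows.append({
            "iteration": i,
            "inc_qaly": res.inc_qaly,
            "inc_cost_payer": res.inc_cost_payer,
            "inc_cost_societal": res.inc_cost_societal,
            "inc_lost_income": res.inc_lost_income,
        })
    return PSAResult(n_iterations=n_iterations, seed=seed,
                     draws=pd.DataFrame(rows))


def ceac(r: PSAResult, wtp_grid: np.ndarray | None = None,
         perspective: str = "societal") -> pd.DataFrame:
    """P(cost-effective) per willingness-to-pay: share of iterations with
    positive incremental net monetary benefit, lambda*dQALY - dCost > 0."""
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 15_000_001.0, 250_000.0)
    dc = r.draws["inc_cost_" + perspective].to_numpy()
    de = r.draws["inc_qaly"].to_numpy()
    probs = [(wtp * de - dc > 0).mean() for wtp in np.asarray(wtp_grid, float)]
    return pd.DataFrame({"wtp": np.asarray(wtp_grid, float),
                         "probability": probs})
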