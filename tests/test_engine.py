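import numpy as np
import pytest

from adcea.engine import (
    ArmResult,
    full_trace,
    per_cycle_exit_probability,
    run_arm,
    run_decision_tree,
    run_markov,
    waning_survival,
)
from adcea.mortality import life_expectancy
from adcea.synthetic_data import make_test_parameters
from adcea.valuation import CATEGORIES
from conftest import flat_lifetable


def totals(res: ArmResult) -> dict[str, float]:
    a = res.accruals
    return {"ly": a.ly, "qaly": a.qaly, "lost_income": a.lost_income,
            "years_in_response": a.years_in_response, **a.costs}


class TestDecisionTree:
    def test_week52_entrants_abrocitinib(self, basecase):
        # 42.9% respond x 93.1% stay on drug x 80.6% sustain (no mortality)
        lt = flat_lifetable(110)
        init = run_decision_tree(basecase, "abrocitinib", lt)
        assert init.occupancy["in_response"] == \
            pytest.approx(0.429 * (1 - 0.069) * 0.806, abs=1e-12)

    def test_week52_entrants_soc(self, basecase):
        lt = flat_lifetable(110)
        init = run_decision_tree(basecase, "soc", lt)
        assert init.occupancy["in_response"] == \
            pytest.approx(0.107 * 0.725, abs=1e-12)

    def test_no_response_means_no_maintenance_entrants(self, basecase):
        lt = flat_lifetable(110)
        basecase.clinical.abrocitinib.p_response_16w = 0.0
        init = run_decision_tree(basecase, "abrocitinib", lt)
        assert init.occupancy["in_response"] == 0.0
        assert init.occupancy["non_response"] == pytest.approx(1.0)
        assert init.accruals.years_in_response == 0.0

    def test_occupancy_sums_to_one_with_mortality(self, basecase, lifetable):
        init = run_decision_tree(basecase, "abrocitinib", lifetable)
        assert sum(init.occupancy.values()) == pytest.approx(1.0, abs=1e-12)
        assert init.occupancy["dead"] > 0.0


class TestWaning:
    def test_starts_at_one(self, basecase):
        assert waning_survival(basecase, "abrocitinib", 0.0) == 1.0
        assert waning_survival(basecase, "soc", 0.0) == 1.0

    def test_reaches_longterm_rate_at_horizon(self, basecase):
        # maintenance survival anchored directly at the long-term rates
        assert waning_survival(basecase, "abrocitinib", 10.0) == \
            pytest.approx(0.62)
        assert waning_survival(basecase, "soc", 5.0) == pytest.approx(0.03)

    def test_constant_beyond_horizon(self, basecase):
        assert waning_survival(basecase, "abrocitinib", 25.0) == \
            pytest.approx(0.62)
        assert waning_survival(basecase, "soc", 40.0) == pytest.approx(0.03)

    def test_linear_midpoint(self, basecase):
        assert waning_survival(basecase, "abrocitinib", 5.0) == \
            pytest.approx(1.0 - 0.38 / 2)

    def test_monotone_non_increasing(self, basecase):
        for arm in ("abrocitinib", "soc"):
            w = [waning_survival(basecase, arm, t) for t in
                 np.linspace(0, 20, 81)]
            assert all(a >= b for a, b in zip(w, w[1:]))


class TestExitProbability:
    def test_soc_exits_stop_after_horizon(self, basecase):
        # no discontinuation and waning finished: nobody leaves response
        assert per_cycle_exit_probability(20, "soc", basecase) == 0.0

    def test_abrocitinib_post_horizon_is_discontinuation_only(self, basecase):
        expected = 1.0 - 0.937 ** 0.5   # 6.3%/year over a half-year cycle
        assert per_cycle_exit_probability(30, "abrocitinib", basecase) == \
            pytest.approx(expected)

    def test_waning_adds_to_discontinuation(self, basecase):
        disc_only = 1.0 - 0.937 ** 0.5
        assert per_cycle_exit_probability(0, "abrocitinib", basecase) > disc_only


class TestMarkov:
    def test_all_dead_cohort_stays_dead(self, basecase, lifetable):
        from adcea.engine import InitialPhaseResult
        from adcea.valuation import Accruals
        init = InitialPhaseResult(
            occupancy={"in_response": 0.0, "non_response": 0.0, "dead": 1.0},
            accruals=Accruals())
        trace = run_markov(basecase, "abrocitinib", init, lifetable)
        assert trace.accruals.ly == 0.0
        assert trace.accruals.qaly == 0.0
        assert all(v == 0.0 for v in trace.accruals.costs.values())

    def test_conservation_without_mortality_or_exit(self, basecase):
        from adcea.engine import InitialPhaseResult
        from adcea.valuation import Accruals
        lt = flat_lifetable(110, min_age=30)
        c = basecase.clinical.abrocitinib
        c.annual_disc_post52w = 0.0
        c.longterm_response_rate = c.p_sustained_52w = 1.0
        init = InitialPhaseResult(
            occupancy={"in_response": 1.0, "non_response": 0.0, "dead": 0.0},
            accruals=Accruals())
        trace = run_markov(basecase, "abrocitinib", init, lt)
        assert np.allclose(trace.table["in_response"].iloc[:-1], 1.0)
        # full half-year per cycle, half-cycle in the closing cycle
        assert trace.accruals.ly == pytest.approx(
            (len(trace.table) - 1) * 0.5 + 0.25)


class TestWholeArmProperties:
    @pytest.fixture(params=["base", 1, 2, 3], ids=lambda s: f"set-{s}")
    def param_set(self, request):
        if request.param == "base":
            return make_test_parameters(scale="base")
        return make_test_parameters(seed=request.param, scale="stress")

    def test_occupancy_conserved_and_dead_monotone(self, param_set, lifetable):
        for arm in ("abrocitinib", "soc"):
            tr = full_trace(run_arm(param_set, arm, lifetable))
            occ = tr[["in_response", "non_response", "dead"]].to_numpy()
            assert np.all(np.abs(occ.sum(axis=1) - 1.0) < 1e-12)
            assert np.all(occ >= -1e-15) and np.all(occ <= 1 + 1e-12)
            assert np.all(np.diff(tr["dead"].to_numpy()) >= -1e-15)

    def test_life_years_equal_across_arms(self, param_set, lifetable):
        # mortality carries no treatment effect
        ab = run_arm(param_set, "abrocitinib", lifetable)
        soc = run_arm(param_set, "soc", lifetable)
        assert ab.accruals.ly == pytest.approx(soc.accruals.ly, abs=1e-10)

    def test_life_years_match_life_expectancy(self, param_set, lifetable):
        ab = run_arm(param_set, "abrocitinib", lifetable)
        le = life_expectancy(lifetable, param_set.settings.start_age,
                             param_set.settings.cycle_length_years)
        assert ab.accruals.ly == pytest.approx(le, abs=1e-9)

    def test_halfcycle_totals_bracketed(self, basecase, lifetable):
        # Bracketing applies where end-of-cycle weighting moves accrual the
        # same way for both the alive mass and the state mix: life-years and
        # QALYs, plus costs whose responder rate dominates the non-responder
        # rate (drug, monitoring, adverse events on the abrocitinib arm).
        # HCRU and lost income pay *more* per non-responder year, so the
        # exit-driven state shift can outweigh the smaller alive mass there.
        runs = {t: run_arm(basecase, "abrocitinib", lifetable, timing=t)
                for t in ("begin", "mid", "end")}
        for metric in ("ly", "qaly"):
            lo = getattr(runs["end"].accruals, metric)
            hi = getattr(runs["begin"].accruals, metric)
            mid = getattr(runs["mid"].accruals, metric)
            assert lo <= mid <= hi
        for cat in ("drug_acquisition", "monitoring", "ae"):
            lo = runs["end"].accruals.costs[cat]
            hi = runs["begin"].accruals.costs[cat]
            mid = runs["mid"].accruals.costs[cat]
            assert lo - 1e-9 <= mid <= hi + 1e-9

    def test_zero_discount_weakly_increases_totals(self, param_set, lifetable):
        undisc = param_set.copy()
        undisc.settings.discount_rate_annual = 0.0
        for arm in ("abrocitinib", "soc"):
            with_d = totals(run_arm(param_set, arm, lifetable))
            without = totals(run_arm(undisc, arm, lifetable))
            for metric, v in with_d.items():
                assert without[metric] >= v - 1e-9

    def test_identical_arms_give_identical_traces(self, basecase, lifetable):
        import copy
        basecase.clinical.soc = copy.deepcopy(basecase.clinical.abrocitinib)
        basecase.utilities.soc = copy.deepcopy(basecase.utilities.abrocitinib)
        ab = full_trace(run_arm(basecase, "abrocitinib", lifetable))
        soc = full_trace(run_arm(basecase, "soc", lifetable))
        assert np.allclose(ab.to_numpy(), soc.to_numpy(), atol=1e-14)
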