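import copy
import logging

import numpy as np
import pytest

from adcea.analysis import (
    _sample_one,
    calibrate_start_age,
    ceac,
    owsa,
    owsa_bounds,
    psa,
    run_cea,
    sample_parameters,
)
from adcea.mortality import life_expectancy
from adcea.parameters import UncertainParameter, save_parameters
from adcea.valuation import CATEGORIES


def make_symmetric(p):
    """Identical clinical pathway and utilities in both arms."""
    p = p.copy()
    p.clinical.soc = copy.deepcopy(p.clinical.abrocitinib)
    p.utilities.soc = copy.deepcopy(p.utilities.abrocitinib)
    return p


class TestRunCEA:
    def test_perspectives_differ_only_by_lost_income(self, calibrated, lifetable):
        soc = run_cea(calibrated, lifetable, "societal")
        pay = run_cea(calibrated, lifetable, "payer")
        assert soc.inc_qaly == pytest.approx(pay.inc_qaly)
        assert soc.inc_cost - pay.inc_cost == \
            pytest.approx(soc.inc_lost_income, abs=1e-6)

    def test_totals_sum_their_components(self, calibrated, lifetable):
        r = run_cea(calibrated, lifetable, "societal")
        for arm in ("abrocitinib", "soc"):
            s = r.arms[arm]
            assert s.total_payer == pytest.approx(
                sum(s.costs[c] for c in CATEGORIES), abs=1e-9)
            assert s.total_societal == pytest.approx(
                s.total_payer + s.lost_income, abs=1e-9)

    def test_icer_is_cost_over_effect(self, calibrated, lifetable):
        r = run_cea(calibrated, lifetable, "societal")
        assert r.icer == pytest.approx(r.inc_cost / r.inc_qaly)

    def test_symmetric_arms_have_undefined_icer(self, basecase, lifetable):
        r = run_cea(make_symmetric(basecase), lifetable, "societal")
        assert abs(r.inc_qaly) < 1e-12
        assert r.icer is None

    def test_soc_drug_acquisition_is_subsequent_treatment_only(
            self, calibrated, lifetable):
        """Topicals cost nothing: the comparator's drug-acquisition row is
        exactly the discounted subsequent-treatment spend."""
        q = calibrated.copy()
        q.costs.subsequent_monthly_cost = 0.0
        with_sub = run_cea(calibrated, lifetable, "societal")
        without = run_cea(q, lifetable, "societal")
        assert without.arms["soc"].costs["drug_acquisition"] == 0.0
        assert with_sub.arms["soc"].costs["drug_acquisition"] > 0.0


class TestCalibration:
    def test_fixed_point_recovers_integer_age(self, basecase, lifetable):
        target = life_expectancy(lifetable, 40.0)
        assert calibrate_start_age(basecase, lifetable, target) == \
            pytest.approx(40.0, abs=1e-3)

    def test_unachievable_target_reports_range(self, basecase, lifetable):
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_start_age(basecase, lifetable, 200.0)
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_start_age(basecase, lifetable, 0.01)

    def test_published_life_years_imply_adult_start_age(self, basecase,
                                                        lifetable):
        age = calibrate_start_age(basecase, lifetable, 46.05)
        assert 35.0 <= age <= 45.0


class TestOWSA:
    def test_zero_se_parameter_has_zero_range(self, calibrated, lifetable):
        entries = owsa(calibrated, lifetable, mode="ci")
        by_name = {e.parameter: e for e in entries}
        e = by_name["costs.hcru_annual_freq.responder.hospitalization"]
        assert e.low_value == e.high_value
        assert e.range == 0.0

    def test_responder_utility_among_most_influential(self, calibrated,
                                                      lifetable):
        entries = owsa(calibrated, lifetable, mode="ci")
        top = [e.parameter for e in entries[:5]]
        assert "utilities.abrocitinib.responder" in top

    def test_base_icer_between_bound_icers_for_utility(self, calibrated,
                                                       lifetable):
        base = run_cea(calibrated, lifetable, "societal").icer
        entries = owsa(calibrated, lifetable, mode="ci")
        e = next(x for x in entries
                 if x.parameter == "utilities.abrocitinib.responder")
        assert min(e.icer_low, e.icer_high) <= base <= \
            max(e.icer_low, e.icer_high)

    def test_fraction_bounds_scale_linearly(self):
        u = UncertainParameter(name="x", family="gamma", se=None,
                               owsa_fraction=0.2)
        lo1, hi1 = owsa_bounds(u, 100.0, "fixed_fraction")
        u2 = UncertainParameter(name="x", family="gamma", se=None,
                                owsa_fraction=0.4)
        lo2, hi2 = owsa_bounds(u2, 100.0, "fixed_fraction")
        assert (hi2 - lo2) == pytest.approx(2 * (hi1 - lo1))

    def test_ci_bounds_clamped_to_support(self):
        u = UncertainParameter(name="x", family="beta", se=0.3)
        lo, hi = owsa_bounds(u, 0.9, "ci")
        assert lo == pytest.approx(0.9 - 1.96 * 0.3)
        assert hi == 1.0


class TestSampling:
    def test_zero_se_everywhere_reproduces_base_case(self, basecase):
        for u in basecase.uncertainty:
            u.se = 0.0
        q = sample_parameters(basecase, seed=3)
        assert save_parameters(q) == save_parameters(basecase)

    def test_same_seed_same_draw(self, basecase):
        a = sample_parameters(basecase, seed=11)
        b = sample_parameters(basecase, seed=11)
        assert a == b

    def test_law_of_large_numbers_for_beta_utility(self):
        rng = np.random.default_rng(0)
        draws = [_sample_one(rng, "beta", 0.86, 0.172, "u") for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(0.86, abs=0.01)

    def test_infeasible_beta_moments_fall_back_to_uniform(self, caplog):
        rng = np.random.default_rng(0)
        with caplog.at_level(logging.WARNING, logger="adcea.analysis"):
            draws = [_sample_one(rng, "beta", 0.5, 0.6, "u") for _ in range(200)]
        assert "falling back" in caplog.text
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_draws_respect_longterm_ordering(self, basecase):
        for seed in range(20):
            q = sample_parameters(basecase, seed=seed)
            for arm in ("abrocitinib", "soc"):
                c = q.clinical.for_arm(arm)
                assert c.longterm_response_rate <= c.p_sustained_52w + 1e-12


class TestPSA:
    def test_degenerate_psa_equals_deterministic(self, calibrated, lifetable):
        p = calibrated.copy()
        for u in p.uncertainty:
            u.se = 0.0
        det = run_cea(p, lifetable, "societal")
        r = psa(p, lifetable, n_iterations=10, seed=1)
        assert np.allclose(r.draws["inc_qaly"], det.inc_qaly)
        assert np.allclose(r.draws["inc_cost_societal"], det.inc_cost_societal)

    def test_seed_reproducibility(self, calibrated, lifetable):
        a = psa(calibrated, lifetable, n_iterations=20, seed=9)
        b = psa(calibrated, lifetable, n_iterations=20, seed=9)
        assert a.draws.equals(b.draws)

    def test_different_seeds_agree_within_monte_carlo_error(self, calibrated,
                                                            lifetable):
        a = psa(calibrated, lifetable, n_iterations=150, seed=1)
        b = psa(calibrated, lifetable, n_iterations=150, seed=2)
        assert not a.draws.equals(b.draws)
        qa, qb = a.draws["inc_qaly"], b.draws["inc_qaly"]
        pooled_se = np.hypot(qa.sem(), qb.sem())
        assert abs(qa.mean() - qb.mean()) < 4 * pooled_se

    def test_both_mean_icer_conventions_reported(self, calibrated, lifetable):
        r = psa(calibrated, lifetable, n_iterations=50, seed=4)
        assert np.isfinite(r.mean_icer("societal", "ratio_of_means"))
        assert np.isfinite(r.mean_icer("payer", "mean_of_ratios"))


@pytest.fixture(scope="module")
def psa_result(calibrated, lifetable):
    return psa(calibrated, lifetable, n_iterations=200, seed=6)


class TestCEAC:

    def test_zero_wtp_counts_cost_saving_iterations(self, psa_result):
        curve = ceac(psa_result, np.array([0.0]), "societal")
        dc = psa_result.draws["inc_cost_societal"]
        assert curve["probability"].iloc[0] == (dc < 0).mean()

    def test_large_wtp_counts_qaly_gaining_iterations(self, psa_result):
        curve = ceac(psa_result, np.array([1e12]), "societal")
        de = psa_result.draws["inc_qaly"]
        assert curve["probability"].iloc[0] == (de > 0).mean()

    def test_probabilities_bounded_and_complementary_at_zero(self, psa_result):
        curve = ceac(psa_result, None, "payer")
        assert ((curve["probability"] >= 0) & (curve["probability"] <= 1)).all()
        dc = psa_result.draws["inc_cost_payer"]
        at_zero = ceac(psa_result, np.array([0.0]), "payer")
        assert at_zero["probability"].iloc[0] + (dc >= 0).mean() == \
            pytest.approx(1.0)
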