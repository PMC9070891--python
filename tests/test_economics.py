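"""Discounting, utilities, cycle valuation, and strategy comparison."""

import numpy as np
import pytest

from cbtcea import (
    State,
    StrategyOutcome,
    base_case,
    compare,
    cycle_value,
    discount_factor,
    evaluate_strategy,
    run_cohort,
    state_utility,
    summarize,
)
from cbtcea.economics import DOMINANT_COMPARATOR, DOMINANT_INTERVENTION, TRADE_OFF


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, expected",
        [(0, 1.0), (12, 1 / 1.03), (60, 1.03**-5)],
    )
    def test_closed_form(self, cycle, expected):
        assert discount_factor(cycle, 0.03) == pytest.approx(expected)

    def test_zero_rate_is_unity(self):
        assert discount_factor(37, 0.0) == 1.0

    def test_discounting_lowers_totals(self, params, cfg):
        disc = evaluate_strategy(params, cfg, "icbt")
        undisc = evaluate_strategy(
            params.with_base("discount_annual", 0.0), cfg, "icbt"
        )
        assert disc.total_cost < undisc.total_cost
        assert disc.qalys < undisc.qalys


class TestStateUtility:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (State.WELL, 0.92 * 0.72),
            (State.MILD, 0.92 * 0.64),
            (State.MODERATE, 0.92 * 0.60),
            (State.SEVERE, 0.92 * 0.53),
            (State.DEAD, 0.0),
        ],
    )
    def test_age_adjusted(self, params, state, expected):
        assert state_utility(params, state) == pytest.approx(expected)


class TestCycleValue:
    def test_all_severe_post_phase(self, params, cfg):
        row = np.array([0, 0, 0, 1.0, 0])
        p0 = params.with_base("discount_annual", 0.0)
        direct, indirect, _ = cycle_value(row, 10, "fcbt", p0, cfg)
        assert direct == pytest.approx(220 + 0.0114 * 1278)  # 234.5692
        assert indirect == pytest.approx(0.31668 * 10 * 56)  # 177.3408

    def test_all_well(self, params, cfg):
        row = np.array([1.0, 0, 0, 0, 0])
        p0 = params.with_base("discount_annual", 0.0)
        direct, indirect, qaly = cycle_value(row, 10, "icbt", p0, cfg)
        assert direct == 0.0
        assert indirect == 0.0
        assert qaly == pytest.approx(0.6624 / 12)  # 0.0552

    def test_all_dead(self, params, cfg):
        row = np.array([0, 0, 0, 0, 1.0])
        assert cycle_value(row, 10, "icbt", params, cfg) == (0.0, 0.0, 0.0)


class TestSummarize:
    def test_zero_costs_zero_totals(self, params, cfg):
        p = params
        for key in ("wage_psych", "platform_cost_icbt", "outpatient_monthly",
                    "hosp_cost_episode", "student_wage"):
            p = p.with_base(key, 0.0)
        out = evaluate_strategy(p, cfg, "icbt")
        assert out.direct_cost == 0.0
        assert out.indirect_cost == 0.0

    def test_zero_age_utility_zero_qalys(self, params, cfg):
        import dataclasses

        spec = params.specs["utility_age"]
        p = params.with_specs(utility_age=dataclasses.replace(spec, base=0.0, low=0.0))
        assert evaluate_strategy(p, cfg, "icbt").qalys == 0.0

    def test_qaly_upper_bound(self, params, cfg):
        """QALYs cannot exceed the discounted all-well trajectory."""
        pt = params.point()
        bound = sum(
            discount_factor(c, pt.discount_annual) * 0.92 * 0.72 / 12
            for c in range(1, 61)
        )
        for arm in ("icbt", "fcbt"):
            assert evaluate_strategy(params, cfg, arm).qalys <= bound

    def test_total_is_direct_plus_indirect(self, params, cfg):
        out = evaluate_strategy(params, cfg, "fcbt")
        assert out.total_cost == out.direct_cost + out.indirect_cost

    def test_half_cycle_correction_changes_little(self, params, cfg):
        from cbtcea import StructuralConfig

        hcc = StructuralConfig(half_cycle_correction=True)
        a = evaluate_strategy(params, cfg, "icbt")
        b = evaluate_strategy(params, hcc, "icbt")
        assert a.qalys != b.qalys
        assert abs(a.qalys - b.qalys) / a.qalys < 0.01


class TestCompare:
    def _outcome(self, cost, qaly, arm="icbt"):
        return StrategyOutcome(arm=arm, direct_cost=cost, indirect_cost=0.0,
                               qalys=qaly)

    def test_dominance_classification(self):
        ce = compare(self._outcome(6101, 2.9956), self._outcome(6246, 2.9917), 46070)
        assert ce.dominance == DOMINANT_INTERVENTION
        assert ce.icer is None
        assert ce.delta_cost == pytest.approx(-145)
        assert ce.delta_qaly == pytest.approx(0.0039)

    def test_trade_off_icer_and_inmb(self):
        ce = compare(self._outcome(100, 0.01), self._outcome(0, 0.0), 46070)
        assert ce.dominance == TRADE_OFF
        assert ce.icer == pytest.approx(10_000)
        assert ce.inmb == pytest.approx(46070 * 0.01 - 100)  # 360.70

    def test_comparator_dominant(self):
        ce = compare(self._outcome(100, -0.01), self._outcome(0, 0.0), 46070)
        assert ce.dominance == DOMINANT_COMPARATOR
        assert ce.icer is None

    def test_zero_qaly_delta_classified_by_cost_sign(self):
        assert compare(self._outcome(-5, 0.0), self._outcome(0, 0.0),
                       46070).dominance == DOMINANT_INTERVENTION
        assert compare(self._outcome(5, 0.0), self._outcome(0, 0.0),
                       46070).dominance == DOMINANT_COMPARATOR

    def test_identical_outcomes_zero_deltas(self):
        ce = compare(self._outcome(7, 2.0), self._outcome(7, 2.0), 46070)
        assert ce.delta_cost == ce.delta_qaly == ce.inmb == 0.0

    def test_antisymmetry(self, params, cfg):
        out_i = evaluate_strategy(params, cfg, "icbt")
        out_f = evaluate_strategy(params, cfg, "fcbt")
        fwd = compare(out_i, out_f, 46070)
        rev = compare(out_f, out_i, 46070)
        assert fwd.delta_cost == pytest.approx(-rev.delta_cost)
        assert fwd.delta_qaly == pytest.approx(-rev.delta_qaly)


class TestEqualRatioClosedForm:
    def test_delta_is_acceptance_weighted_course_difference(self, params, cfg):
        """With all four relative differences at 1, the arms differ only in
        the course fee: dQALY = 0 exactly and dCost equals the acceptance-
        weighted course-cost gap discounted over the phase instalments."""
        p = params
        for key in ("rr_accept_icbt", "rr_adhere_icbt", "rr_recovery_icbt",
                    "rr_deterioration_icbt"):
            p = p.with_base(key, 1.0)
        out_i, out_f, ce = base_case(p, cfg)
        assert ce.delta_qaly == 0.0
        f_low, i_low = 52 * 0.5 * 8, 19 + 0.22 * 208
        mean_disc = np.mean([discount_factor(c, 0.03) for c in (1, 2, 3)])
        expected = -0.633 * (f_low - i_low) * mean_disc
        assert ce.delta_cost == pytest.approx(expected, abs=1e-8)


def test_trace_reuse_matches_evaluate(params, cfg):
    tr = run_cohort(params, cfg, "fcbt")
    assert summarize(tr, params, cfg) == evaluate_strategy(params, cfg, "fcbt")
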