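"""Discounting, QALY accrual, ICER quadrants and dominance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from padcea import (
    compare_means,
    discounted_event_cost,
    discounted_sojourn_value,
    evaluate_strategy,
    icer,
    override_parameters,
    simulate_cohort,
    toy_cohort,
)
from padcea.economics import StrategyOutcome, patient_value
from padcea.engine import EventRecord, Trajectory
from padcea.parameters import ASYMPTOMATIC


def _traj(sojourns, events=(), pharma_start=None, death=None):
    death = death if death is not None else sojourns[-1][1]
    return Trajectory(
        patient_id=0,
        events=list(events) or [EventRecord(death, "death", "", sojourns[-1][2], 0.0)],
        sojourns=list(sojourns),
        death_time=death,
        pharma_start=pharma_start,
        n_successful_interventions=0,
        perioperative_death=False,
    )


class TestDiscountedSojournValue:
    def test_zero_rate_is_plain_area(self):
        assert discounted_sojourn_value(0.89, 0.0, 1.0, 0.0) == pytest.approx(0.89)

    def test_zero_utility_is_zero(self):
        assert discounted_sojourn_value(0.0, 2.0, 7.5, 0.03) == 0.0

    @pytest.mark.parametrize("r", [0.01, 0.03, 0.05, 0.2])
    @pytest.mark.parametrize("t0,t1", [(0.0, 1.0), (2.5, 9.0), (0.0, 40.0)])
    def test_matches_numeric_quadrature(self, r, t0, t1):
        u = 0.89
        expected, _ = quad(lambda t: u * (1 + r) ** (-t), t0, t1, epsabs=1e-13)
        assert discounted_sojourn_value(u, t0, t1, r) == pytest.approx(
            expected, abs=1e-10
        )

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            discounted_sojourn_value(0.5, 3.0, 2.0, 0.03)


class TestDiscountedEventCost:
    def test_zero_rate_unchanged(self):
        assert discounted_event_cost(123.0, 5.0, 0.0) == 123.0

    def test_one_year_at_three_percent(self):
        assert discounted_event_cost(100.0, 1.0, 0.03) == pytest.approx(
            97.0874, abs=1e-4
        )

    def test_time_zero_unchanged(self):
        assert discounted_event_cost(55.0, 0.0, 0.03) == 55.0


class TestEvaluate:
    def test_death_at_entry_gives_zero_qalys(self, params):
        tr = _traj([(0.0, 0.0, "ic_iia")], death=0.0)
        cost, qaly = patient_value(tr, params, discount_rate=0.03)
        assert qaly == 0.0
        assert cost == 0.0

    def test_age_banded_asymptomatic_accrual(self, params):
        # asymptomatic from entry (66) to death at 76 with no discounting:
        # nine years at 0.89 plus one year at 0.84 = 8.85 QALYs
        tr = _traj([(0.0, 10.0, ASYMPTOMATIC)])
        _, qaly = patient_value(tr, params, discount_rate=0.0)
        assert qaly == pytest.approx(0.89 * 9 + 0.84 * 1)

    def test_utility_scaling_is_linear(self, params):
        halved = override_parameters(
            params,
            {
                f"utilities.{k}.value": params.utilities.entries[k].value / 2
                for k in params.utilities.entries
            },
        )
        cohort = toy_cohort(100, 0.833, 5)
        trajs = simulate_cohort(cohort, "CTA", params, seed=6)
        full = evaluate_strategy(trajs, params, "CTA")
        # trajectories never depend on utilities, so they can be re-valued
        half = evaluate_strategy(trajs, halved, "CTA")
        assert np.allclose(half.qalys, full.qalys / 2)

    def test_zero_rate_equals_step_function_integral(self, params):
        cohort = toy_cohort(50, 0.833, 8)
        trajs = simulate_cohort(cohort, "MRA", params, seed=9)
        out = evaluate_strategy(trajs, params, "MRA", discount_rate=0.0)
        t75 = 75.0 - params.cohort.entry_age
        for tr, qaly in zip(trajs, out.qalys):
            expected = 0.0
            for t0, t1, state in tr.sojourns:
                if state == ASYMPTOMATIC and t0 < t75 < t1:
                    expected += 0.89 * (t75 - t0) + 0.84 * (t1 - t75)
                else:
                    expected += params.utility(state, 66.0 + t0) * (t1 - t0)
            assert qaly == pytest.approx(expected, abs=1e-9)

    def test_cost_and_qaly_nonincreasing_in_discount_rate(self, params):
        cohort = toy_cohort(200, 0.833, 10)
        trajs = simulate_cohort(cohort, "DUS", params, seed=11)
        outs = [
            evaluate_strategy(trajs, params, "DUS", discount_rate=r)
            for r in (0.0, 0.03, 0.05)
        ]
        for lo, hi in zip(outs[1:], outs[:-1]):
            assert np.all(lo.costs <= hi.costs + 1e-12)
            assert np.all(lo.qalys <= hi.qalys + 1e-12)
            assert lo.mean_cost <= hi.mean_cost
            assert lo.mean_qaly <= hi.mean_qaly


class TestIcer:
    def test_published_base_case_worked_example(self):
        cmp_ = compare_means("DUS", 10_778, 5.542, "CTA", 10_804, 5.554)
        assert cmp_.delta_cost == pytest.approx(26.0)
        assert cmp_.delta_effect == pytest.approx(0.012)
        assert cmp_.icer_rounded == 2_167

    def test_published_head_to_head_example(self):
        cmp_ = compare_means("MRA", 11_184, 5.554, "DSA", 11_460, 5.562)
        assert cmp_.icer_rounded == 34_500

    def test_dominant_when_cheaper_and_more_effective(self):
        cmp_ = compare_means("A", 100.0, 1.0, "B", 90.0, 1.1)
        assert cmp_.label == "dominant"
        assert cmp_.icer is None
        assert cmp_.quadrant == "SE"

    def test_dominated_when_costlier_and_less_effective(self):
        cmp_ = compare_means("A", 100.0, 1.0, "B", 190.0, 0.9)
        assert cmp_.label == "dominated"
        assert cmp_.quadrant == "NW"

    def test_equal_effects_reduce_to_cost_minimization(self):
        cmp_ = compare_means("A", 100.0, 1.0, "B", 190.0, 1.0)
        assert cmp_.label == "cost_minimization"
        assert cmp_.icer is None

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        c1=st.floats(0, 1e5),
        c2=st.floats(0, 1e5),
        e1=st.floats(0, 20),
        e2=st.floats(0, 20),
    )
    def test_antisymmetry_under_swap(self, c1, c2, e1, e2):
        fwd = compare_means("A", c1, e1, "B", c2, e2)
        rev = compare_means("B", c2, e2, "A", c1, e1)
        assert rev.delta_cost == -fwd.delta_cost
        assert rev.delta_effect == -fwd.delta_effect
        mirror = {"NE": "SW", "SW": "NE", "SE": "NW", "NW": "SE", None: None}
        assert rev.quadrant == mirror[fwd.quadrant]

    def test_mismatched_discount_rates_rejected(self):
        a = StrategyOutcome("A", np.ones(3), np.ones(3), np.ones(3), 0.03)
        b = StrategyOutcome("B", np.ones(3), np.ones(3), np.ones(3), 0.05)
        with pytest.raises(ValueError):
            icer(a, b)
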