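"""Scenario analyses: discount rates, combined DSA, pharmacotherapy timing,
two-way sweeps."""

import numpy as np
import pytest

from padcea import (
    ScenarioSpec,
    combined_dsa_scenario,
    override_parameters,
    pharmacotherapy_timing_scenario,
    run_base_case,
    run_discount_scenarios,
    run_scenario,
    two_way_sweep,
)

N = 600
SEED = 17


@pytest.fixture(scope="module")
def base_result(params):
    return run_base_case(params, seed=SEED, n_patients=N)


class TestDiscountScenarios:
    def test_costs_and_effects_ordered_by_rate(self, params):
        tbl = run_discount_scenarios(params, seed=SEED, n_patients=N)
        for strategy in ("DUS", "CTA", "MRA", "DSA"):
            sub = tbl[tbl.strategy == strategy].sort_values("discount_rate")
            assert sub.cost_eur.is_monotonic_decreasing
            assert sub.effect_qaly.is_monotonic_decreasing

    def test_base_rate_block_matches_base_case(self, params, base_result):
        tbl = run_discount_scenarios(params, seed=SEED, rates=(0.03,), n_patients=N)
        base_tbl = base_result.table()
        assert np.allclose(tbl.cost_eur.values, base_tbl.cost_eur.values)
        assert np.allclose(tbl.effect_qaly.values, base_tbl.effect_qaly.values)


class TestCombinedDsa:
    def test_p_zero_reproduces_base_bit_exactly(self, params, base_result):
        res = combined_dsa_scenario(params, 0.0, seed=SEED, n_patients=N)
        for s in res.outcomes:
            assert np.array_equal(res.outcomes[s].costs, base_result.outcomes[s].costs)
            assert np.array_equal(res.outcomes[s].qalys, base_result.outcomes[s].qalys)

    def test_p_one_waives_first_endovascular_diagnosis(self, params):
        from padcea import scaled_cohort, simulate_cohort
        from padcea.engine import SimulationOptions
        from padcea.parameters import ENDOVASCULAR_TYPES

        cohort = scaled_cohort(params, 300, seed=SEED)
        opts = SimulationOptions(combined_dsa_fraction=1.0)
        checked = 0
        for tr in simulate_cohort(cohort, "DSA", params, SEED, opts):
            interventions = [e for e in tr.events if e.kind == "intervention"]
            if not interventions:
                continue
            first = interventions[0]
            itype = first.detail.split(":")[0]
            if itype in ENDOVASCULAR_TYPES:
                preceding = [
                    e
                    for e in tr.events
                    if e.kind == "diagnostic_test"
                    and e.detail == "positive"
                    and e.time <= first.time
                ]
                assert preceding[-1].cost == 0.0
                checked += 1
        assert checked > 50

    def test_mean_dsa_cost_decreasing_in_p(self, params):
        costs = [
            combined_dsa_scenario(params, p, seed=SEED, n_patients=N)
            .outcomes["DSA"]
            .mean_cost
            for p in (0.0, 0.5, 1.0)
        ]
        assert costs[0] > costs[1] > costs[2]

    def test_other_strategies_unaffected(self, params, base_result):
        res = combined_dsa_scenario(params, 1.0, seed=SEED, n_patients=N)
        for s in ("DUS", "CTA", "MRA"):
            assert np.array_equal(res.outcomes[s].costs, base_result.outcomes[s].costs)


class TestPharmacotherapyTiming:
    def test_from_entry_mode_reproduces_base(self, params, base_result):
        res = pharmacotherapy_timing_scenario(
            params, "from_entry", seed=SEED, n_patients=N
        )
        for s in res.outcomes:
            assert np.array_equal(res.outcomes[s].costs, base_result.outcomes[s].costs)

    def test_zero_pharmacotherapy_cost_makes_modes_equal(self, params):
        free = override_parameters(
            params, {"clinical.pharmacotherapy_annual_cost_eur": 0.0}
        )
        a = pharmacotherapy_timing_scenario(free, "from_entry", seed=SEED, n_patients=N)
        b = pharmacotherapy_timing_scenario(
            free, "after_positive_diagnosis", seed=SEED, n_patients=N
        )
        for s in a.outcomes:
            assert np.array_equal(a.outcomes[s].costs, b.outcomes[s].costs)

    def test_cost_saving_largest_for_least_sensitive_modality(self, params, base_result):
        # DUS has the lowest sensitivity, hence the longest diagnostic delay
        # and the largest pharmacotherapy saving when costs start at diagnosis
        res = pharmacotherapy_timing_scenario(
            params, "after_positive_diagnosis", seed=SEED, n_patients=N
        )
        savings = {
            s: base_result.outcomes[s].mean_cost - res.outcomes[s].mean_cost
            for s in res.outcomes
        }
        assert savings["DUS"] == max(savings.values())
        assert savings["DUS"] > savings["DSA"]

    def test_unknown_mode_rejected(self, params):
        with pytest.raises(ValueError):
            pharmacotherapy_timing_scenario(params, "sometimes", seed=1, n_patients=10)

    def test_utilities_unchanged_by_timing(self, params, base_result):
        res = pharmacotherapy_timing_scenario(
            params, "after_positive_diagnosis", seed=SEED, n_patients=N
        )
        for s in res.outcomes:
            assert np.array_equal(res.outcomes[s].qalys, base_result.outcomes[s].qalys)


class TestTwoWaySweep:
    def test_single_cell_at_base_values_matches_base(self, params, base_result):
        tbl = two_way_sweep(
            params,
            "modalities.DUS.sensitivity",
            [0.86],
            "modalities.CTA.procedure_cost_eur",
            [64.0],
            seed=SEED,
            n_patients=N,
        )
        assert len(tbl) == 1
        assert tbl.cost_DUS.iloc[0] == pytest.approx(
            base_result.outcomes["DUS"].mean_cost
        )

    def test_grid_shape(self, params):
        tbl = two_way_sweep(
            params,
            "modalities.DUS.sensitivity",
            [0.8, 0.9],
            "modalities.CTA.procedure_cost_eur",
            [50.0, 64.0, 80.0],
            seed=SEED,
            n_patients=100,
        )
        assert len(tbl) == 6

    def test_dus_qalys_nondecreasing_in_dus_sensitivity(self, params):
        tbl = two_way_sweep(
            params,
            "modalities.DUS.sensitivity",
            [0.66, 0.86, 1.0],
            "modalities.CTA.procedure_cost_eur",
            [64.0],
            seed=SEED,
            n_patients=1500,
        )
        q = tbl.sort_values("value_a").qaly_DUS.values
        assert np.all(np.diff(q) >= 0)

    def test_unknown_field_rejected(self, params):
        with pytest.raises(KeyError):
            two_way_sweep(
                params,
                "modalities.DUS.does_not_exist",
                [1.0],
                "economics.discount_rate",
                [0.03],
                seed=1,
                n_patients=10,
            )

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            two_way_sweep(
                params,
                "modalities.DUS.sensitivity",
                [],
                "economics.discount_rate",
                [0.03],
                seed=1,
                n_patients=10,
            )


def test_no_override_scenario_reproduces_base(params, base_result):
    res = run_scenario(params, ScenarioSpec("null"), seed=SEED, n_patients=N)
    for s in res.outcomes:
        assert np.array_equal(res.outcomes[s].costs, base_result.outcomes[s].costs)
        assert np.array_equal(res.outcomes[s].qalys, base_result.outcomes[s].qalys)
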