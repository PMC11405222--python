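"""Base-case orchestration: one common-random-numbers cohort, four strategies.

All strategies are simulated on the identical cohort with identical
patient-level random streams, so cost and effect differences reflect the
diagnostic strategy alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Patient, cohort_from_params, scaled_cohort
from .economics import PairwiseComparison, StrategyOutcome, evaluate_strategy, icer, results_table
from .engine import BASE_OPTIONS, SimulationOptions, Trajectory, simulate_cohort
from .parameters import MODALITIES, ParameterSet


@dataclass
class BaseCaseResult:
    """Outcomes of all strategies on one CRN cohort plus pairwise comparisons
    against the baseline strategy (by convention the lowest-cost one, DUS)."""

    outcomes: dict[str, StrategyOutcome]
    baseline: str
    seed: int
    n_patients: int
    discount_rate: float
    parameter_digest: str

    @property
    def comparisons(self) -> list[PairwiseComparison]:
        ref = self.outcomes[self.baseline]
        return [
            icer(ref, out) for name, out in self.outcomes.items() if name != self.baseline
        ]

    def comparison(self, comparator: str) -> PairwiseComparison:
        return icer(self.outcomes[self.baseline], self.outcomes[comparator])

    def table(self) -> pd.DataFrame:
        return results_table(self.outcomes, self.baseline)

    @property
    def median_survival(self) -> dict[str, float]:
        return {k: v.median_survival for k, v in self.outcomes.items()}


def simulate_strategies(
    cohort: list[Patient],
    params: ParameterSet,
    seed,
    strategies=MODALITIES,
    options: SimulationOptions = BASE_OPTIONS,
    options_by_strategy: dict[str, SimulationOptions] | None = None,
) -> dict[str, list[Trajectory]]:
    """Simulate the same cohort under each strategy with shared streams."""
    out = {}
    for s in strategies:
        opts = (options_by_strategy or {}).get(s, options)
        out[s] = simulate_cohort(cohort, s, params, seed, opts)
    return out


def run_base_case(
    params: ParameterSet,
    seed: int,
    n_patients: int | None = None,
    strategies=MODALITIES,
    baseline: str = "DUS",
    discount_rate: float | None = None,
    options: SimulationOptions = BASE_OPTIONS,
    options_by_strategy: dict[str, SimulationOptions] | None = None,
) -> BaseCaseResult:
    """Run the full pairwise cost-effectiveness comparison.

    ``n_patients=None`` simulates the full configured cohort (population size
    times prevalences); an integer requests a desk-scale cohort preserving the
    IC:CLTI mix.
    """
    if n_patients is None:
        cohort = cohort_from_params(params, seed)
    else:
        cohort = scaled_cohort(params, n_patients, seed)
    trajsets = simulate_strategies(
        cohort, params, seed, strategies, options, options_by_strategy
    )
    r = params.economics.discount_rate if discount_rate is None else discount_rate
    outcomes = {
        s: evaluate_strategy(trajs, params, s, discount_rate=r)
        for s, trajs in trajsets.items()
    }
    return BaseCaseResult(
        outcomes=outcomes,
        baseline=baseline,
        seed=seed,
        n_patients=len(cohort),
        discount_rate=r,
        parameter_digest=params.digest(),
    )
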