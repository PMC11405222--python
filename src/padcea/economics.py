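"""Discounted lifetime costs and QALYs; pairwise ICERs and dominance.

Discounting is continuous-time by default: a flow active on [t0, t1] at
annual-compounded rate r is worth ``integral of (1+r)^(-t) dt``, i.e.
``[(1+r)^(-t0) - (1+r)^(-t1)] / ln(1+r)`` per unit of flow, and a point cost
at time t is worth ``c (1+r)^(-t)``.  An annual-cycle approximation is
available as a cross-check toggle.  Both costs and effects are discounted at
the same rate.

Quality-adjusted life years integrate the piecewise-constant utility of the
visited health states; the asymptomatic utility switches from its 66-74 to
its 75+ value at simulated age exactly 75, splitting any sojourn spanning
that age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory
from .parameters import ASYMPTOMATIC, ParameterSet


def discounted_event_cost(c: float, t: float, r: float) -> float:
    """Present value of a one-off cost ``c`` incurred at year ``t``."""
    if r == 0.0:
        return c
    return c * (1.0 + r) ** (-t)


def _annuity(t_start: float, t_end: float, r: float) -> float:
    """Present value of a unit continuous flow over [t_start, t_end]."""
    if t_end < t_start:
        raise ValueError("reversed interval")
    if r == 0.0:
        return t_end - t_start
    lr = math.log1p(r)
    return ((1.0 + r) ** (-t_start) - (1.0 + r) ** (-t_end)) / lr


def discounted_sojourn_value(
    u: float, t_start: float, t_end: float, r: float
) -> float:
    """Discounted QALYs accrued at constant utility ``u`` over an interval."""
    if t_start < 0:
        raise ValueError("interval must start at or after model entry")
    return u * _annuity(t_start, t_end, r)


def _annual_cycle_value(u: float, t_start: float, t_end: float, r: float) -> float:
    """Annual-cycle approximation: each model year's accrual discounted at
    the factor of its starting year boundary."""
    total = 0.0
    t = t_start
    while t < t_end:
        nxt = min(math.floor(t) + 1.0, t_end)
        total += u * (nxt - t) * (1.0 + r) ** (-math.floor(t))
        t = nxt
    return total


@dataclass
class StrategyOutcome:
    """Per-strategy discounted lifetime costs and effects over a cohort."""

    strategy: str
    costs: np.ndarray  # per-patient discounted cost, EUR
    qalys: np.ndarray  # per-patient discounted QALYs
    death_times: np.ndarray  # undiscounted survival, years
    discount_rate: float

    @property
    def mean_cost(self) -> float:
        return float(np.mean(self.costs))

    @property
    def mean_qaly(self) -> float:
        return float(np.mean(self.qalys))

    @property
    def median_survival(self) -> float:
        return float(np.median(self.death_times))

    @property
    def n(self) -> int:
        return len(self.costs)


def patient_value(
    tr: Trajectory,
    params: ParameterSet,
    discount_rate: float | None = None,
    annual_cycle: bool = False,
) -> tuple[float, float]:
    """Discounted (cost, QALY) for one trajectory."""
    r = params.economics.discount_rate if discount_rate is None else discount_rate
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    # age-75 utility switch for the asymptomatic state
    t75 = 75.0 - params.cohort.entry_age
    sojourn_value = _annual_cycle_value if annual_cycle else discounted_sojourn_value

    cost = 0.0
    for e in tr.events:
        if e.cost:
            cost += discounted_event_cost(e.cost, e.time, r)
    if tr.pharma_start is not None and tr.pharma_start < tr.death_time:
        cost += params.clinical.pharmacotherapy_annual_cost * _annuity(
            tr.pharma_start, tr.death_time, r
        )

    qaly = 0.0
    for t0, t1, state in tr.sojourns:
        if t1 <= t0:
            continue
        if state == ASYMPTOMATIC and t0 < t75 < t1:
            qaly += sojourn_value(params.utility(state, params.cohort.entry_age), t0, t75, r)
            qaly += sojourn_value(params.utility(state, 75.0), t75, t1, r)
        else:
            age = params.cohort.entry_age + t0
            qaly += sojourn_value(params.utility(state, age), t0, t1, r)
    return cost, qaly


def evaluate_strategy(
    trajectories: list[Trajectory],
    params: ParameterSet,
    strategy: str,
    discount_rate: float | None = None,
    annual_cycle: bool = False,
) -> StrategyOutcome:
    """Turn simulated trajectories into a cohort-level outcome summary."""
    r = params.economics.discount_rate if discount_rate is None else discount_rate
    n = len(trajectories)
    costs = np.empty(n)
    qalys = np.empty(n)
    deaths = np.empty(n)
    for i, tr in enumerate(trajectories):
        c, q = patient_value(tr, params, discount_rate=r, annual_cycle=annual_cycle)
        costs[i] = c
        qalys[i] = q
        deaths[i] = tr.death_time
    return StrategyOutcome(
        strategy=strategy,
        costs=costs,
        qalys=qalys,
        death_times=deaths,
        discount_rate=r,
    )


@dataclass(frozen=True)
class PairwiseComparison:
    """Incremental comparison of one strategy against a reference.

    ``icer`` is defined only in the trade-off quadrants (NE: more costly and
    more effective; SW: cheaper and less effective).  In SE the comparator
    dominates; in NW it is dominated; with equal effects the comparison
    reduces to cost minimization.
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "cost_minimization" | "equivalent"
    quadrant: str | None  # NE | SE | NW | SW | None (on an axis)

    @property
    def icer_rounded(self) -> int | None:
        """ICER to the nearest integer EUR/QALY (half away from zero)."""
        if self.icer is None:
            return None
        x = self.icer
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compare_means(
    reference: str,
    cost_ref: float,
    effect_ref: float,
    comparator: str,
    cost_comp: float,
    effect_comp: float,
) -> PairwiseComparison:
    """ICER / dominance classification from cohort mean costs and effects."""
    dc = cost_comp - cost_ref
    de = effect_comp - effect_ref
    if de > 0 and dc > 0:
        quadrant, label, ratio = "NE", "icer", dc / de
    elif de < 0 and dc < 0:
        quadrant, label, ratio = "SW", "icer", dc / de
    elif de > 0 and dc < 0:
        quadrant, label, ratio = "SE", "dominant", None
    elif de < 0 and dc > 0:
        quadrant, label, ratio = "NW", "dominated", None
    elif de == 0 and dc == 0:
        quadrant, label, ratio = None, "equivalent", None
    elif de == 0:
        quadrant, label, ratio = None, "cost_minimization", None
    else:  # dc == 0, de != 0
        quadrant = "SE" if de > 0 else "NW"
        label = "dominant" if de > 0 else "dominated"
        ratio = None
    return PairwiseComparison(
        reference=reference,
        comparator=comparator,
        delta_cost=dc,
        delta_effect=de,
        icer=ratio,
        label=label,
        quadrant=quadrant,
    )


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> PairwiseComparison:
    """Pairwise ICER between two strategy outcomes on the same cohort."""
    if reference.discount_rate != comparator.discount_rate:
        raise ValueError("outcomes computed at different discount rates")
    if reference.n != comparator.n:
        raise ValueError("outcomes computed on different cohorts")
    return compare_means(
        reference.strategy,
        reference.mean_cost,
        reference.mean_qaly,
        comparator.strategy,
        comparator.mean_cost,
        comparator.mean_qaly,
    )


def results_table(
    outcomes: dict[str, StrategyOutcome], baseline: str
) -> pd.DataFrame:
    """Cost-effectiveness table: per-strategy means, differences vs the
    baseline strategy, and ICERs (rounded to whole EUR / 3-decimal QALYs for
    presentation; unrounded columns retained)."""
    rows = []
    ref = outcomes[baseline]
    for name, out in outcomes.items():
        if name == baseline:
            rows.append(
                {
                    "strategy": name,
                    "cost_eur": out.mean_cost,
                    "cost_difference_eur": np.nan,
                    "effect_qaly": out.mean_qaly,
                    "effect_difference_qaly": np.nan,
                    "icer_eur_per_qaly": None,
                    "label": "baseline",
                }
            )
        else:
            cmp_ = icer(ref, out)
            rows.append(
                {
                    "strategy": name,
                    "cost_eur": out.mean_cost,
                    "cost_difference_eur": cmp_.delta_cost,
                    "effect_qaly": out.mean_qaly,
                    "effect_difference_qaly": cmp_.delta_effect,
                    "icer_eur_per_qaly": cmp_.icer_rounded
                    if cmp_.icer is not None
                    else cmp_.label,
                    "label": cmp_.label,
                }
            )
    return pd.DataFrame(rows)
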