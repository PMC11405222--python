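"""Cohort construction from population size and disease prevalences.

The simulated cohort is every symptomatic 66-year-old in a reference
population: intermittent claudication (IC, Fontaine IIa/IIb) and chronic
limb-threatening ischemia (CLTI, Fontaine III/IV) prevalences are applied to
the population size with round-half-away-from-zero, which reproduces the
canonical counts 7,955 IC + 1,591 CLTI = 9,546 from 132,576 persons at
prevalences 6% and 1.2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CLTI_III, CLTI_IV, IC_IIA, IC_IIB, ParameterSet


@dataclass
class Patient:
    """One simulated individual at model entry.

    The trailing fields mirror the run-time bookkeeping the simulator keeps
    (success counts, eligibility, scheduled death); the engine never mutates a
    Patient, so the same cohort object can be reused across strategies and
    scenarios under common random numbers.
    """

    id: int
    sex: str  # "male" | "female"
    entry_age: float
    initial_state: str  # ic_iia | ic_iib | clti_iii | clti_iv
    n_successful_interventions: int = 0
    consecutive_failures: int = 0
    reoperable: bool = True
    scheduled_death_time: float | None = None
    alive: bool = True


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_cohort(
    population_size: int,
    prev_ic: float,
    prev_clti: float,
    male_fraction: float,
    seed: int,
    entry_age: float = 66.0,
    ic_iia_fraction: float = 0.5,
    clti_iii_fraction: float = 0.5,
) -> list[Patient]:
    """Construct the symptomatic cohort implied by population and prevalences.

    IC and CLTI counts are deterministic (rounded prevalence shares of the
    population); only per-patient attributes (sex, Fontaine subclass) depend
    on the seed, so cohort size is invariant to it.
    """
    if population_size < 0:
        raise ValueError("population_size must be >= 0")
    if not (0.0 <= prev_ic <= 1.0 and 0.0 <= prev_clti <= 1.0):
        raise ValueError("prevalences must be in [0, 1]")
    if prev_ic + prev_clti > 1.0:
        raise ValueError("prev_ic + prev_clti must be <= 1")
    n_ic = round_half_away(population_size * prev_ic)
    n_clti = round_half_away(population_size * prev_clti)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 11))))
    patients: list[Patient] = []
    for i in range(n_ic + n_clti):
        ic = i < n_ic
        if ic:
            state = IC_IIA if rng.random() < ic_iia_fraction else IC_IIB
        else:
            state = CLTI_III if rng.random() < clti_iii_fraction else CLTI_IV
        sex = "male" if rng.random() < male_fraction else "female"
        patients.append(Patient(id=i, sex=sex, entry_age=entry_age, initial_state=state))
    return patients


def cohort_from_params(params: ParameterSet, seed: int) -> list[Patient]:
    """Full cohort at the configured population size and prevalences."""
    c = params.cohort
    return build_cohort(
        c.population_size,
        c.prev_ic,
        c.prev_clti,
        c.male_fraction,
        seed,
        entry_age=c.entry_age,
        ic_iia_fraction=c.ic_iia_fraction,
        clti_iii_fraction=c.clti_iii_fraction,
    )


def scaled_cohort(params: ParameterSet, n_patients: int, seed: int) -> list[Patient]:
    """Desk-scale cohort of ``n_patients`` preserving the IC:CLTI ratio."""
    c = params.cohort
    total_prev = c.prev_ic + c.prev_clti
    if total_prev <= 0:
        raise ValueError("prevalences sum to zero; empty cohort requested")
    ic_share = c.prev_ic / total_prev
    n_ic = round_half_away(n_patients * ic_share)
    n_clti = n_patients - n_ic
    return _explicit_cohort(n_ic, n_clti, c, seed)


def _explicit_cohort(n_ic: int, n_clti: int, c, seed: int) -> list[Patient]:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 11))))
    patients: list[Patient] = []
    for i in range(n_ic + n_clti):
        ic = i < n_ic
        if ic:
            state = IC_IIA if rng.random() < c.ic_iia_fraction else IC_IIB
        else:
            state = CLTI_III if rng.random() < c.clti_iii_fraction else CLTI_IV
        sex = "male" if rng.random() < c.male_fraction else "female"
        patients.append(
            Patient(id=i, sex=sex, entry_age=c.entry_age, initial_state=state)
        )
    return patients


def cohort_to_dataframe(cohort: list[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "sex": [p.sex for p in cohort],
            "entry_age": [p.entry_age for p in cohort],
            "initial_state": [p.initial_state for p in cohort],
        }
    )
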