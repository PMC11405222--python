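"""Patient-level discrete event simulation of the disease and care pathway.

Each symptomatic patient (intermittent claudication or chronic
limb-threatening ischemia at entry) moves through diagnosis, endovascular or
surgical revascularisation, patency, disease progression, amputation and
death in continuous time.  The logic:

* Diagnostic testing has no false positives (every tested patient is
  diseased); a test is positive with probability equal to the modality's
  sensitivity.  After a negative result, CLTI patients are re-examined after
  a short interval and IC patients after one year.
* A positive test triggers an intervention whose type is drawn at random
  (PTA, PTA with stent, autologous or prosthetic bypass).  Technical success,
  30-day mortality and 30-day morbidity are simulated per procedure.  Success
  renders the patient asymptomatic for a sampled patency time (primary for
  the first success, secondary for the second).  A patient can accumulate at
  most two successful interventions; two consecutive technical failures end
  all interventional therapy, and each repeat procedure may find the patient
  unsuitable for reoperation.
* While symptomatic, IC may progress to CLTI and CLTI to amputation
  (below- or above-knee, affecting utility and one-off cost).
* Time of death is sampled once at entry from the initial state's
  time-to-death distribution and, at every health-state change, the remaining
  time is rescaled by the ratio of the updated to the previous baseline life
  expectancy, so a state change never lengthens or shortens life by more than
  the life-expectancy ratio implies.

Patients are mutually independent, so each trajectory is resolved by its own
next-event loop over a small pending-event set ordered by (time, fixed
event-kind priority); this is equivalent to a single global event queue and
keeps paired runs bit-reproducible.  Every random decision draws from a named
per-patient substream keyed by (seed, patient id, stream index), which is
what makes common-random-number comparisons across strategies meaningful:
streams for intervention outcomes, patency times and survival stay aligned
even when diagnostic histories differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Patient
from .parameters import (
    AMP_ABOVE,
    AMP_BELOW,
    ASYMPTOMATIC,
    CLTI_III,
    CLTI_STATES,
    ENDOVASCULAR_TYPES,
    IC_STATES,
    INTERVENTION_TYPES,
    SYMPTOMATIC_STATES,
    ParameterSet,
    survival_group,
)

DAYS_30 = 30.0 / 365.25

# Fixed event-kind priorities used to break ties at equal event times.  Death
# always wins; intervention runs last so that a same-time diagnosis has
# already been recorded.
_PRIORITY = {
    "death": 0,
    "amputation": 1,
    "progression": 2,
    "patency_loss": 3,
    "diagnostic_test": 4,
    "intervention": 5,
}


class SimulationError(RuntimeError):
    """Internal consistency violation (unreachable transition)."""


@dataclass(slots=True)
class EventRecord:
    time: float
    kind: str
    detail: str
    resulting_state: str
    cost: float


@dataclass(slots=True)
class Trajectory:
    """One patient's lifetime event history under one diagnostic strategy."""

    patient_id: int
    events: list[EventRecord]
    sojourns: list[tuple[float, float, str]]  # (t_start, t_end, state)
    death_time: float
    pharma_start: float | None  # start of the pharmacotherapy cost stream
    n_successful_interventions: int
    perioperative_death: bool

    def total_undiscounted_cost(self) -> float:
        return sum(e.cost for e in self.events)


@dataclass(slots=True)
class SimulationOptions:
    """Scenario switches; the defaults are the base case."""

    pharmacotherapy_mode: str = "from_entry"  # or "after_positive_diagnosis"
    combined_dsa_fraction: float = 0.0  # share of DSA patients whose first
    # endovascular intervention absorbs the preceding DSA examination cost


BASE_OPTIONS = SimulationOptions()

# Named per-patient random substreams.
_STREAM_DIAGNOSTIC = 0
_STREAM_INTERVENTION = 1
_STREAM_PATENCY = 2
_STREAM_SURVIVAL = 3  # death draw at entry, then progression clocks
_STREAM_MISC = 4  # intervention type, amputation level
_STREAM_SCENARIO = 5  # combined-DSA per-patient eligibility


def _stream(seed_key: tuple, pid: int, idx: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((*seed_key, pid, idx)))
    )


def adjust_time_of_death(
    t_now: float, t_death_current: float, le_baseline: float, le_updated: float
) -> float:
    """Rescale remaining time to death by a life-expectancy ratio.

    Returns ``t_now + (t_death_current - t_now) * le_updated / le_baseline``,
    never less than ``t_now``.
    """
    if le_baseline <= 0:
        raise ValueError("baseline life expectancy must be > 0")
    if t_death_current < t_now:
        raise ValueError("current death time precedes current time")
    return t_now + (t_death_current - t_now) * (le_updated / le_baseline)


def _draw_intervention_type(u: float, weights: dict[str, float]) -> str:
    total = sum(weights[k] for k in INTERVENTION_TYPES)
    acc = 0.0
    for k in INTERVENTION_TYPES:
        acc += weights[k] / total
        if u < acc:
            return k
    return INTERVENTION_TYPES[-1]


def simulate_patient(
    patient: Patient,
    strategy: str,
    params: ParameterSet,
    seed,
    options: SimulationOptions = BASE_OPTIONS,
) -> Trajectory:
    """Simulate one patient's lifetime under one diagnostic strategy.

    ``seed`` may be an int or a tuple of ints; together with the patient id it
    keys the per-patient random substreams, so identical (seed, parameters,
    strategy) reproduce the trajectory bit-for-bit and different strategies
    share the same patient-level randomness (common random numbers).
    """
    if patient.initial_state not in SYMPTOMATIC_STATES:
        raise SimulationError("patients must be symptomatic at entry")
    seed_key = seed if isinstance(seed, tuple) else (int(seed),)
    pid = patient.id
    modality = params.modalities[strategy]
    clin = params.clinical

    rng_diag = _stream(seed_key, pid, _STREAM_DIAGNOSTIC)
    rng_int = _stream(seed_key, pid, _STREAM_INTERVENTION)
    rng_pat = _stream(seed_key, pid, _STREAM_PATENCY)
    rng_surv = _stream(seed_key, pid, _STREAM_SURVIVAL)
    rng_misc = _stream(seed_key, pid, _STREAM_MISC)

    state = patient.initial_state
    t_death = clin.survival[survival_group(state)].ppf(rng_surv.random())
    t_periop: float | None = None
    n_succ = 0
    n_interventions = 0
    cons_fail = 0
    reoperable = True
    pre_intervention_state = state
    amputated = False

    combined_dsa_waiver: bool | None = None  # decided lazily, own substream

    events: list[EventRecord] = []
    sojourns: list[tuple[float, float, str]] = []
    seg_start = 0.0
    pharma_start = 0.0 if options.pharmacotherapy_mode == "from_entry" else None
    last_diag_event: EventRecord | None = None

    # pending event times by kind; absent key = not scheduled
    pending: dict[str, float] = {"diagnostic_test": 0.0}

    def change_state(new_state: str, t: float) -> None:
        nonlocal state, t_death, seg_start
        if new_state == state:
            return
        t_death = adjust_time_of_death(
            t, t_death, params.life_expectancy(state), params.life_expectancy(new_state)
        )
        sojourns.append((seg_start, t, state))
        state = new_state
        seg_start = t

    def schedule_progression(t: float) -> None:
        """Arm the symptomatic progression clock for the current state."""
        if state in IC_STATES:
            dist = clin.progression_ic_to_clti
        elif state in CLTI_STATES:
            dist = clin.progression_clti_to_amputation
        else:
            pending.pop("progression", None)
            return
        pending["progression"] = t + dist.ppf(rng_surv.random())

    schedule_progression(0.0)

    while True:
        if t_periop is not None and t_periop <= t_death:
            death_candidate = (t_periop, _PRIORITY["death"], "perioperative_death")
        else:
            death_candidate = (t_death, _PRIORITY["death"], "death")
        t_ev, _, kind = min(
            [death_candidate]
            + [(tt, _PRIORITY[k], k) for k, tt in pending.items()],
            key=lambda c: (c[0], c[1]),
        )

        if kind in ("death", "perioperative_death"):
            sojourns.append((seg_start, t_ev, state))
            events.append(EventRecord(t_ev, kind, "", state, 0.0))
            return Trajectory(
                patient_id=pid,
                events=events,
                sojourns=sojourns,
                death_time=t_ev,
                pharma_start=pharma_start,
                n_successful_interventions=n_succ,
                perioperative_death=(kind == "perioperative_death"),
            )

        del pending[kind]

        if kind == "progression":
            if state in IC_STATES:
                change_state(CLTI_III, t_ev)
                events.append(EventRecord(t_ev, "progression", "ic_to_clti", state, 0.0))
                schedule_progression(t_ev)
            elif state in CLTI_STATES:
                below = rng_misc.random() < clin.below_knee_fraction
                new_state = AMP_BELOW if below else AMP_ABOVE
                cost = (
                    clin.amputation_cost_below if below else clin.amputation_cost_above
                )
                change_state(new_state, t_ev)
                amputated = True
                events.append(
                    EventRecord(
                        t_ev,
                        "amputation",
                        "below_knee" if below else "above_knee",
                        state,
                        cost,
                    )
                )
                # the interventional pathway ends with the limb
                pending.pop("diagnostic_test", None)
                pending.pop("intervention", None)
                pending.pop("patency_loss", None)
            else:
                raise SimulationError("progression fired outside a symptomatic state")

        elif kind == "diagnostic_test":
            if state not in SYMPTOMATIC_STATES:
                raise SimulationError("diagnostic test on a non-symptomatic patient")
            positive = rng_diag.random() < modality.sensitivity
            rec = EventRecord(
                t_ev,
                "diagnostic_test",
                "positive" if positive else "negative",
                state,
                modality.total_cost,
            )
            events.append(rec)
            if positive:
                last_diag_event = rec
                if pharma_start is None:
                    pharma_start = t_ev
                pending["intervention"] = t_ev
            else:
                interval = (
                    clin.retest_interval_clti_years
                    if state in CLTI_STATES
                    else clin.retest_interval_ic_years
                )
                pending["diagnostic_test"] = t_ev + interval

        elif kind == "intervention":
            if not (
                n_succ < 2
                and cons_fail < 2
                and reoperable
                and state in SYMPTOMATIC_STATES
            ):
                raise SimulationError("intervention scheduled for ineligible patient")
            u_type = rng_misc.random()
            u_succ = rng_int.random()
            u_mort = rng_int.random()
            u_morb = rng_int.random()
            u_unsuit = rng_int.random()
            itype = _draw_intervention_type(u_type, clin.intervention_weights)
            ipar = clin.interventions[itype]
            first_ever = n_interventions == 0
            n_interventions += 1

            if (
                strategy == "DSA"
                and options.combined_dsa_fraction > 0.0
                and first_ever
                and itype in ENDOVASCULAR_TYPES
                and last_diag_event is not None
            ):
                if combined_dsa_waiver is None:
                    rng_scen = _stream(seed_key, pid, _STREAM_SCENARIO)
                    combined_dsa_waiver = (
                        rng_scen.random() < options.combined_dsa_fraction
                    )
                if combined_dsa_waiver:
                    # examination cost absorbed into the endovascular procedure
                    last_diag_event.cost = 0.0

            success = u_succ < ipar.technical_success
            if success:
                n_succ += 1
                cons_fail = 0
                pre_intervention_state = state
                change_state(ASYMPTOMATIC, t_ev)
                pending.pop("progression", None)
                dist = clin.patency_primary if n_succ == 1 else clin.patency_secondary
                pending["patency_loss"] = t_ev + dist.ppf(rng_pat.random())
            events.append(
                EventRecord(
                    t_ev,
                    "intervention",
                    f"{itype}:{'success' if success else 'failure'}",
                    state,
                    ipar.cost,
                )
            )
            if u_morb < ipar.morbidity_30d:
                events.append(
                    EventRecord(
                        t_ev,
                        "morbidity_episode",
                        itype,
                        state,
                        clin.morbidity_episode_cost,
                    )
                )
            if u_mort < ipar.mortality_30d and t_periop is None:
                t_periop = t_ev + DAYS_30
            if not success:
                cons_fail += 1
                if cons_fail >= 2:
                    pass  # no further interventional therapy, ever
                elif u_unsuit < clin.p_unsuitable_reoperation:
                    reoperable = False
                else:
                    pending["intervention"] = t_ev + clin.reintervention_delay_years

        elif kind == "patency_loss":
            if state != ASYMPTOMATIC:
                raise SimulationError("patency loss without an asymptomatic sojourn")
            change_state(pre_intervention_state, t_ev)
            events.append(EventRecord(t_ev, "patency_loss", "", state, 0.0))
            schedule_progression(t_ev)
            if n_succ < 2 and reoperable and cons_fail < 2 and not amputated:
                pending["diagnostic_test"] = t_ev

        else:  # pragma: no cover
            raise SimulationError(f"unknown event kind {kind!r}")


def simulate_cohort(
    cohort: list[Patient],
    strategy: str,
    params: ParameterSet,
    seed,
    options: SimulationOptions = BASE_OPTIONS,
) -> list[Trajectory]:
    """Simulate every patient in the cohort under one strategy."""
    return [simulate_patient(p, strategy, params, seed, options) for p in cohort]


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into an audit event log."""
    rows = []
    for tr in trajectories:
        for e in tr.events:
            rows.append(
                (tr.patient_id, e.time, e.kind, e.detail, e.resulting_state, e.cost)
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "time", "event", "detail", "state", "cost_eur"]
    )


def check_trajectory_invariants(tr: Trajectory) -> None:
    """Raise AssertionError if a structural invariant is violated."""
    times = [e.time for e in tr.events]
    assert all(t >= 0 for t in times), "negative event time"
    assert times == sorted(times), "event times not nondecreasing"
    terminal = [e for e in tr.events if e.kind in ("death", "perioperative_death")]
    assert len(terminal) == 1, "exactly one terminal death event required"
    assert tr.events[-1] is terminal[0], "events recorded after death"
    assert tr.n_successful_interventions <= 2, "more than two successful interventions"
    assert all(e.cost >= 0 for e in tr.events), "negative event cost"
    assert math.isclose(tr.death_time, terminal[0].time), "death time mismatch"
    # no third intervention after two consecutive failures
    fails = 0
    for e in tr.events:
        if e.kind == "intervention":
            assert fails < 2, "intervention after two consecutive failures"
            if e.detail.endswith(":failure"):
                fails += 1
            else:
                fails = 0
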