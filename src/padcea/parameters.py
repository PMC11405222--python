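"""Model parameterization: types, validation, config I/O, and PSA sampling.

The parameter set covers four diagnostic imaging strategies (DUS, CTA, MRA,
DSA) for symptomatic lower-limb peripheral arterial disease, the utilities of
the modelled health states, cohort-construction constants, economic settings,
and the clinical/time-to-event parameters driving the discrete event
simulation.  A single nested-key/value YAML file is the canonical on-disk
form; :func:`load_parameters` validates every invariant on load and
enumerates all violations at once.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import special, stats

SCHEMA_VERSION = 1

MODALITIES = ("DUS", "CTA", "MRA", "DSA")
INTERVENTION_TYPES = ("PTA", "PTA_S", "bypass_autologous", "bypass_prosthetic")
ENDOVASCULAR_TYPES = frozenset({"PTA", "PTA_S"})

# Health states.  Asymptomatic utility is age-banded (66-74 vs 75+); the
# other states carry a single utility each.
ASYMPTOMATIC = "asymptomatic"
IC_IIA = "ic_iia"
IC_IIB = "ic_iib"
CLTI_III = "clti_iii"
CLTI_IV = "clti_iv"
AMP_BELOW = "amputation_below_knee"
AMP_ABOVE = "amputation_above_knee"

IC_STATES = frozenset({IC_IIA, IC_IIB})
CLTI_STATES = frozenset({CLTI_III, CLTI_IV})
SYMPTOMATIC_STATES = IC_STATES | CLTI_STATES
AMPUTATION_STATES = frozenset({AMP_BELOW, AMP_ABOVE})

UTILITY_KEYS = (
    "asymptomatic_66_74",
    "asymptomatic_75_plus",
    IC_IIA,
    IC_IIB,
    CLTI_III,
    CLTI_IV,
    AMP_BELOW,
    AMP_ABOVE,
)

# Survival (time-to-death) distributions are indexed by coarse state group.
SURVIVAL_GROUPS = ("asymptomatic", "ic", "clti", AMP_BELOW, AMP_ABOVE)


def survival_group(state: str) -> str:
    """Map a health state to its survival-distribution group."""
    if state == ASYMPTOMATIC:
        return "asymptomatic"
    if state in IC_STATES:
        return "ic"
    if state in CLTI_STATES:
        return "clti"
    if state in AMPUTATION_STATES:
        return state
    raise ValueError(f"unknown health state: {state}")


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates one or more invariants.

    ``errors`` lists every violated invariant, each naming the field.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid parameter set:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class Distribution:
    """A positive time-to-event distribution (years).

    Supported families: ``weibull`` (shape, scale), ``exponential`` (scale),
    ``lognormal`` (mu, sigma of log-time), ``gamma`` (shape, scale).  Sampling
    is by inverse transform from a single uniform draw, which keeps paired
    runs aligned under common random numbers.
    """

    family: str
    params: tuple[float, ...]

    def ppf(self, u: float) -> float:
        if self.family == "weibull":
            shape, scale = self.params
            return scale * (-math.log1p(-u)) ** (1.0 / shape)
        if self.family == "exponential":
            (scale,) = self.params
            return -scale * math.log1p(-u)
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma * special.ndtri(u))
        if self.family == "gamma":
            shape, scale = self.params
            return float(stats.gamma.ppf(u, a=shape, scale=scale))
        raise ValueError(f"unknown distribution family: {self.family}")

    def mean(self) -> float:
        if self.family == "weibull":
            shape, scale = self.params
            return scale * math.gamma(1.0 + 1.0 / shape)
        if self.family == "exponential":
            return self.params[0]
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + 0.5 * sigma * sigma)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        raise ValueError(f"unknown distribution family: {self.family}")

    def median(self) -> float:
        return self.ppf(0.5)

    def validate(self, name: str, errors: list[str]) -> None:
        known = {"weibull": 2, "exponential": 1, "lognormal": 2, "gamma": 2}
        if self.family not in known:
            errors.append(f"{name}.family: unknown distribution family {self.family!r}")
            return
        if len(self.params) != known[self.family]:
            errors.append(
                f"{name}.params: {self.family} needs {known[self.family]} parameters, "
                f"got {len(self.params)}"
            )
            return
        if self.family == "lognormal":
            if self.params[1] <= 0:
                errors.append(f"{name}.params: lognormal sigma must be > 0")
        elif any(p <= 0 for p in self.params):
            errors.append(f"{name}.params: all {self.family} parameters must be > 0")

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Distribution":
        return cls(family=str(d["family"]), params=tuple(float(p) for p in d["params"]))


@dataclass(frozen=True)
class DiagnosticModality:
    """One imaging strategy: sensitivity, per-examination costs, PSA inputs.

    The model has no false positives (every tested patient is diseased), so
    sensitivity alone characterises test performance.  ``contrast_cost`` is 0
    for DUS, which uses no contrast agent.
    """

    name: str
    sensitivity: float
    procedure_cost: float  # EUR per examination
    contrast_cost: float  # EUR per examination
    sensitivity_beta: tuple[float, float]
    cost_halfwidth: float = 0.20  # +/- fraction for the uniform PSA draw

    @property
    def total_cost(self) -> float:
        return self.procedure_cost + self.contrast_cost

    def validate(self, errors: list[str]) -> None:
        p = f"modalities.{self.name}"
        if self.name not in MODALITIES:
            errors.append(f"{p}.name: unknown modality {self.name!r}")
        if not 0.0 <= self.sensitivity <= 1.0:
            errors.append(f"{p}.sensitivity: {self.sensitivity} outside [0, 1]")
        if self.procedure_cost < 0:
            errors.append(f"{p}.procedure_cost: must be >= 0")
        if self.contrast_cost < 0:
            errors.append(f"{p}.contrast_cost: must be >= 0")
        if self.name == "DUS" and self.contrast_cost != 0:
            errors.append(f"{p}.contrast_cost: DUS uses no contrast agent, must be 0")
        a, b = self.sensitivity_beta
        if a <= 0 or b <= 0:
            errors.append(f"{p}.sensitivity_beta: alpha and beta must be > 0")
        if not 0.0 <= self.cost_halfwidth < 1.0:
            errors.append(f"{p}.cost_halfwidth: must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "procedure_cost_eur": self.procedure_cost,
            "contrast_cost_eur": self.contrast_cost,
            "sensitivity_beta": list(self.sensitivity_beta),
            "cost_halfwidth": self.cost_halfwidth,
        }

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "DiagnosticModality":
        return cls(
            name=name,
            sensitivity=float(d["sensitivity"]),
            procedure_cost=float(d["procedure_cost_eur"]),
            contrast_cost=float(d["contrast_cost_eur"]),
            sensitivity_beta=tuple(float(x) for x in d["sensitivity_beta"]),
            cost_halfwidth=float(d.get("cost_halfwidth", 0.20)),
        )


@dataclass(frozen=True)
class UtilityEntry:
    value: float
    beta: tuple[float, float]


@dataclass(frozen=True)
class UtilityTable:
    """EQ-5D utilities per health state, asymptomatic split by age band."""

    entries: Mapping[str, UtilityEntry]

    def utility(self, state: str, age: float) -> float:
        if state == ASYMPTOMATIC:
            key = "asymptomatic_66_74" if age < 75.0 else "asymptomatic_75_plus"
            return self.entries[key].value
        return self.entries[state].value

    def validate(self, errors: list[str]) -> None:
        for key in UTILITY_KEYS:
            if key not in self.entries:
                errors.append(f"utilities.{key}: missing")
                continue
            e = self.entries[key]
            if not 0.0 <= e.value <= 1.0:
                errors.append(f"utilities.{key}.value: {e.value} outside [0, 1]")
            a, b = e.beta
            if a <= 0 or b <= 0:
                errors.append(f"utilities.{key}.beta: alpha and beta must be > 0")

    def to_dict(self) -> dict:
        return {
            k: {"value": e.value, "beta": list(e.beta)} for k, e in self.entries.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UtilityTable":
        return cls(
            entries={
                k: UtilityEntry(value=float(v["value"]), beta=tuple(float(x) for x in v["beta"]))
                for k, v in d.items()
            }
        )


@dataclass(frozen=True)
class InterventionParams:
    """Outcome probabilities and unit cost for one revascularisation type."""

    technical_success: float
    mortality_30d: float
    morbidity_30d: float
    cost: float  # EUR per procedure

    def validate(self, name: str, errors: list[str]) -> None:
        p = f"clinical.interventions.{name}"
        for f_name in ("technical_success", "mortality_30d", "morbidity_30d"):
            v = getattr(self, f_name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{p}.{f_name}: {v} outside [0, 1]")
        if self.cost < 0:
            errors.append(f"{p}.cost: must be >= 0")

    def to_dict(self) -> dict:
        return {
            "technical_success": self.technical_success,
            "mortality_30d": self.mortality_30d,
            "morbidity_30d": self.morbidity_30d,
            "cost_eur": self.cost,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InterventionParams":
        return cls(
            technical_success=float(d["technical_success"]),
            mortality_30d=float(d["mortality_30d"]),
            morbidity_30d=float(d["morbidity_30d"]),
            cost=float(d["cost_eur"]),
        )


@dataclass(frozen=True)
class ClinicalParams:
    """Disease-course, intervention-outcome and non-diagnostic cost inputs."""

    interventions: Mapping[str, InterventionParams]
    intervention_weights: Mapping[str, float]
    p_unsuitable_reoperation: float
    below_knee_fraction: float
    patency_primary: Distribution
    patency_secondary: Distribution
    progression_ic_to_clti: Distribution
    progression_clti_to_amputation: Distribution
    survival: Mapping[str, Distribution]  # keyed by SURVIVAL_GROUPS
    retest_interval_ic_years: float
    retest_interval_clti_years: float
    reintervention_delay_years: float
    pharmacotherapy_annual_cost: float  # EUR per year, continuous
    morbidity_episode_cost: float  # EUR per 30-day morbidity episode
    amputation_cost_below: float  # EUR, one-off
    amputation_cost_above: float  # EUR, one-off

    def validate(self, errors: list[str]) -> None:
        for name in INTERVENTION_TYPES:
            if name not in self.interventions:
                errors.append(f"clinical.interventions.{name}: missing")
            else:
                self.interventions[name].validate(name, errors)
        wsum = 0.0
        for name in INTERVENTION_TYPES:
            w = self.intervention_weights.get(name)
            if w is None:
                errors.append(f"clinical.intervention_weights.{name}: missing")
            elif w < 0:
                errors.append(f"clinical.intervention_weights.{name}: must be >= 0")
            else:
                wsum += w
        if wsum <= 0:
            errors.append("clinical.intervention_weights: weights must sum to > 0")
        for f_name in ("p_unsuitable_reoperation", "below_knee_fraction"):
            v = getattr(self, f_name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"clinical.{f_name}: {v} outside [0, 1]")
        for d_name in (
            "patency_primary",
            "patency_secondary",
            "progression_ic_to_clti",
            "progression_clti_to_amputation",
        ):
            getattr(self, d_name).validate(f"clinical.{d_name}", errors)
        for group in SURVIVAL_GROUPS:
            if group not in self.survival:
                errors.append(f"clinical.survival.{group}: missing")
            else:
                self.survival[group].validate(f"clinical.survival.{group}", errors)
        for f_name in (
            "retest_interval_ic_years",
            "retest_interval_clti_years",
            "reintervention_delay_years",
        ):
            if getattr(self, f_name) < 0:
                errors.append(f"clinical.{f_name}: must be >= 0")
        for f_name in (
            "pharmacotherapy_annual_cost",
            "morbidity_episode_cost",
            "amputation_cost_below",
            "amputation_cost_above",
        ):
            if getattr(self, f_name) < 0:
                errors.append(f"clinical.{f_name}: must be >= 0")

    def to_dict(self) -> dict:
        return {
            "interventions": {k: v.to_dict() for k, v in self.interventions.items()},
            "intervention_weights": dict(self.intervention_weights),
            "p_unsuitable_reoperation": self.p_unsuitable_reoperation,
            "below_knee_fraction": self.below_knee_fraction,
            "patency_primary": self.patency_primary.to_dict(),
            "patency_secondary": self.patency_secondary.to_dict(),
            "progression_ic_to_clti": self.progression_ic_to_clti.to_dict(),
            "progression_clti_to_amputation": self.progression_clti_to_amputation.to_dict(),
            "survival": {k: v.to_dict() for k, v in self.survival.items()},
            "retest_interval_ic_years": self.retest_interval_ic_years,
            "retest_interval_clti_years": self.retest_interval_clti_years,
            "reintervention_delay_years": self.reintervention_delay_years,
            "pharmacotherapy_annual_cost_eur": self.pharmacotherapy_annual_cost,
            "morbidity_episode_cost_eur": self.morbidity_episode_cost,
            "amputation_cost_below_eur": self.amputation_cost_below,
            "amputation_cost_above_eur": self.amputation_cost_above,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClinicalParams":
        return cls(
            interventions={
                k: InterventionParams.from_dict(v) for k, v in d["interventions"].items()
            },
            intervention_weights={k: float(v) for k, v in d["intervention_weights"].items()},
            p_unsuitable_reoperation=float(d["p_unsuitable_reoperation"]),
            below_knee_fraction=float(d["below_knee_fraction"]),
            patency_primary=Distribution.from_dict(d["patency_primary"]),
            patency_secondary=Distribution.from_dict(d["patency_secondary"]),
            progression_ic_to_clti=Distribution.from_dict(d["progression_ic_to_clti"]),
            progression_clti_to_amputation=Distribution.from_dict(
                d["progression_clti_to_amputation"]
            ),
            survival={k: Distribution.from_dict(v) for k, v in d["survival"].items()},
            retest_interval_ic_years=float(d["retest_interval_ic_years"]),
            retest_interval_clti_years=float(d["retest_interval_clti_years"]),
            reintervention_delay_years=float(d["reintervention_delay_years"]),
            pharmacotherapy_annual_cost=float(d["pharmacotherapy_annual_cost_eur"]),
            morbidity_episode_cost=float(d["morbidity_episode_cost_eur"]),
            amputation_cost_below=float(d["amputation_cost_below_eur"]),
            amputation_cost_above=float(d["amputation_cost_above_eur"]),
        )


@dataclass(frozen=True)
class CohortParams:
    """Cohort-construction constants.

    ``patient_weight_kg`` is provenance metadata only (contrast dosing is not
    computed; contrast costs are fixed per-examination constants).
    """

    population_size: int = 132_576
    prev_ic: float = 0.06
    prev_clti: float = 0.012
    male_fraction: float = 0.472
    entry_age: float = 66.0
    ic_iia_fraction: float = 0.5  # split of IC entrants between Fontaine IIa / IIb
    clti_iii_fraction: float = 0.5  # split of CLTI entrants between III / IV
    patient_weight_kg: float = 70.0

    def validate(self, errors: list[str]) -> None:
        if self.population_size < 0:
            errors.append("cohort.population_size: must be >= 0")
        for f_name in (
            "prev_ic",
            "prev_clti",
            "male_fraction",
            "ic_iia_fraction",
            "clti_iii_fraction",
        ):
            v = getattr(self, f_name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"cohort.{f_name}: {v} outside [0, 1]")
        if self.prev_ic + self.prev_clti > 1.0:
            errors.append("cohort.prev_ic + cohort.prev_clti: must be <= 1")
        if self.entry_age < 0:
            errors.append("cohort.entry_age: must be >= 0")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "prev_ic": self.prev_ic,
            "prev_clti": self.prev_clti,
            "male_fraction": self.male_fraction,
            "entry_age": self.entry_age,
            "ic_iia_fraction": self.ic_iia_fraction,
            "clti_iii_fraction": self.clti_iii_fraction,
            "patient_weight_kg": self.patient_weight_kg,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortParams":
        return cls(
            population_size=int(d["population_size"]),
            prev_ic=float(d["prev_ic"]),
            prev_clti=float(d["prev_clti"]),
            male_fraction=float(d["male_fraction"]),
            entry_age=float(d["entry_age"]),
            ic_iia_fraction=float(d.get("ic_iia_fraction", 0.5)),
            clti_iii_fraction=float(d.get("clti_iii_fraction", 0.5)),
            patient_weight_kg=float(d.get("patient_weight_kg", 70.0)),
        )


@dataclass(frozen=True)
class EconomicParams:
    discount_rate: float = 0.03  # per annum, applied to both costs and QALYs
    wtp_threshold: float = 48_700.0  # EUR per QALY
    exchange_rate_czk_per_eur: float = 24.64

    def validate(self, errors: list[str]) -> None:
        if self.discount_rate < 0:
            errors.append("economics.discount_rate: must be >= 0")
        if self.wtp_threshold < 0:
            errors.append("economics.wtp_threshold: must be >= 0")
        if self.exchange_rate_czk_per_eur <= 0:
            errors.append("economics.exchange_rate_czk_per_eur: must be > 0")

    def to_dict(self) -> dict:
        return {
            "discount_rate": self.discount_rate,
            "wtp_threshold_eur_per_qaly": self.wtp_threshold,
            "exchange_rate_czk_per_eur": self.exchange_rate_czk_per_eur,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EconomicParams":
        return cls(
            discount_rate=float(d["discount_rate"]),
            wtp_threshold=float(d["wtp_threshold_eur_per_qaly"]),
            exchange_rate_czk_per_eur=float(d["exchange_rate_czk_per_eur"]),
        )


@dataclass(frozen=True)
class ParameterSet:
    """Complete model parameterization for one simulation run."""

    modalities: Mapping[str, DiagnosticModality]
    utilities: UtilityTable
    clinical: ClinicalParams
    cohort: CohortParams = field(default_factory=CohortParams)
    economics: EconomicParams = field(default_factory=EconomicParams)
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        errors: list[str] = []
        if self.schema_version != SCHEMA_VERSION:
            errors.append(
                f"schema_version: expected {SCHEMA_VERSION}, got {self.schema_version}"
            )
        for name in MODALITIES:
            if name not in self.modalities:
                errors.append(f"modalities.{name}: missing")
        for mod in self.modalities.values():
            mod.validate(errors)
        self.utilities.validate(errors)
        self.clinical.validate(errors)
        self.cohort.validate(errors)
        self.economics.validate(errors)
        if errors:
            raise ParameterValidationError(errors)

    def life_expectancy(self, state: str) -> float:
        """Baseline remaining life expectancy (years) for a health state.

        Defined as the mean of the state group's time-to-death distribution;
        used by the life-expectancy-ratio adjustment of scheduled death times.
        """
        return self.clinical.survival[survival_group(state)].mean()

    def utility(self, state: str, age: float) -> float:
        return self.utilities.utility(state, age)

    def replace(self, **kwargs) -> "ParameterSet":
        d = {
            "modalities": self.modalities,
            "utilities": self.utilities,
            "clinical": self.clinical,
            "cohort": self.cohort,
            "economics": self.economics,
            "schema_version": self.schema_version,
        }
        d.update(kwargs)
        return ParameterSet(**d)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "modalities": {k: v.to_dict() for k, v in self.modalities.items()},
            "utilities": self.utilities.to_dict(),
            "clinical": self.clinical.to_dict(),
            "cohort": self.cohort.to_dict(),
            "economics": self.economics.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        ps = cls(
            modalities={
                k: DiagnosticModality.from_dict(k, v) for k, v in d["modalities"].items()
            },
            utilities=UtilityTable.from_dict(d["utilities"]),
            clinical=ClinicalParams.from_dict(d["clinical"]),
            cohort=CohortParams.from_dict(d["cohort"]),
            economics=EconomicParams.from_dict(d["economics"]),
            schema_version=int(d.get("schema_version", SCHEMA_VERSION)),
        )
        return ps

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True, default_flow_style=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def digest(self) -> str:
        """Stable content hash of the parameter set (for run manifests)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_parameters(path) -> ParameterSet:
    """Load a parameter config file, validate it, and return a ParameterSet.

    Raises :class:`ParameterValidationError` listing every violated invariant,
    or ``KeyError`` for missing required keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ps = ParameterSet.from_dict(raw)
    ps.validate()
    return ps


def czk_to_eur(amount_czk: float, rate: float = 24.64) -> float:
    """Convert CZK to EUR at ``rate`` CZK per EUR (unrounded)."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_czk / rate


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def sample_psa_parameters(
    base: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """Draw one probabilistic-sensitivity-analysis parameter set.

    Diagnostic sensitivities and state utilities are drawn from their beta
    distributions; each modality's summed examination cost (procedure plus
    contrast agent) from a uniform distribution spanning +/- the configured
    halfwidth around the point estimate, implemented as a common scale factor
    on both components.  Structural constants (discount rate, cohort inputs,
    clinical/time-to-event parameters) are left at their base values.  All
    draws are clipped to the declared invariant ranges, and the result passes
    the same validation as a loaded parameter set.
    """
    modalities = {}
    for name, mod in base.modalities.items():
        a, b = mod.sensitivity_beta
        sens = _clip01(float(rng.beta(a, b)))
        f = float(rng.uniform(1.0 - mod.cost_halfwidth, 1.0 + mod.cost_halfwidth))
        modalities[name] = DiagnosticModality(
            name=name,
            sensitivity=sens,
            procedure_cost=mod.procedure_cost * f,
            contrast_cost=mod.contrast_cost * f,
            sensitivity_beta=mod.sensitivity_beta,
            cost_halfwidth=mod.cost_halfwidth,
        )
    entries = {}
    for key, entry in base.utilities.entries.items():
        a, b = entry.beta
        entries[key] = UtilityEntry(
            value=_clip01(float(rng.beta(a, b))), beta=entry.beta
        )
    sampled = base.replace(
        modalities=modalities, utilities=UtilityTable(entries=entries)
    )
    sampled.validate()
    return sampled


def collapse_psa_to_point_masses(base: ParameterSet) -> ParameterSet:
    """Return a copy whose PSA distributions are degenerate at the point
    estimates (betas with huge concentration, zero cost halfwidth).

    Useful for null-case checks: PSA draws from the collapsed set reproduce
    the base case up to beta-sampling noise of order 1e-7.
    """
    d = copy.deepcopy(base.to_dict())
    for name, mod in d["modalities"].items():
        s = max(min(mod["sensitivity"], 1.0 - 1e-12), 1e-12)
        kappa = 1e14
        mod["sensitivity_beta"] = [s * kappa, (1.0 - s) * kappa]
        mod["cost_halfwidth"] = 0.0
    for key, entry in d["utilities"].items():
        u = max(min(entry["value"], 1.0 - 1e-12), 1e-12)
        kappa = 1e14
        entry["beta"] = [u * kappa, (1.0 - u) * kappa]
    return ParameterSet.from_dict(d)
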