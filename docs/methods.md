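# Methods

## The model

`padcea` is a patient-level, continuous-time discrete event simulation of the
lifetime course of symptomatic lower-limb peripheral arterial disease (PAD) in
the femoropopliteal segment, built to compare four diagnostic imaging
strategies — duplex ultrasonography (DUS), computed tomography angiography
(CTA), magnetic resonance angiography (MRA) and digital subtraction
angiography (DSA) — by lifetime cost (EUR, payer perspective) and
quality-adjusted life years (QALYs).

A cohort of 66-year-old symptomatic patients enters with intermittent
claudication (IC, Fontaine IIa/IIb) or chronic limb-threatening ischemia
(CLTI, Fontaine III/IV).  Cohort size follows from a reference population of
132,576 persons with prevalences of 6% (IC) and 1.2% (CLTI), rounded half
away from zero: 7,955 + 1,591 = 9,546 patients.  Sex (47.2% male) is recorded
for reporting; no sex-specific parameters exist in the base model.

Each patient's pathway:

1. **Diagnosis.** Every entrant is referred for the strategy's examination at
   entry.  The model has no false positives — all tested patients are
   diseased — so a test is positive with probability equal to the modality's
   sensitivity (DUS 0.86, CTA 0.96, MRA 0.96, DSA 1.00).  After a negative
   result an IC patient is re-examined after one year; a CLTI patient after a
   short interval (default 30 days).  Each examination charges the modality's
   procedure-plus-contrast cost.
2. **Intervention.** A positive test triggers revascularisation of a type
   drawn at random (PTA, PTA with stent, autologous bypass, prosthetic
   bypass; uniform weights by default).  Technical success, 30-day mortality
   and 30-day morbidity are simulated per procedure.  Success makes the
   patient asymptomatic for a sampled patency time (primary after the first
   success, secondary after the second).  At most two successful
   interventions are allowed; two consecutive technical failures end all
   interventional therapy; each repeat procedure may find the patient
   unsuitable for reoperation.  Perioperative death occurs 30/365.25 years
   after the procedure.
3. **Patency loss** returns the patient to the pre-intervention Fontaine
   class and, if still eligible, back into the diagnostic pathway.
4. **Progression.** While symptomatic, IC may progress to CLTI (entering
   Fontaine III) and CLTI to amputation, distinguished below- vs above-knee
   (affecting utility and one-off cost).  Amputation ends the interventional
   pathway for the modelled limb.
5. **Death.** Time of death is sampled once at entry from the initial state
   group's time-to-death distribution.  At every state change at time *t* the
   remaining time is rescaled:
   `t_death ← t + (t_death − t) · LE(new state) / LE(old state)`,
   where LE is the baseline life expectancy of a state group, defined here as
   the mean of its time-to-death distribution.  Sampling once and rescaling
   avoids the artificial life extension that resampling at each transition
   would introduce.

### Event ordering and randomness

Patients are mutually independent, so each trajectory is resolved by a
per-patient next-event loop over a small pending-event set ordered by
(time, fixed event-kind priority), with death < amputation < progression <
patency loss < diagnosis < intervention at ties.  This is observationally
equivalent to one global queue keyed by (time, priority, patient id) and
faster.

Every random decision draws from a named per-patient substream keyed by
(seed, patient id, stream index): diagnostics, intervention outcomes, patency
times, survival/progression, categorical draws, and scenario flags each have
their own stream, and each intervention consumes a fixed number of draws
regardless of branch.  Consequences:

* identical (seed, parameters, strategy) reproduce trajectories bit-for-bit;
* all strategies share the same patient-level randomness (common random
  numbers, CRN), so with equal sensitivities and equal examination costs the
  four strategies produce *identical* trajectories and exactly zero
  incremental cost and effect;
* raising a modality's sensitivity converts some negative tests to positive
  without disturbing the aligned intervention/patency/survival draws, so
  earlier treatment weakly dominates and cohort QALYs are nondecreasing in
  sensitivity (checked on paired runs; individual patients can still differ
  because diverged histories consume their diagnostic streams differently).

## Economics

Costs are in EUR (converted from CZK at 24.64 CZK/EUR where applicable); the
willingness-to-pay threshold is EUR 48,700 per QALY (CZK 1.2 million rounded
to the nearest hundred EUR).  Both costs and effects are discounted at the
same annual rate (default 3%; 0% and 5% as scenarios).  Discounting is
continuous-time: a point cost at time *t* is worth `c(1+r)^(−t)` and a flow
on [t0, t1] is worth `[(1+r)^(−t0) − (1+r)^(−t1)]/ln(1+r)` per unit; an
annual-cycle approximation is available as a cross-check toggle.
Pharmacotherapy is a continuous cost stream from entry (base case) or from
the first positive diagnosis (scenario).  QALYs integrate the
piecewise-constant utility of the visited states (asymptomatic 0.89/0.84
split at age exactly 75, IC IIa 0.63, IIb 0.52, CLTI III 0.44, IV 0.40,
below-knee amputation 0.61, above-knee 0.40).

Pairwise comparisons report ΔC, ΔE and the ICER ΔC/ΔE in the trade-off
quadrants, or a dominance/cost-minimization label otherwise; reported ICERs
are rounded to the nearest integer EUR/QALY with unrounded arithmetic
internally.

## Probabilistic sensitivity analysis

Each PSA iteration draws diagnostic sensitivities and state utilities from
their published beta distributions (used verbatim even where the implied mean
disagrees with the point estimate — notably DUS beta(2.03, 0.06) with mean
≈0.97 vs point 0.86, DSA beta(12.13, 1.81) with mean ≈0.87 vs 1.00, and
above-knee amputation beta(79.80, 319.20) with mean 0.20 vs 0.40; the base
case always uses the point estimates), and each modality's summed examination
cost from a uniform ±20% band applied as a common scale factor to procedure
and contrast components.  Clinical parameters are held at their point values:
their sensitivity distributions are not published.  Two named streams are
used per iteration — "parameters" for the PSA draws and "patients" for
trajectory randomness, the latter re-seeded identically per iteration index
across strategies (CRN).  Outputs: per-iteration (ΔC, ΔE) clouds vs DUS, 95%
percentile confidence intervals, the ICER of mean deltas (per-iteration ICERs
are never averaged — the ratio is unstable near ΔE = 0), and
cost-effectiveness acceptability curves using strictly positive net monetary
benefit (ties count as not accepted).  As λ → ∞ the CEAC converges to
P(ΔE > 0); because the DUS sensitivity distribution concentrates near 1, a
sizeable share of iterations puts a comparator in the upper-left quadrant and
the curves plateau below 1, which is the qualitative signature the scaled-down
PSA checks.

## Scenarios

* **Discount rates** 0%, 3%, 5%: trajectories do not depend on the rate, so
  each strategy is simulated once and re-valued per rate with identical
  seeds.
* **Combined DSA:** a fraction *p* of DSA-strategy patients whose *first*
  intervention is endovascular (PTA/PTA-S) are not charged the examination
  that led to it (the cost is absorbed into the procedure).  The flag is a
  per-patient draw from a dedicated substream, so *p* = 0 reproduces the base
  case bit-exactly and the waived set grows monotonically in *p*.
  Bypass-assigned patients always pay for DSA, and repeat diagnoses are never
  waived.
* **Pharmacotherapy timing:** the continuous pharmacotherapy cost stream
  starts at entry or at the first positive diagnosis; utilities unchanged.
  The saving is largest for the least sensitive modality (DUS), whose
  diagnosis is delayed longest.
* **Two-way sweep:** any two scalar parameter fields (dot-path addressed) on
  arbitrary grids, same seeds at every grid point, reporting per-strategy
  means and the comparator-vs-baseline ICER per cell.

## The synthetic fixture, and what results mean

The published inputs cover the diagnostic sensitivities and their beta
parameters, examination costs with the ±20% band, state utilities with their
beta parameters, cohort constants, the discount rate, exchange rate and WTP
threshold.  Everything else the simulation needs — technical success, 30-day
mortality/morbidity, probability of being unsuitable for reoperation,
patency-time and progression-time distributions, state-specific survival,
intervention/amputation/pharmacotherapy/morbidity costs — is available only
in unpublished supplementary material.  The default fixture therefore fills
these with synthetic placeholders (Weibull patency with ~4-year primary and
~3-year secondary medians, technical success 0.90–0.95, 30-day mortality
1–3%, uniform intervention-type weights, etc.), every one tagged PLACEHOLDER
in a provenance manifest together with a declared plausible range, and logged
by the CLI whenever consumed.  Survival placeholders were calibrated once so
that base-case cohort median survival lands near the published ≈8.5 years
(the default fixture gives ≈8.5 at desk scale).

Consequently the published lifetime magnitudes (e.g. mean DUS cost
EUR 10,778 and 5.542 QALYs) are **not reproducible** from printed inputs and
are not reproduced by this package; the simulator's desk-scale means differ
by roughly 10–15%.  What the tests verify instead is (a) every published
ICER recomputed from the published per-strategy means and incremental
columns, (b) cohort construction and threshold conversion from printed
constants, and (c) the structural properties of the simulator (CRN null
case, discount monotonicity, quadrature agreement of discounted accrual,
treatment-rule invariants over 10^5 lifetimes, bit-identical reruns, CEAC
limits and plateau shape).  Passing tests demonstrate correctness of the
model logic and arithmetic under the synthetic fixture, not equivalence to
the unpublished parameterization — and none of the placeholder choices is
informative about real clinical practice.

## Numerical choices and problem sizes

* Time unit: years as continuous reals; 30-day quantities are 30/365.25.
* Time-to-event sampling is by inverse transform from a single uniform draw
  (Weibull, exponential, lognormal, gamma families), keeping paired runs
  aligned.
* Rounding: cohort counts half away from zero (which reproduces the printed
  7,955/1,591); reported ICERs to the nearest integer EUR/QALY; reported
  costs to whole EUR and effects to 3 decimals, with unrounded companions.
* Defaults chosen for desk-scale work: base-case runs support the full 9,546
  cohort but tests and the acceptance script use 2,000–4,000 patients; the
  scaled-down PSA uses 100 iterations × 1,000 patients (the full 1,000 × full
  cohort remains available through the API/CLI).
* Degenerate inputs: zero discount rate, zero sensitivities, point-mass PSA
  distributions and empty cohorts are all defined and tested; a sampled death
  at t = 0 yields a single-event trajectory with no accruals.

## Known limitations

* One limb, one (femoropopliteal) segment; the contralateral limb exists
  only as an amputation target without an independent disease process.
* No myocardial infarction or stroke events; no exercise-therapy first line;
  contrast-agent dosing is not computed (the 70 kg assumption is recorded as
  metadata only).
* Whether a negative CLTI examination should repeat the same modality or
  escalate to another is ambiguous in the source material; the model repeats
  the same modality after a short interval.
* 30-day morbidity affects costs only, not utilities.
* The IC→CLTI progression enters Fontaine III, and patency loss returns the
  patient to the pre-intervention Fontaine class; both are modelling choices
  where the source is silent.
* All clinical placeholder values are synthetic; absolute cost/QALY levels
  produced with the default fixture should not be quoted as estimates for
  any real population.
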