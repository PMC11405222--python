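# padcea

Lifetime cost-effectiveness of diagnostic imaging strategies in symptomatic
lower-limb peripheral arterial disease (PAD), by patient-level discrete event
simulation.

Symptomatic PAD — intermittent claudication (IC, Fontaine IIa/IIb) or chronic
limb-threatening ischemia (CLTI, Fontaine III/IV) — requires an imaging
examination before revascularisation.  Four strategies are compared: duplex
ultrasonography (**DUS**, sensitivity 0.86, EUR 47/exam), computed tomography
angiography (**CTA**, 0.96, EUR 100 incl. contrast), magnetic resonance
angiography (**MRA**, 0.96, EUR 294) and digital subtraction angiography
(**DSA**, 1.00, EUR 422).  A more sensitive examination treats patients
earlier but costs more; the trade-off is quantified as an incremental
cost-effectiveness ratio

    ICER = ΔC / ΔE   [EUR per QALY]

between each strategy and DUS (the lowest-cost baseline), judged against a
willingness-to-pay threshold λ = EUR 48,700/QALY (CZK 1.2 million at 24.64
CZK/EUR).  Each of 9,546 simulated 66-year-olds (7,955 IC + 1,591 CLTI, from
a population of 132,576 at prevalences 6%/1.2%) moves in continuous time
through diagnosis (no false positives; retest after 1 year for IC, 30 days
for CLTI), randomly assigned endovascular or bypass intervention (technical
success, 30-day mortality/morbidity; at most two successful procedures; two
consecutive failures end interventional therapy), patency-limited
asymptomatic spells, IC→CLTI progression, below/above-knee amputation, and
death — the remaining time to death rescaled at every state change by the
ratio of state life expectancies.  Costs (payer perspective) and
health-state utilities are discounted continuously at 3% (0%/5% in
scenarios); QALYs integrate the piecewise-constant utility of the visited
states with an asymptomatic utility switch at age 75.  All strategies share
one cohort and identical patient-level random streams (common random
numbers), so incremental results reflect the strategy alone.  A
probabilistic sensitivity analysis redraws sensitivities and utilities from
their published beta distributions and examination costs from ±20% uniform
bands, yielding cost-effectiveness planes and acceptability curves (CEAC).

The published inputs cover the diagnostic, utility, cohort and economic
parameters; the clinical time-to-event and non-diagnostic cost parameters
are only available in unpublished supplementary material and are replaced by
documented synthetic placeholders (tagged in a provenance manifest).
Absolute cost/QALY levels from the default fixture are therefore
illustrative; the incremental arithmetic, the model logic and the published
summary tables are what the test suite verifies.  See `docs/methods.md`.

## Worked example

```python
from padcea import default_fixture, run_base_case

params, manifest = default_fixture()
result = run_base_case(params, seed=1, n_patients=4000)
print(result.table())
```

prints (desk-scale cohort of 4,000 patients; `examples/base_case.py`):

```
strategy  cost_eur  cost_difference_eur  effect_qaly  effect_difference_qaly  icer_eur_per_qaly    label
     DUS    9124.0                  NaN        6.045                     NaN                NaN baseline
     CTA    9294.0                169.0        6.076                   0.031             5395.0     icer
     MRA    9628.0                504.0        6.076                   0.031            16046.0     icer
     DSA    9860.0                736.0        6.086                   0.042            17628.0     icer
```

DUS is the cheapest and least effective strategy, DSA the costliest and most
effective, CTA and MRA tie on effects with CTA cheaper, and every ICER falls
below the EUR 48,700/QALY threshold — the qualitative ordering of the
published analysis.  Cohort median survival is ≈8.5 years.  The absolute
levels depend on the synthetic placeholders (the manifest lists all 48).

The pure-arithmetic worked example reproduces the published ICERs exactly
from the published cohort means, e.g. CTA vs DUS: ΔC = EUR 26,
ΔE = 0.012 QALY, ICER = EUR 2,167/QALY (`examples/worked_icers.py`).

A command-line interface mirrors the library:

```bash
padcea base-case --seed 1 --n-patients 4000 --out results/
padcea psa --seed 1 --n-iter 1000 --n-patients 1000 --out results/
padcea scenarios --seed 1 --out results/
padcea sweep --seed 1 --out results/
padcea make-fixture --out results/
```

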