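# cytocea

Decision-analytic cost-utility modelling of **one-off Cytosponge-TFF3
screening for Barrett esophagus (BE)** in primary-care patients with
gastro-esophageal reflux disease (GERD), versus usual care.

Esophageal adenocarcinoma (EAC) has a dismal prognosis unless caught
early, and its precursor — Barrett esophagus — is mostly undiagnosed.
The Cytosponge-TFF3 is a swallowed cell-collection sponge coupled with
trefoil-factor-3 immunostaining that triages GERD patients for
confirmatory endoscopy without endoscoping everyone. `cytocea` is a
tested, reusable implementation of the health-economic model used to ask
whether offering that test once is worth the money: a two-chain Markov
cohort model of BE progression, with screening-cost entry logic,
incremental cost-effectiveness analysis, probabilistic and deterministic
sensitivity analysis, scenario analysis and budget impact. It is aimed
at health economists and screening researchers who want to reproduce,
stress or extend the published analysis.

## The model

Seven health states: `NoBE → NDBE → LGD → HGD → EarlyEAC → LateEAC → Dead`
(non-dysplastic BE; low/high-grade dysplasia; early = curable and late =
palliative adenocarcinoma), with regression LGD→NDBE and a direct
NDBE→EarlyEAC route. A cohort of n = 6834 GERD patients per arm (median
age 69) enters at *t* = 0:

* **Treatment chain** — true positives confirmed by endoscopy (assumed
  gold-standard). They receive state-appropriate therapy at entry
  (EMR/RFA endotherapy for BE and dysplasia; resection/chemotherapy with
  90-day surgical mortality for early EAC); successes move to `NoBE`,
  failures remain in-state, and one-off costs and procedure disutilities
  (stricture, perforation, EMR/RFA, chemotherapy, esophagectomy — each a
  utility decrement × duration) are charged at entry.
* **Natural-history chain** — everyone else, including false negatives,
  progressing under annual transition probabilities composited with
  age-specific all-cause mortality from a packaged life table.

Yearly cycles run to age 100 with half-cycle (trapezoidal) correction;
costs (GBP) and QALYs are discounted at 3.5%/year. Cost-effectiveness is
the incremental cost-effectiveness ratio

ICER = ΔC/ΔE  (GBP per QALY gained),

with net monetary benefit NMB = ΔE·λ − ΔC at willingness-to-pay λ. The
PSA re-runs the pipeline over 1000 independent parameter draws
(moment-matched beta for probabilities/utilities, gamma for costs) and
summarises them as a CE plane and a cost-effectiveness acceptability
curve; the one-way DSA varies each parameter between documented bounds
(default ±20%) and ranks ICER ranges tornado-style. A per-person
microsimulation oracle and a synthetic screening-trial generator
(invitation → uptake → disease state → TFF3 result → confirmatory
endoscopy) make every stage testable without external data.

All inputs are data, not code: a YAML settings file plus CSV tables
(transitions, costs, utilities, life table), each parameter tagged with
provenance and sensitivity metadata. The packaged base case reproduces
the reference analysis; appendix-level inputs unavailable in print were
calibrated once against the published outputs (see
`docs/methods.md` and `scripts/calibrate.py`).

## Worked example

```sh
$ cytocea run-base --out demo
ICER: 5500 GBP/QALY  (dC 82 GBP, dE 0.015 QALYs)
```

One round of screening costs £82 more per GERD patient than usual care
(£77 of it the screening programme itself) and yields 0.015 extra QALYs
per patient — small on average because >90% of the cohort has no BE, but
concentrated in the ~131 patients whose disease is found and treated —
giving £5,500 per QALY gained, well under the usual £20,000 threshold.
`demo/cost_effectiveness.csv` holds the per-patient breakdown:

```
quantity,intervention,usual,difference
screening_cost,76.78021656,1.1425226807140767,75.63769388352355
treatment_cost,488.6523061,482.00000000010044,6.652306116475131
total_cost,565.4325227,483.1425226808145,82.28999999999871
qalys,9.925961818,9.910999999997358,0.014961818181877362
life_years,13.02712309,13.015386151389837,0.011736935723675401
icer,5500,,
```

and `demo/model_outputs.csv` the clinical trajectory — e.g. 161 usual-care
EAC deaths versus 143 with screening, an 18-death difference from one
screening round:

```
arm,invited,cytosponge_tests,endoscopies,...,incident_early_eac,eac_deaths
intervention,6834,1654,198,...,164.991945,142.7701986
usual,0,0,16,...,186.26362,161.4047439
```

The same library surface is available programmatically:

```python
import cytocea

ps = cytocea.base_case()
trace_int, trace_usual, ce = cytocea.run_base_case(ps)
print(round(ce.icer))          # 5500
psa = cytocea.run_psa(ps, cytocea.PSAConfig(n_draws=1000, seed=1))
print(psa.prob_cost_effective(20_000))   # ~0.96
```

Other subcommands: `run-psa` (CE plane, CEAC, ICER interval), `run-dsa`
(tornado table/plot), `budget` (≈ £21.6m over 29 years ≈ £746k/year for
262,941 eligible patients), `scenario` (repeat-test readministration or
`--uptake` rescaling) and `synth` (synthetic trial through the full
pipeline). Every run writes a `manifest.json` sufficient to reproduce it.

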