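# Methods

## Model structure and assumptions

The model is a cohort-expectation state-transition (Markov) model over
seven mutually exclusive health states: no Barrett esophagus (`NoBE`),
non-dysplastic BE (`NDBE`), low- and high-grade dysplasia (`LGD`,
`HGD`), early (curable) and late (palliative) esophageal adenocarcinoma
(`EarlyEAC`, `LateEAC`), and absorbing `Dead`. Fractional persons are
allowed throughout — counts are expectations over the cohort, matching
the decimal entries of the trial's starting table.

Each arm's 6834 GERD patients are split at entry into a *treatment*
chain (screen-detected, endoscopy-confirmed true positives) and a
*natural-history* chain (everyone else, including false negatives).
Treatment is applied once, at entry: endotherapy (RFA, plus EMR for HGD)
for BE/dysplasia and a resection + chemotherapy pathway with 90-day
surgical mortality for early EAC. Successes join the natural-history
chain's `NoBE` state; failures remain in-state in the natural-history
chain. After entry both arms therefore evolve under a single
natural-history process, and the arms differ only in the entry split and
the screening/treatment costs. A consequence worth knowing: patients
treated at entry leave surveillance entirely, so cumulative
*entry counts* into LGD in the screened arm come out somewhat below the
reference analysis (whose footnotes imply treated patients remained
under surveillance and could be re-treated); the usual-care trajectory
and all incremental results are unaffected. Late EAC may not be a
starting state, and treated-at-entry late EAC is rejected as an error.

False positives (implied by specificity 92.4% among non-diseased
attendees) incur screening and endoscopy costs — carried by the observed
endoscopy counts — but enter `NoBE` with no treatment cost and do not
perturb the allocation.

Key structural conventions:

* **Cycles and correction.** One-year cycles from the start age (default
  69) to the age cap (default 100; survivors at the cap are reported as
  a censoring fraction, ~1.5% at base case). State-occupancy quantities
  (life years, QALYs, recurring costs) accrue on the trapezoidal mean of
  start- and end-of-cycle occupancy (half-cycle correction); one-off
  quantities (screening, treatment entry, palliative care) are charged
  at full value at their cycle.
* **Discounting.** Factor 1/(1+r)^t with t = whole cycles since entry
  and r = 0.035/year, so cycle-0 accruals — including screening and
  treatment-entry costs — are undiscounted.
* **Mortality compositing.** Disease transitions are conditional on
  surviving the year; every alive state carries the life-table
  probability q(age), and EAC states add cancer-specific annual
  mortality. Rows of the resulting matrix sum to 1 within 1e-12.
* **EAC deaths.** Any death from the `LateEAC` state (cancer-specific or
  background — stage-4 patients' deaths are attributed to the cancer)
  plus cancer-specific deaths from `EarlyEAC` and 90-day surgical deaths
  at entry. Palliative care is charged once per `LateEAC` death.
* **Recurring costs.** Acid-suppressant (PPI/H2RA) drug cost accrues for
  every alive state except `LateEAC`; `LateEAC` carries one
  chemotherapy course per person-year as its management cost.
* **Incident counts.** "Start with or develop X" counts state *entries*
  (initial occupancy plus per-cycle inflow), not distinct persons — a
  cohort model cannot distinguish re-entries, and the reference output
  tables evidently counted the same way.

## Parameters

Every scalar input lives in the parameter registry with a provenance
tag (`trial-publication` — printed trial/report values; `literature` —
values typical of the antecedent modelling literature; `assumption`;
`derived-calibration` — see below), optional low/high bounds for the
one-way DSA, and a sampling distribution for the PSA. Headline
defaults:

| parameter | default | source class |
|---|---|---|
| start age / cohort / uptake | 69 y / 6834 / 24.2% | trial-publication |
| TFF3 sensitivity / specificity | 0.799 / 0.924 | trial-publication |
| confirmatory endoscopy accuracy | 1.0 (gold standard) | trial-publication |
| BE prevalence in cohort | 8.83% (NDBE 8.29%, LGD 0.07%, HGD 0.20%, EarlyEAC 0.27%) | trial-publication (starting table) |
| discount rate / WTP threshold | 3.5%/y / £20,000 per QALY | trial-publication |
| endoscopy + biopsy | £488 (= £7808 / 16) | trial-publication |
| Cytosponge-TFF3 per test | £258.82 | derived-calibration |
| disutility durations | stricture 2 wk, perforation 4 wk, EMR/RFA 4 wk, chemotherapy 4.5 mo, esophagectomy 3 mo | trial-publication (perforation duration assumed) |
| budget population / horizon | 262,941 / 29 y | trial-publication (treated as inputs) |

The Cytosponge unit cost is never printed; it is fixed in closed form as
the value making 1654 tests + 198 endoscopies total £524,716, and falls
inside the published £144–£344 sensitivity band.

The life table is a packaged Gompertz abridgement (ages 50–100, log
slope 0.095/year, level calibrated; q(69) ≈ 0.0134), overridable via
config — the analysis needs *a* national-style life table, and its level
is pinned by the published discounted life expectancy rather than by any
one registry year.

## Calibration (`scripts/calibrate.py`)

The natural-history transition probabilities, state utilities and
several unit costs were published only in an appendix that is not part
of the printed record. They are therefore shipped as *data* calibrated
once, in a fixed staged order, to the printed model outputs:

1. life-table level → usual-care discounted life years (13.016);
2. transitions (9 probabilities + effective NDBE treatment success) →
   usual-care cumulative incident LGD/HGD/early-EAC and EAC deaths,
   the between-arm EAC-death difference, and incremental life years;
3. utilities (NoBE level and the NoBE–NDBE gap; dysplasia states tied at
   small offsets) → usual-care QALYs (9.911) and incremental QALYs;
4. costs (annual PPI, RFA course) → usual-care treatment cost (£482)
   and the incremental cost (£82.29).

Stages 1–2 iterate twice; later stages cannot perturb earlier targets.
The fit reproduces every targeted quantity within 10% (most within 1%);
the residual tension sits between the EAC-death difference (fit −7%)
and incremental life years (fit +7%), which pull the cancer-timing
parameters in opposite directions.

Calibrated values are effective, not literature, estimates. Notably the
fitted NDBE progression (NDBE→LGD 0.054/y, NDBE→EarlyEAC 0.006/y) is
faster than published natural-history cohorts — but it is what the
printed outputs imply (567 prevalent NDBE generating ~160 incident
early EAC over a lifetime); the fitted `NoBE`→`NDBE` incidence is
correspondingly near zero, and the effective NDBE treatment success
(0.61) folds post-ablation recurrence into a single entry-time
probability. They should be read as a faithful *input reconstruction*
of the reference analysis, not as fresh clinical evidence.

## Sensitivity analyses

**PSA.** 1000 draws (seeded `numpy` Generator; bit-for-bit reproducible)
sampling every flagged parameter independently: gamma for costs, beta
for probabilities, moment-matched with default SD = 20% of the mean —
mirroring the ±20% DSA convention, since the reference analysis
acknowledged it lacked standard errors. State utilities instead carry an
absolute SD of 0.02 (the order of published EQ-5D standard errors); a
20%-of-mean SD on a ~0.77 utility would imply ±0.15 utility swings that
no elicitation study reports and, under independent sampling, would make
utility noise dominate the incremental QALY. Uptake, prevalence and
sensitivity draws re-trigger the cohort-entry rebuild (tests,
endoscopies and detections scale proportionally). Per-draw ICERs with
non-positive QALY gains are retained for the percentile interval, but
the CEAC uses the sign of net monetary benefit, which is well defined in
every quadrant. The CEAC grid is £0–£50,000 in £1,000 steps.

**DSA.** One-way variation between explicit bounds where the reference
analysis names them (uptake 10–50%, start age 50–74, prevalence 4–12%,
Cytosponge £144–£344, sensitivity 76.4–83.0%) and mean ±20% (clipped to
the unit interval for probabilities) otherwise. Structural parameters
rebuild the entry allocation; start age re-enters the life table at the
new age with the same allocation. Entries are ranked by |ICER(high) −
ICER(low)|. One known artifact: at the low extreme of the `NoBE`
utility the treated patients are moved to a state *assumed worse* than
NDBE, the QALY gain turns negative and the signed ICER crosses
quadrants — a standard one-way-DSA pathology; the tornado keeps the
signed values and the entry simply ranks (very) wide.

**Scenarios.** Repeat-test readministration adds the observed 202 extra
tests, 23 extra endoscopies and (+0.1 LGD, +1.0 HGD, +2.0 early-EAC)
detections. Uptake rescaling scales the funnel linearly. Budget impact
is eligible patients × unrounded ΔC, spread undiscounted over the
horizon.

## Synthetic trials and validation

The generator draws, per invited person: attendance ~ Bernoulli(uptake);
true state ~ multinomial over the prevalence vector (the disease split
conditional on BE matches the trial's starting table); TFF3 positivity
with probability = sensitivity if diseased else 1 − specificity;
confirmatory endoscopy attendance ~ Bernoulli; perfect endoscopy
resolves true disease. An optional repeat-test path re-reads a
configurable inadequate fraction (base 311/1654, attended 202/311).
Funnel inversion — detected / (attendees × sensitivity × endoscopy
attendance) — recovers prevalence unbiasedly, verified over 200
replicate trials.

What the generator does *not* emulate: cluster randomisation and
GP-practice effects, symptom-driven referral dynamics in the usual-care
arm (a fixed endoscopy count stands in), stage-dependent TFF3
sensitivity, and any dependence of attendance on disease status. Tests
passing on synthetic data therefore validate the pipeline's
*arithmetic and statistical structure*, not the trial's clinical
generalisability.

The deterministic engine is validated against an independent per-person
microsimulation (same matrices, 50,000 individuals, fixed seed), which
must reproduce mean life years and QALYs within three Monte-Carlo
standard errors, alongside closed-form two-cycle oracles, conservation
and row-stochasticity invariants, and limit identities (unit utility /
zero discount ⇒ QALYs = life years; zero treatment success ⇒ the arms'
state dynamics coincide).

## Numerical choices and degenerate inputs

Conservation is enforced to 1e-9 relative; matrix rows to 1e-12. ICER
at ΔE = 0 is an explicit `None` sentinel; the cost-saving quadrant is
reported as "dominant", never as a negative headline ratio. Display
rounding (£ to units, QALYs to 3 d.p.) never feeds back into
arithmetic. Beta sampling clips requested SDs inside the distribution's
support; parameters with zero mean are not sampled. Problem sizes used
throughout (1000 PSA draws, 50,000 microsimulated persons, 200 replicate
trials) were chosen so Monte-Carlo error is well below the tolerances
they are tested against.

## Known limitations

* Only one screening round; BE incidence after a negative screen is not
  modelled.
* The two EAC stages carry provisional (calibrated) inter-stage
  dynamics; monotonicity and conservation results do not depend on
  them, but cancer-timing quantities (EAC-death difference, incremental
  life years) inherit their uncertainty.
* Treated patients exit surveillance (see above) — re-treatment on
  progression is not modelled.
* PSA dispersions are assumptions; PSA-derived summaries (point ICER,
  interval, per-arm SDs) are reproducible only in order of magnitude.
* No currency conversion or price-year inflation adjustment.
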