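# crcsim — colorectal-cancer screening microsimulation under real-world adherence

`crcsim` is a race- and gender-stratified microsimulation of colorectal
cancer (CRC) screening for average-risk U.S. adults.  It asks how
screening strategies compare — CT colonography (CTC) every 5 years,
colonoscopy every 10, annual fecal immunochemical testing (FIT),
multitarget stool DNA (MT-sDNA) every 3, and the real-world *status quo*
mix of colonoscopy and FIT — when adherence is not assumed perfect but
modeled from observed behavior that differs by race (Black, White) and
gender.  It is written for health-economics and screening-policy
researchers who want a tested, config-driven pipeline: natural history,
adherence behavior, calibration, and cost-effectiveness analysis, each
usable on its own from Python.

## The model

**Natural history.** Each person occupies one state of the
adenoma–carcinoma sequence per annual cycle: no lesion; adenoma by size
(diminutive 1–5 mm, small 6–9 mm, large ≥ 10 mm); preclinical cancer by
stage I–IV (present, undiagnosed, screen-detectable); clinical cancer by
stage; death from CRC or other causes.  Transitions are annual
probabilities: age-banded adenoma onset, size growth, malignant
transformation, a geometric preclinical sojourn with per-stage clinical
detection, stage-graded excess mortality for a fixed horizon after
diagnosis, and a life-table background hazard.  Cohorts of 40-year-olds
are produced by simulating forward from a lesion-free state at age 20.

**Adherence.** Screening behavior has three components per modality:
*initial* adherence (annual probability of first-ever screening by age
band 45–75), *repeat* adherence at the guideline interval (by <65/≥65),
and *switching* between colonoscopy and FIT under the status quo.
Single-modality strategies are derived from the status-quo schedules:

- initial: `p' = min(1, p × RR)`, with RR specific to the modality a
  person would have chosen on their own (CTC: 1.80 from
  colonoscopy-origin, 0.53 from FIT-origin; colonoscopy-only: 0.29 from
  FIT-origin; FIT/MT-sDNA: 3.45 from colonoscopy-origin);
- repeat: taken from the named source modality; for CTC among Black
  adults the colonoscopy repeat probability is uplifted on the odds
  scale, `p' = OR·o/(1+OR·o)` with `o = p/(1−p)` and OR = 1.83.

Positive non-colonoscopy tests lead to diagnostic colonoscopy with
modality-specific follow-up adherence (CTC 97.7%, FIT 48.7%, MT-sDNA
66.6%); polypectomy moves people into tiered surveillance (low/high
risk) with its own attendance probabilities.  All screening ends after
age 75.

**Economics and decision analysis.** Event ledgers are converted to
discounted (3%/year) lifetime costs and QALYs; QALYs gained (QALYG) are
paired differences against a seed-matched no-screening run.  Strategies
are ranked by cost, dominated and extended-dominated ones removed, and
ICERs chained along the frontier; the cost-effective strategy has the
largest ICER at or below the willingness-to-pay threshold
($100,000/QALYG default) — equivalent to maximizing net monetary
benefit, `NMB = WTP×QALYG − cost`.  One-way sensitivity analyses report
incremental NMB tornado rows; probabilistic sensitivity analysis samples
Beta/PERT parameter distributions and reports cost-effectiveness
acceptability curves.

**Calibration.** Free natural-history parameters are fitted to weighted
summary targets (age-specific incidence, stage distributions by
screening era, size-resolved adenoma prevalence, polypectomy size mix,
screening utilization) by an adaptive tree-structured-Parzen-estimator
style sampler scored with relative mean squared error; the top-100
parameter sets are retained.  A synthetic-data module generates every
input from a known truth so calibration is testable by parameter
recovery.

## Worked example

```python
from crcsim import build_icer_ladder, make_truth
from crcsim.scenario import STRATEGY_ORDER

truth = make_truth(seed=1, group="Black women")
scenario = truth.scenario()
outcomes = scenario.outcomes_frame(STRATEGY_ORDER, n=20_000, seed=11)
ladder = build_icer_ladder(outcomes[["strategy", "cost", "qalyg"]])
print(ladder.table.round(2).to_string(index=False))
print("dominant:", ladder.dominant)
```

prints (seed 1, 20,000 persons):

```
        strategy       cost  qalyg      status  icer
        ctc_only 5124506.06  51.06 undominated   NaN
colonoscopy_only 5706405.20  36.74   dominated   NaN
      status_quo 5716615.99  36.44   dominated   NaN
        fit_only 6017640.07  34.80   dominated   NaN
     mtsdna_only 6896609.23  41.63   dominated   NaN
    no_screening 7539390.70   0.00   dominated   NaN
dominant: ctc_only
```

Costs are USD and QALYG are QALYs gained versus no screening, both per
1000 persons and discounted at 3%.  Every screening strategy saves money
and gains QALYs relative to no screening, and for this group the CTC
strategy is *dominant*: it gains the most QALYs at the lowest cost, so
every other row is eliminated by dominance and no ICER is defined.  The
`examples/` directory walks through each capability (adherence
derivation, natural history, CEA, calibration, PSA) the same way; the
`crcsim` CLI (`crcsim --desk-scale run`) executes the full pipeline and
writes its tables plus a reproducibility manifest.

## Notes

Cost and disutility schedules ship as clearly-labelled synthetic
placeholders of realistic magnitude (only the CTC procedure cost, $225,
is a published 2024 CMS rate); swap in your own via
`CostSchedule`/`UtilitySchedule` config.  The natural-history transition
rates are free parameters recovered by calibration, not asserted
constants.  See `docs/methods.md` for assumptions, parameter defaults,
and limitations.
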