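# Methods

This note documents the model, its assumptions, the packaged parameter
defaults and why they were chosen, the synthetic-data design, numerical
conventions, and known limitations.  Nothing here states an empirical
result the test suite or `scripts/acceptance.py` does not itself
compute.

## Natural-history model

The disease process is a single most-advanced-lesion state machine over
the adenoma–carcinoma sequence: `NO_LESION → ADENOMA_DIMINUTIVE (1–5 mm)
→ ADENOMA_SMALL (6–9 mm) → ADENOMA_LARGE (≥10 mm) → PRECLINICAL_CRC
I–IV → CLINICAL_CRC I–IV → death`.  Multiple concurrent adenomas are not
tracked; multiplicity is absorbed into the calibrated rates.  All
transitions are annual probabilities and a person makes at most one
forward step along the chain per cycle:

| parameter | structure | default (nominal) | units |
|---|---|---|---|
| `adenoma_onset` | decadal age bands 20–80+ | 0.002 → 0.018, rising | /year |
| `growth_dim_to_small` | scalar | 0.060 | /year |
| `growth_small_to_large` | scalar | 0.055 | /year |
| `large_to_preclinical` | scalar | 0.060 | /year |
| `stage_progression` | preclinical I→II, II→III, III→IV | 0.35, 0.45, 0.50 | /year |
| `clinical_detection` | per preclinical stage | 0.12, 0.25, 0.45, 0.70 | /year |
| `crc_mortality` | per clinical stage | 0.010, 0.035, 0.090, 0.350 | /year |

The preclinical→clinical transition is a per-stage annual detection
probability, i.e. a geometric sojourn — the simplest model consistent
with a preclinical/clinical stage split; detection competes with stage
progression and is evaluated first within the cycle.  CRC excess
mortality applies for a configurable `survival_horizon` (default 10
years) after diagnosis, then only background mortality; survival does
not otherwise depend on age at diagnosis.  Background mortality is an
illustrative per-gender Gompertz life table (`a·e^{b·age}`, giving adult
life expectancies in the high-70s for men and low-80s for women),
swappable via config; no national table is asserted.  Nominal rates
carry mild group contrasts (Black onset multiplier 0.80–0.92) so that,
without screening, Black adults show lower CRC incidence than White
adults and any reversal under the status quo is driven by adherence.

**Within-cycle order** (fixed for determinism): (1) screening or
surveillance decision and testing, (2) treatment effects of polypectomy
or diagnosis, (3) disease progression, (4) mortality — CRC excess death
first for clinical states, then other-cause death for every living
state.

**Cohort initialization.** Cohorts of 40-year-olds are produced by
simulating from a lesion-free state at a seeding age (default 20) with
screening disabled and mortality suspended, so everyone is alive at the
start age; anyone who would reach clinical cancer during burn-in is
reset to lesion-free, since an average-risk screening cohort excludes
people with a CRC history.  Screening history before 45 is handled by
the adherence model, not burn-in.

**Random numbers.** Every stochastic decision draws one uniform
addressed by `(seed, person_id, age, channel)` through a splitmix64
counter hash.  Consequences: results are independent of person order
and chunking; replaying the same initialized cohort under different
strategies or candidate parameters uses common random numbers, so
paired comparisons (QALYG, calibration objectives, one-way sensitivity)
are not swamped by Monte-Carlo noise.

## Adherence model

Each modality's adherence has three components: initial (annual
probability of first-ever screening, by age band 45–49 … 70–75), repeat
(annual probability when at or past the due date, by <65/≥65), and
switching between colonoscopy and FIT under the status quo (a
calibrated parameter, default 0 until calibrated).  The packaged
status-quo schedules and the derivation multipliers are published
values; derivation is `min(1, p·RR)` for initial schedules and an
odds-scale adjustment (OR 1.83, CTC repeat among Black adults) for
repeat schedules.  Conventions the sources leave open, resolved here:

- a repeat draw missed in a year is retried annually while overdue (not
  deferred a full interval);
- surveillance non-attenders become re-eligible one tier-interval later;
- surveillance intervals default to 5 years (low-risk: history of small
  adenoma) and 3 years (high-risk: large adenoma), standard
  post-polypectomy guidance; surveillance also stops after 75;
- the fraction already screened before 45 is marked initiated at 45
  with a due date uniform within one modality interval;
- each person's origin modality (their status-quo choice) is drawn once:
  85% colonoscopy / 15% FIT by default, configurable — only
  population-level shares (~85%/>10%) are published;
- a missed diagnostic follow-up leaves the person untreated and back in
  routine screening at the next due date;
- false-positive colonoscopy and CTC results incur the procedure's cost
  and disutility but change no disease state.

Test characteristics (sensitivity by lesion class, specificity) are the
published patient-level base-case values; CTC sensitivity for
diminutive adenomas is 0 because sub-6 mm findings are not referred.

## Economics

Limited societal perspective: medical costs plus patient/escort time,
no productivity losses.  Costs and utilities are discounted at 3%/year
to the cohort start age; events are booked at cycle start with no
half-cycle correction; a person alive at the start of a cycle accrues
the full year.  Cancer care is costed in three phases (initial year at
diagnosis, continuing years, terminal year replacing the continuing
year before a CRC death), per common practice in cancer CEA.  The
packaged cost and disutility values are synthetic placeholders of
realistic magnitude — only the CTC procedure cost ($225, the 2024 CMS
rate) is a published number.  The cancer-care phase costs are anchored
so the discounted lifetime cost per no-screening case is ≈$100k, the
magnitude published per-1000 cost and case tables imply; without that
anchor, test-cost-heavy strategies would not show the published
cost-saving property relative to no screening.  QALYs apply an
age-banded baseline utility, one-off decrements per screening/
diagnostic/surveillance/complication event (magnitude × duration folded
into a single QALY loss at the event age), and a per-year stage-graded
decrement from diagnosis to death.  QALYG is a paired difference
against the seed-matched no-screening replay of the identical cohort.

## Cost-effectiveness analysis

Strategies are sorted by ascending cost (ties: higher QALYG first;
exact ties keep input order, the duplicate marked dominated).  Simple
dominance removes rows beaten by a cheaper-or-equal row; extended
dominance then removes frontier points until the ICER sequence strictly
increases.  Both labels are kept distinct so report tables can print
either.  The cost-effective strategy at a WTP is the undominated row
with the largest ICER ≤ WTP (the cheapest undominated row when all
ICERs exceed it); with deterministic outcomes this coincides with the
max-NMB rule, which the tests assert.  A strategy is flagged *dominant*
when it has at least as many QALYG at no higher cost than every
alternative, assessed against all strategies jointly.  PSA samples the
published Beta/PERT distributions (PERT uses λ=4, the standard shape,
rescaled Beta on [min, max]); one master seed spawns per-draw
substreams; each draw runs on one calibrated parameter set, rotating
through the top K (the full design averages each draw over the retained
sets; the rotation is the desk-scale economy).

## Calibration

Free parameters and their search bounds (all log-scaled):
`onset_scale` (0.5–2.0, multiplies the age-banded onset schedule),
`growth_dim_to_small`, `growth_small_to_large` (0.02–0.18),
`large_to_preclinical` (0.02–0.20), `detection_scale` (0.5–2.0,
multiplies the per-stage detection schedule).  Candidates are scored by
weighted mean squared *relative* error — each deviation scaled by the
target's observed value — so incidence-per-100k and proportion targets
are commensurable.  Target families and weights: age-banded incidence
(weight 3), stage distributions in the screening and non-screening eras
(1; the non-screening era is emulated by replaying the same cohort with
screening off), total and size-resolved adenoma prevalence at 50/60/70
(2 and 1), polypectomy size mix (1), and screening-utilization
proportions at 65 (0.5 — these move with adherence, not the disease
candidates).  Evaluations use 20,000-person cohorts with a fixed
simulation seed (common random numbers), making the objective
deterministic.

The adaptive sampler is a tree-structured-Parzen-estimator-style
optimizer: after 25 random start-up trials, evaluated points are split
into good/bad by score (`n_good = min(⌈0.1·n⌉, 25)`), independent
per-dimension Gaussian-kernel densities l(x) and g(x) are fitted, and
the next point is the best of 64 candidates (drawn from l, with a small
uniform exploration slice) by `log l − log g`; every fourth trial
instead perturbs the incumbent best locally (σ = 0.03 in unit space).
A pure-random sampler is the always-available fallback, and the module
has no dependency beyond numpy/pandas.

**Recovery tolerance.** On synthetic targets at 5% relative noise with
a 500-evaluation budget, the documented per-parameter tolerance for the
top-1 recovered set is ±25% for `onset_scale` and ±35% for the three
adenoma-flow rates and `detection_scale`.  The asymmetry reflects
identifiability, not optimizer budget: one-dimensional ±25%
perturbations of any parameter raise the objective several-fold above
the noise floor, but the three flow rates trade off along a joint ridge
(slower early growth can be offset by faster later transformation while
moving prevalence and incidence summaries less than the injected noise).

## Synthetic data

The generator stands in for registry incidence curves and survey
screening-behavior summaries.  `make_truth` draws the free parameters
deterministically from the central half of the search space and
rejection-samples (deterministic sequence) until a pilot no-screening
simulation puts lifetime CRC risk in the design band of 60–90 cases per
1000 (6–9%), the magnitude published no-screening incidence implies;
truth is therefore always interior to the calibration bounds.
`make_targets` simulates a 50,000-person cohort at truth and applies
independent multiplicative lognormal noise (mean-1, relative SD 5% by
default) per target.  What the generator does *not* emulate: registry
microdata, survey weighting, secular trends, birth-cohort effects, or
correlated target errors.  Passing tests therefore demonstrate that the
pipeline recovers parameters and reproduces qualitative orderings under
its own assumptions — not that the packaged rates describe any real
population.

## Problem sizes and numerical conventions

Packaged run sizes: full configuration 500,000-person cohorts, 500
calibration evaluations, top-100 sets, 5,000 PSA draws; the desk preset
(used in examples and the pipeline smoke tests) runs 20,000-person
cohorts, 120 evaluations, top-5 sets, 100 draws, and completes well
inside the pipeline's 15-minute design envelope on one CPU.  The
acceptance checks run 20,000-person strategy cohorts and one
500-evaluation calibration.  Derived-adherence cells are reported in
percent at one decimal using decimal round-half-up on the printed
inputs (binary floats would tip exact half-way cells such as
7.0%×3.45 = 24.15% the wrong way).  Tables are written as
tab-separated text with `%.10g` floats, period decimal separators, and
fixed column order; reruns under the same config and seed are
bit-identical.  Degenerate inputs are rejected with messages (empty
cohorts, unknown groups/strategies, dead persons stepped, probability
out of range, budget below top-k, invalid sensitivity ranges).

## Limitations

- One lesion per person; no serrated pathway, no sigmoidoscopy, no
  molecular subtypes, no treatment-era stage shifts.
- Cost/disutility defaults are placeholders (see above); absolute cost
  and QALY levels are illustrative even though orderings are the tested
  quantity.
- CRC survival is independent of age at diagnosis.
- The status-quo switching probability defaults to 0 pending
  calibration against behavior summaries that identify it.
- Calibration recovery is demonstrated against the generator's own
  model (an inverse-crime design): it validates the machinery, not
  structural correctness against real registries.
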