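# Methods

## Model

`cllburden` is a deterministic state-transition cohort model of chronic
lymphocytic leukemia (CLL) in Canada. Patients move forward-only through
five health states — watchful waiting (WW), first-line treatment,
relapsed/refractory (second-line) treatment, a palliative sub-state
(progressed on second line, not yet dead) and death — in 28-day cycles,
with calendar years attached by the rule *cycle k belongs to year
`start_year + floor(k x 28 / 365.25)`*. The cohort is stratified at
entry by age group (<65, 65–70, >70), fitness, del(17p)/TP53 status and
(among non-del(17p) patients) IGHV mutation status; del(17p) patients
are not split by IGHV because treatment choice branches on del(17p)
first, giving 18 strata. Strata never change after entry.

Incident patients enter at the end of their entry cycle, 85% into WW
and 15% directly into first-line therapy. A 2010–2019 *warm-up* phase
accumulates incident cohorts under the treatment algorithms of that era
to build the prevalent 2020 population; the 2020–2025 *projection* then
runs under one of two treatment-policy scenarios:

* **continuous OTT** — oral targeted therapy (ibrutinib/acalabrutinib)
  taken until progression or discontinuation;
* **fixed OTT** — venetoclax-based fixed-duration combinations
  (VO, 13 cycles, first line; VR, 26 cycles plus a ramp-up charge,
  second line) absorbing the OTT-eligible share from 2021.

### Transition probabilities

Published trial summaries are converted to per-cycle probabilities
under a constant-hazard (exponential) assumption:

    median m months:            p = 1 − 0.5^(28 / (m × 30.4375))
    survival S at t years:      p = 1 − S^(28 / (t × 365.25))
    annual probability p_a:     p = 1 − (1 − p_a)^(28 / 365.25)

with a 30.4375-day month (365.25/12) for consistency with the cycle
grid. Subgroup summaries take precedence over pooled ones in the order
del(17p), then IGHV status, then age. PFS drives progression out of a
treatment line (first line → second-line assignment; second line →
palliative); the OS of the last second-line regimen drives palliative
death; pooled all-cause background mortality (0.695% per cycle) applies
to WW, first-line and responding second-line patients.

### Within-cycle event order

The published description does not fix an order, so one is fixed,
documented, and mirrored exactly in the micro-simulation oracle:
(1) background death; (2) WW → first-line initiation (1.65%/cycle,
calibrated); (3) progression at the PFS-derived rate, on or off drug;
(4) OTT discontinuation (0.70%/1.40% per cycle, first/second line);
(5) palliative death; (6) tunnel advance, with course completers moving
off drug; incident entrants arrive last and face their first risks the
following cycle. Risks are sequential (each applies to the survivors of
the previous), so e.g. 1000 WW patients yield 6.95 deaths and
0.0165 × 993.05 = 16.39 treatment starts in one cycle. No half-cycle
correction is applied.

### Discontinuation destination

Discontinuation is modelled as the point where drug-cost accrual stops,
not as a health-state transition: discontinuers stay in their line in
an off-drug pool, keep progressing at the trial PFS rate, and keep
facing background mortality. This follows the source description, which
lists discontinuation only among the cost rules and derives all state
transitions from PFS/OS and all-cause mortality; it also keeps the two
scenarios' prevalence trajectories close, as reported. The alternative
reading — discontinuation as line exit — is available as the
`discontinue_destination="next_line"` option. Fixed-duration completers
are treated the same way: off drug, retaining the trial PFS (which
spans post-treatment follow-up) until progression.

### Costing

All costs are 2020 Canadian dollars, undiscounted, accrued per cycle
and aggregated to calendar years by the cycle-to-year rule, keyed by
line (first / second / other) and category:

* **drug** — the regimen's cycle-indexed schedule (tunnel states track
  cycles-on-treatment); continuous regimens have a constant open-ended
  tail; the VR ramp-up charge (C$3,773) lands in the first on-treatment
  cycle; a new line's cycle-1 cost is charged in the transition cycle.
* **administration** — C$105.15 per infusion plus 30 nurse-minutes at
  C$0.63/min, and 15 pharmacist-minutes at C$0.87/min per on-drug cycle.
* **monitoring** — one full laboratory panel (electrolyte + renal +
  liver + CBC = C$67.29) per on-treatment cycle, half that frequency in
  WW and off-drug follow-up; quarterly partial assessments (C$38.05);
  one hematology consultation (C$157) per treatment initiation. The
  published sources give unit costs but not frequencies; these defaults
  are configuration (`MonitoringSchedule`) chosen as typical oncology
  follow-up intensity.
* **adverse events** — the expected grade-3/4 management cost
  (Σ incidence × unit cost) charged once per course initiation; trial
  AE rates are course-level incidences, so per-cycle charging would
  inflate costs with duration (available as `ae_cost_basis="per_cycle"`).
* **palliative care** — a one-time C$9,326 charge on palliative entry
  (a per-stay estimate, not a per-cycle cost).

WW monitoring and palliative care are reported under the "other" line.

### Treatment algorithms

The published figure gives the menu of regimens per stratum and year
but not the percentage mix, so the shipped policies are reconstructed
from the Canadian reimbursement timeline (ibrutinib: second line 2015,
first-line high-risk 2016–2018; acalabrutinib 2019; VR 2020; VO late
2021) with deterministic stratum→regimen assignment and one mixed rule
in second line (80/20 with acalabrutinib). They are first-class
configuration, labelled reconstructed, not verbatim. Both scenarios
share the 2010–2019 rules; VR uptake is modelled from 2021 so the two
scenarios' 2020 rules — and 2020 costs — coincide, matching the
reported near-identical 2020 starting costs. del(17p) patients stay on
BTK inhibition in both scenarios (VO's del(17p) PFS is materially
worse). A validator checks share sums, registry coverage and
availability years over the full (year × line × stratum) grid.

## Calibration

The original model was calibrated with a spreadsheet solver; here the
same step minimizes Σ wᵢ ((modelᵢ − targetᵢ)/targetᵢ)² over a named
subset of {WW→treatment, discontinuation (×2), background death}
probabilities with bounded Nelder–Mead (gradient-based refinement
optional), evaluated against warm-up observables only (prevalence at a
year, on-drug share, deaths in a year). Relative error keeps counts and
proportions commensurable. The fit is deterministic (fixed start, no
restarts); non-convergence returns the best point found, flagged.
Recovery experiments with noise-free synthetic targets recover a
displaced WW→treatment probability to well under 5% and a joint
two-parameter displacement to under 10%.

## Synthetic data

External inputs the original analysis consumed but did not print are
emulated: the incidence series is geometric growth with optional
multiplicative lognormal noise (unit median, configurable CV);
calibration targets are generated from the model's own warm-up
observables at known parameters (the basis of the recovery
experiments). The defaults — 2000 incident cases in 2010 growing
2%/year, noise-free — were fixed once so the warm-up yields a 2020
prevalence near the reported 15,512 (scripts/tune_incidence.py shows
the scan; the shipped value is the nearest round number). These
defaults emulate scale and trend only: real incidence has age-period
structure, and real calibration targets carry sampling error, so
passing tests show internal consistency, not agreement with Canadian
registry data.

## Validation oracle

An individual-level Monte-Carlo simulator implements the identical
pathway rules independently of the cohort engine's matrix algebra:
each patient draws Bernoulli events per cycle in the same order, from a
fixed per-patient block of uniforms (4 entry draws + 4 per cycle) laid
out in fixed 50,000-patient chunks of one seeded PCG64 stream, so
earlier patients' histories are invariant to cohort size. On five small
configurations (one or two regimens per line, 3-year horizon), every
annual state occupancy and per-line/per-category cost from the cohort
engine lies within 3 Monte-Carlo standard errors of the simulator at
n = 200,000.

## Sensitivity analysis

One-way sensitivity analysis varies each non-calibrated cost and
probability — unit costs, per-regimen drug-cost scales, WW-at-diagnosis
and marker prevalences — to 75%/125% of baseline (probabilities clipped
to [0, 1] with a logged warning), recomputing the cumulative 2020–2025
fixed-minus-continuous cost difference with both scenarios at each
bound. PFS/OS and the calibrated probabilities are excluded, as they
were set by calibration. Rows sort by bar width, ties alphabetically;
the tornado CSV is the artifact, the plot a convenience. With the
shipped defaults the ibrutinib drug-cost bar is the widest drug-cost
bar, reflecting its continuous-tail exposure in both lines.

## Numerical choices and problem sizes

Counts are double-precision expectations; mass conservation
(alive + dead = entrants, relative 1e-9) is asserted every cycle. The
tunnel dimension is capped at 40 cycles with pooling at the cap
(continuous regimens have constant tail costs, so pooling is exact;
the cap exceeds the longest finite course, 26 cycles). The default
horizon is 131 warm-up + 79 projection cycles; a full two-scenario run
takes well under a second, the oracle comparison about ten seconds, and
the full sensitivity sweep a few seconds, so the entire test suite runs
in well under a minute of compute.

## Known limitations

* No third-line therapy or retreatment after fixed-duration relapse;
  palliative is absorbing except for death.
* Stratum fixed at entry (no acquired del(17p) at relapse).
* Exponential hazards between published summary points; real PFS/OS
  curves are not exponential, so per-cycle rates are approximations.
* OS measured from treatment start is applied as the palliative death
  rate; under non-exponential true hazards this understates
  post-progression mortality.
* Treatment-mix shares, monitoring frequencies and the incidence series
  are reconstructions/configuration, not published data; absolute cost
  levels should be read as internally consistent projections, not
  national estimates.
* The two scenarios' prevalence trajectories differ by ~0.5% by 2025
  because the fixed-duration regimens' published efficacy genuinely
  exceeds the continuous comparators'; the model makes no attempt to
  force them closer.
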