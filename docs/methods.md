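# Methods

## Model structure

Five-state Markov cohort model (well, mild, moderate, severe, dead; dead
absorbing) in monthly cycles over a 60-cycle horizon. The cohort enters
entirely in *mild*. Cycle values are computed on end-of-cycle occupancy; a
half-cycle correction (averaging start and end occupancy for state-dependent
costs and QALYs) is available but off by default — the comparison between
arms is differential and the correction cancels almost exactly.

### Programme phase

The low-intensity CBT programme occupies the first `phase_cycles` cycles
(default 3, ≈ the 9–12-week course the guideline recommends; configurable).
During the phase the cohort is held in *mild* apart from background
mortality. The programme's recovery and deterioration probabilities are
programme-level outcomes that already summarise within-programme change;
applying monthly transitions concurrently would double-count movement. At
the end of the phase the surviving cohort is split over
(well, mild, moderate, severe) as a two-stratum mixture:

* **effective** (accepted × adhered): recovery 0.639, deterioration 0.053
  (i-CBT multiplies both by its relative differences, default 1.00);
* **non-effective** (declined or dropped out, pooled): recovery 0.25,
  deterioration 0.174 (no-intervention rates).

Uptake enters the state dynamics only through the product
`p_accept × p_adhere`. A direct consequence — verified numerically and used
as a test oracle — is that the incremental QALY crosses zero exactly where
the products coincide: at a relative acceptance of 1/0.99 ≈ 1.0101 and a
relative adherence of 1/1.19 ≈ 0.8403.

Deteriorating mass is split moderate:severe in proportion to the background
mild→moderate and mild→severe probabilities (0.73 : 0.67 ≈ 0.521 : 0.479);
an `all_moderate` alternative is provided. When both background
probabilities are zero the split defaults to moderate.

### Escalation

Survivors not in *well* at phase end are charged one high-intensity
face-to-face course (US$728) — a cost event only; subsequent care effects
are taken to be embodied in the post-programme transition matrix. The
default recipients are **all** non-well survivors: the programme description
("students who did not improve were advanced to high-intensity CBT") does
not restrict escalation to accepters, and the two-way acceptance/adherence
frontier reproduces the published 1.13 value only under this reading
(restricting to accepters shifts the frontier to ≈1.16). The
`accepters_not_well` alternative remains available.

### Transitions and mortality

The published monthly morbidity probabilities are used verbatim. Monthly
all-cause mortality (2.5e-5) enters each alive row, multiplied by the
anxiety mortality rate ratio (1.66) in the mild/moderate/severe states (not
in *well*, which represents remission); the stay probability absorbs the
remainder rather than rescaling morbidity entries — at ~4e-5/month the
competing-risk distortion is negligible. `matrix_root` converts multi-month
matrices to the monthly cycle by eigendecomposition with principal roots;
entries in (−1e-8, 0) arising from numerical noise are clipped and rows
renormalised, and anything worse (negative real eigenvalues, defective
bases, complex residues above 1e-8, reconstruction error above 1e-8) raises
an explicit no-stochastic-root error. Since only already-converted monthly
probabilities are published, the root is validated by its self-inverse
property on embeddable matrices, not against an external conversion.

## Economics

All values are discounted to model entry at 3%/year,
`d(c) = 1.03^(−c/12)`. QALYs per cycle are occupancy-weighted age-adjusted
utilities divided by 12, with `u(state) = 0.92 × u_state`. Direct medical
cost per cycle: psychiatric outpatient care (US$220/month) for occupancy of
the configured states (default moderate + severe — resource use was
estimated from students receiving psychiatric consultation, which we read as
actively symptomatic care; a switch adds mild), plus expected
hospitalisation among the severe (probability × episode cost), plus course
fees. Course fees are acceptance-weighted, spread evenly over the phase
cycles and discounted per cycle (charging undiscounted at entry differs by
<1%); accepters pay in full by default (`half` prorates drop-outs). The
cheaper i-CBT course is `platform + 0.22 × f-CBT course` = US$64.76.
Indirect cost applies the friction-cost approach: the employed fraction
(participation × (1 − unemployment) = 0.317) loses the student wage × 56
hours in every moderate/severe month; the friction period is the full
duration of those states.

Comparison: dominance when the cost and QALY increments disagree in sign;
otherwise ICER = ΔC/ΔE against the WTP threshold; `INMB = λΔE − ΔC`. With a
zero QALY increment the classification follows the cost sign and the ICER is
undefined. For two strategies the "preferred" rule used in the two-way grid
and the CEAC reduces to `INMB > 0`, ties to the comparator.

## Sensitivity analyses

* **One-way**: each input swept over its declared range (the published 95%
  CI / high–low values; inputs without a published range carry ±20%
  triangular ranges); endpoint comparisons reported, and any sign change in
  the incremental QALY located by bisection (interval tolerance 1e-6, well
  below the 4-decimal reporting precision). Degenerate (fixed) inputs are
  flagged, not swept. Cost-only inputs provably cannot move the QALY
  increment; the tests assert this to 1e-15.
* **Two-way**: grid classification of the preferred strategy plus a per-row
  INMB-root frontier.
* **PSA**: every input drawn independently — beta via method of moments with
  `sd = range/3.92` (the fitted mean equals the base value exactly; an
  infeasible fit falls back to triangular with a logged warning), triangular
  with mode at the base value, fixed inputs untouched. Probability caps are
  applied after ratio multiplication, and a sampled row whose off-diagonal
  sum reaches 1 is rescaled proportionally and counted. Mean increments are
  reported with normal-approximation CIs of the mean (`SE = sd/√n`, matching
  the very narrow published intervals at n = 10,000). The CEAC is evaluated
  on a WTP grid from 0 to 3× GDP per capita in steps of 2,000 plus the exact
  1×/2×/3× anchors.

## Validation by microsimulation

`simulate_individuals` replays the identical process at the individual
level: Bernoulli acceptance/adherence, categorical phase outcome by stratum,
categorical monthly transitions, Bernoulli hospitalisation events (the
cohort engine uses the expectation), per-individual escalation and course
fees. One uniform-variate matrix per run, drawn row-major from a seeded
generator, gives each individual a private stream, so the first *m*
individuals are identical whatever the sample size. At n = 200,000 the
sample means agree with the cohort engine within 3 standard errors for
costs, QALYs, and occupancy at cycles 3, 12 and 60 — this is the package's
independent oracle for the cohort engine. `generate_random_scenario`
supplies valid random input sets and structural switches for fuzzing the
structural invariants (row-stochasticity, occupancy conservation, monotone
dead fraction).

What the synthetic machinery does *not* emulate: real students are
heterogeneous in uptake and prognosis, transition probabilities drift with
time and treatment history, and costs are lumpier than monthly expectations.
Passing tests show internal consistency of the decision model, not external
validity of its inputs.

## Numerical and design notes

* Problem sizes: 60 cycles; PSA 10,000 draws (≈15 s); two-way grids 50×50;
  microsimulation 200,000 individuals (≈2 s). Bisection: 1e-6 interval.
* `age_years` only labels the cohort; the age-specific utility (0.92) is a
  single constant over the 5-year horizon.
* Currency is US$ throughout (inputs were converted upstream at US$1 =
  HK$7.8); no inflation adjustment.
* The psychiatric outpatient cost range (185–348) is asymmetric around the
  base 220 (a median of reimbursement records); the triangular mode is kept
  at 220 with those bounds.
* Cumulative *well* occupancy is **not** monotone in the deterioration
  probability: under the published matrix the moderate and severe states
  recover to well faster per month (4.5%, 3.9%) than mild does (2.4%), so
  pushing cohort mass out of mild can raise long-run well time while still
  lowering QALYs. Property tests therefore assert QALY monotonicity.

## Known limitations

* **Absolute levels**: with the published inputs taken verbatim, the model's
  absolute QALYs (≈2.84 per arm) and total costs (≈US$3.9–4.1k) sit below
  the published per-arm figures (≈2.99 QALYs, ≈US$6.1–6.2k). These levels
  are over-determined: the published transition matrix fixes steady-state
  occupancy (well ≈0.54, mild ≈0.29, moderate+severe ≈0.18), which caps the
  achievable time-average utility at ≈0.61 — below what the published QALYs
  require (≈0.645) — while simultaneously matching the published indirect
  cost closely. No setting of the structural switches closes that gap
  (adding mild to the outpatient states overshoots total costs by ≈20% and
  degrades every incremental quantity). The *incremental* results — the
  decision-relevant layer — are robust: dominance, threshold values,
  frontier, CEAC probabilities and PSA mean increments all reproduce well.
* No treatment re-entry, no time-varying mortality over the 5-year horizon,
  no correlation between sampled inputs, no EVPI.
* One hospitalisation probability applies only to the severe state; inpatient
  costs for moderate cases are not modelled separately.
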