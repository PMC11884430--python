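# Methods

This note records the model as implemented: its assumptions, the
conventions chosen where the design was genuinely open, the synthetic
data's relationship to real inputs, and the numerical choices that affect
reproducibility. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Cohort model

**States and time.** Six visual-acuity health states per eye, defined on
ETDRS letters (>85, 85–71, 70–56, 55–41, 40–26, ≤25), indexed 0 (best)
to 5 (worst). Time advances in 4-week cycles, 13 per year, over a
25-year horizon (configurable). All "monthly" rates are applied once per
4-week cycle; keeping 13 cycles per year puts every year boundary on a
whole cycle.

**Sign convention.** Clinical movement rules are phrased as vision
*gains*; in index space a one-category gain is an index shift of −1. The
conversion is made exactly once (`Phase.allowed_index_shifts`); matrices
are validated against the index-shift mask, with off-grid movements
truncated to the nearest edge state. Letter changes map to category
movements through fixed thresholds: >+22.5 letters → +2 states,
(+7.5, +22.5] → +1, [−7.5, +7.5] → 0, and symmetrically for losses.

**Phases.** Cycles 1–13 are the loading phase (gains of up to 2 states,
losses of 1; matrices may be stratified by the eye's baseline state),
cycles 14–26 the stabilisation phase (±1), and cycles ≥27 maintenance
(decline-only: 0, −1, −2 in vision terms). During the loading phase the
engine propagates one sub-distribution per baseline stratum so that
stratified matrices act on the mass that actually started in each
stratum; afterwards the marginal suffices because transitions no longer
condition on baseline.

**Two eyes.** The first (index) eye starts from the baseline VA
distribution. The second eye starts unaffected; at cycle 1 the baseline
bilateral share converts, and each later cycle the per-cycle incidence
erodes the remaining unaffected pool (DME: 46.5% baseline, 0.8%/cycle;
nAMD: 7.3%, 1.4%/cycle in the bundled defaults). Converted mass enters
the affected states per the second-eye baseline distribution, treated as
its baseline stratum. The affected second eye follows the same matrices
as the first eye, phase-aligned to calendar time, not to its own onset —
the alternative (restarting the loading phase at onset) would make the
engine an individual-history model rather than a cohort model. The two
eyes are propagated as independent marginals; person-level quantities
couple them as a product distribution.

**Event order within a cycle.** Record state and injections at cycle
start, then: transitions → second-eye incidence → mortality →
discontinuation. The order is fixed and shared verbatim by the
microsimulation; note that the baseline bilateral conversion therefore
first appears in the cycle-2 record, so first-cycle injections and costs
cover the first eye only.

**Discontinuation and natural history.** At the first cycle of year 6
(cycle 66) the discontinuation fraction (default 85%) of on-treatment
mass moves off treatment, once. Discontinued mass accrues no drug,
administration or monitoring costs and follows a designated
natural-history matrix — by default the treatment's own maintenance
(year-3+) matrix, configurable via the scenario file. The engine tracks
on- and off-treatment sub-distributions separately; collapsing them to a
single marginal would silently bias results whenever natural history
differs from on-treatment dynamics.

**Mortality.** The published model family does not describe background
mortality; it is included as an optional absorbing death state with a
constant annual probability (default 0), converted per cycle as
1−(1−p)^(1/13), applied identically across arms so comparisons are
unaffected at the default.

## Outcomes

**Utility.** A person's per-cycle utility is the utility of the
better-seeing eye (the minimum state index), with the two eyes coupled
independently. An *unaffected* fellow eye counts as best-state vision —
a fellow eye without retinal disease is assumed to see well, the
convention of published bilateral models; consequently unilateral
disease carries little utility burden until the second eye converts,
which is precisely why bilateral incidence matters in this model family.
Cycle QALYs are utility × 4/52 years minus a per-injection disutility.
The published inputs list the injection disutility only as a percentage
with no absolute value, so the default decrement is 0 and the field is
user-configurable.

**Costs.** Four components per cycle: drug = injections × unit price
(both eyes pay full price); administration = first-eye injections ×
(procedure + monitoring) plus second-eye injections × a configurable
share of the same (both eyes are treated in one visit; default share
0.5); supportive care = annual cost × mass whose better-seeing eye is at
or past the threshold state (a person needs low-vision aids only when
the better eye is impaired), spread over 13 cycles; adverse events = a
per-cycle cost on all alive mass, identical across arms.

**Discounting.** Factor (1+r)^(−(cycle−1)/13); cycle 1 is undiscounted
and flows are costed at cycle start. No half-cycle correction by default
— this makes constant flows match the geometric series exactly, which
the tests exploit as a closed-form oracle; a half-cycle option exists in
the settings. Effects and costs use separate rates (both default 5%/yr).

## Sensitivity analyses

**Deterministic.** One-way bounds per parameter: ±10% for drug
acquisition costs; a reported 95% CI when available; otherwise the
30th/70th percentiles of the parameter's PSA distribution (the "30th and
70th percentile of the point estimate" rule is not a defined statistical
object; percentiles of the assigned distribution are the interpretation
used here, and the rule column of the tornado table says which applied).
Output is the intervention-vs-comparator net monetary benefit, rows
sorted by swing.

**Probabilistic.** Beta distributions for proportions, gamma for costs,
normal for the rest, moment-matched so each distribution's mean equals
the base value and its sd is cv × mean (beta infeasibilities shrink the
cv for that parameter and are logged). Stochastic matrices have no
standard "normal" perturbation; rows are jittered multiplicatively on
the log scale over their non-zero cells and renormalised, which keeps
them row-stochastic and phase-legal by construction. Each draw is keyed
by (seed, draw index), so draws are reproducible and shared across
treatments (common random numbers); draws failing validation are
re-sampled with a counter rather than clamped, to avoid biasing the
distributions. Dominance probability counts draws where the intervention
is strictly cheaper and strictly more effective; the acceptability curve
takes the highest-NMB arm per draw per λ, splitting ties equally.

## Budget impact

Eligible persons = base population × the product of funnel fractions.
Without the entrant, base-year market shares are frozen; with it, the
entrant gains a fixed share per post-base year (capped at 1), incumbents
losing in proportion to their current shares (configurable displacement
weights). Per-patient annual costs reuse the cost engine in year-1 mode
(incident-style costing), with bilateral patients injected in both eyes
and the second eye charged the visit share. Budgets are computed at full
precision; cumulative cells sum unrounded post-base years. The eligible
population may grow at a configurable annual rate (default 0). Base-year
market shares are scenario inputs — published applications do not print
them — and headline head-count totals are likewise consumed as inputs,
not re-derived from demographic denominators.

## Synthetic scenarios

The generator emulates the *structure* of real inputs, not their values:
loading-phase matrices are built by discretising a normal letter-change
distribution (per-cycle mean = annual improvement/13, sd 12 letters — a
typical trial-level BCVA dispersion) through the category thresholds,
with per-stratum means increasing toward worse baseline vision (ceiling
effect) and forbidden movements folded onto the nearest permitted one;
stabilisation uses a zero-mean, narrower distribution; maintenance a
small negative drift with gains folded into stability. Utilities
decrease strictly from a configurable anchor (default 0.85) with gaps of
0.03–0.07. The intervention shares drug prices with comparators but
needs fewer injections (default gap 2/year) and has the strongest
loading-phase gains, reproducing the dominance mechanism qualitatively.
What passing tests on such scenarios shows is that the *accounting and
propagation machinery* is correct and that the dominance mechanism
follows from its premises — not that any real treatment is dominant;
matrices estimated from trial data, real utilities and real prices must
be supplied through the scenario file for substantive conclusions.

## Validation choices

The cohort engine's correctness oracle is an individual-level
microsimulation sharing only the parameter set and the event order, not
the propagation code. Agreement is scored per occupancy cell in binomial
standard errors with a 1/n discreteness floor. Because one comparison
spans ~5000 correlated cells, the pass threshold is the Šidák bound at
family-wise level 0.01 over all cells (≈4.75 SE at that count, never
below 3 SE): a per-cell 3-SE rule would reject an exact engine about
half the time on max-z grounds alone, while genuine engine defects
compound over 325 cycles and overshoot the corrected bound by an order
of magnitude. The uncorrected mode remains available.

Problem sizes used by the default suite and acceptance script: 100 000
walkers for the microsimulation check, 1000 PSA draws on a 2-treatment
scenario with a 50-point λ grid, 40 000-walker/3-year runs in unit
tests — sizes at which binomial standard errors are small enough to
resolve the quantities being checked.

## Known limitations

* No treatment switching, no individual heterogeneity beyond the
  validation microsimulation, no age-dependent utility beyond an
  optional linear coefficient, no indirect/societal costs.
* The unaffected-fellow-eye convention pins unilateral utility to the
  best state; models with measured fellow-eye acuity would differ.
* Second-eye dynamics are phase-aligned to calendar time (see above).
* BIA costing uses year-1 schedules for all prevalent patients; a
  prevalence mix of treatment years would lower per-patient costs.
* No currency conversion: money fields carry a currency tag only.
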