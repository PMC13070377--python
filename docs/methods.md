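# Methods

This note records the models implemented in `besurv`, the assumptions
behind them, and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Person-time statistics

Progression to high-grade dysplasia (HGD) or esophageal adenocarcinoma
(EAC) is summarised as events per 100 person-years. With k events over PY
person-years the rate is 100·k/PY and its 95% CI uses the exact Garwood
bounds, lower χ²(α/2, 2k)/2 and upper χ²(1−α/2, 2k+2)/2, scaled by
100/PY, with a zero lower bound at k = 0. The incidence rate ratio of
group 1 against reference group 0 conditions on the total event count:
k₁ | (k₁+k₀) is binomial with p = IRR·PY₁/(IRR·PY₁+PY₀); a
Clopper–Pearson interval for p maps to IRR bounds via p/(1−p)·PY₀/PY₁.
Exact methods were chosen because both reproduce the published group CIs
at these event counts, where normal approximations visibly do not (the
log-normal rate interval and the Wald log-IRR interval each miss at
least one printed bound). A reference group with zero events yields an
infinite upper bound, which is flagged (`unbounded_upper`), not raised.

Reported tables round half-up to one decimal (`render_report`); all
computation is done unrounded. Pooled person-years are the sum of the
unrounded group values, so a pooled figure can differ by one unit from
the sum of independently rounded group figures.

## Synthetic cohort

The generator emulates a three-group surveillance cohort of 727/97/90
patients. Per patient it draws an administrative censoring time C from a
gamma distribution moment-matched to the group's observed follow-up mean
and SD (5.3±4.4, 7.2±5.8, 7.1±5.0 years), truncated to the 21-year
program window, and an exponential progression time T at the group
hazard (0.006457, 0.010014, 0.021807 per year — the observed group
rates). Exposure is min(T, C) and an event occurs when T ≤ C. Event
types split HGD/EAC at the observed multinomial fractions (10/25, 1/7,
5/14 EAC); LGD patients receive a course label (reverted 0.690,
back-and-forth 0.198, persistent 0.112), and surveillance-detected LGD a
time-to-LGD from a gamma matched to 3.6±3.1 years. Constant hazards are
the minimal model consistent with per-100-person-year reporting; the
generator does not model endoscopy scheduling, biopsy sampling error or
pathologist disagreement, so passing tests demonstrate correct recovery
of aggregate rates, not robustness to those real-data features. One
top-level seed spawns per-group child streams, so output is reproducible
and byte-identical across runs.

## Markov cohort model

States: three non-dysplastic Barrett's tunnel states encoding the
surveillance interval (6, 12, 24 months — the interval lengthens after a
clean endoscopy and resets on recurrence), LGD, HGD, EAC at T1a, advanced
EAC, post-RFA, post-EMR+RFA, cancer death, other-cause death. The tunnel
states exist because the surveillance policy is history-dependent and
cannot otherwise be expressed in a memoryless chain. Cycle length 0.5
years, horizon 35 years (70 cycles), discrete discounting at
(1.05)^(−t·0.5) applied identically to costs and QALYs.

LGD origin (index endoscopy vs during surveillance) determines both the
progression hazard and whether an ablation strategy triggers, so the
engine runs each origin as its own subcohort starting 100% in LGD and
mixes outcomes 52%/48% (the base-case origin split). This is equivalent
to origin-tagged state copies but keeps each matrix 11×11. Recurrent LGD
in a patient keeps the patient's origin, since the strategies are defined
by patient group.

Annual rates convert to per-cycle probabilities as p = 1 − exp(−r·Δt).
Competing outflows that a sensitivity draw pushes past total probability
1 are rescaled to sum to 1 and logged (an audit entry), never silently
truncated. Payoff conventions: state costs (endoscopy amortised over the
surveillance interval: a 12-monthly state accrues half an endoscopy per
6-month cycle) and utilities accrue on start-of-cycle occupancy; event
payoffs (RFA and EMR procedure costs, one-off disutilities, expected
complication cost/disutility, the advanced-cancer care bundle on entry)
accrue on within-cycle transition flow; both discount at the cycle-start
index; no half-cycle correction. Cumulative EAC incidence counts
undiscounted flow into the two cancer states from non-cancer sources, so
post-resection recurrence is not double-counted. Background other-cause
mortality is a constant annual rate (default 0.0088, approximating an
Australian adult in the cohort's early-60s mean age); age-varying life
tables are out of scope for the shipped configuration.

Strategies differ only in the LGD row: when a strategy ablates an
origin's LGD, that row routes to post-RFA (less background mortality)
with the RFA event payoffs; otherwise LGD stays under 6-monthly
surveillance with competing progression and reversion. All strategies
ablate detected HGD and treat T1a EAC with EMR+RFA. Post-ablation states
carry a recurrence rate back to LGD and a small residual direct
progression rate — without the latter, an ablate-all policy would
(implausibly) eliminate cancer entirely because recurrent LGD is
instantly re-ablated.

### Parameter provenance

Every parameter is tagged `study-observed` (printed cohort counts),
`study-calibrated` (fitted as below) or `placeholder`. Placeholders cover
all costs, utilities, disutilities and the downstream cancer-pathway
probabilities (HGD detection/progression, T1a detection/progression/
mortality, advanced-EAC mortality, post-ablation recurrence, RFA
complications, background mortality). Their values are of realistic
Australian-health-system magnitude but are stand-ins awaiting source
data; `load_spec` emits a warning naming each placeholder so no run can
depend on them silently. Economic outputs under placeholders
characterise the shipped configuration, not any published analysis.

## Calibration

Targets: group progression rates 1.0 and 2.2 per 100 person-years,
pooled LGD-course proportions 0.690/0.198/0.112, and the EAC share of
progressions per group, over a 187-patient LGD cohort followed for its
observed mean of 1341/187 ≈ 7.2 years (14 cycles). Course categories are
history-dependent, so calibration runs on an expanded chain whose states
carry LGD history (never reverted / reverted / recurrent, with
progression absorbing states split by history at progression). Model
person-time accrues on start-of-cycle occupancy of transient states, so
a progressor's final cycle counts in full; the person-time convention is
internal to the model and the calibration makes the model's rate match
the observed rate under it.

The objective is the weighted sum of squared relative deviations, which
puts rates and proportions on one scale. The optimiser is staged: seven
ordered stages from best- to least-identified parameter (surveillance
progression, index progression, reversion, recurrence/persistence split,
EAC split, post-ablation recurrence, background-mortality cross-check),
each freeing its parameters and matching its targets by bounded
Nelder–Mead from the incumbent, cycling until the global objective is
stationary (tolerance 1e-8, max 25 cycles). The last two stages free
nothing — those quantities are not identifiable from a cohort in which
no patient was ablated — and are logged as skipped rather than silently
dropped. Because stages interact, the cycle can stall a few percent from
the optimum, so a final joint bounded minimisation over all freed
parameters polishes the result. `converged` requires each target matched
to about 1% relative error (objective ≤ 1e-4 per target); an infeasible
target therefore returns `converged=False` with parameters pinned at
their bounds. The procedure is deterministic; the `seed` argument exists
only for manifest bookkeeping.

## Economic evaluation

ICER = Δcost/ΔQALY with dominance labels (`dominated`, `dominant`,
`equivalent`) instead of meaningless ratios; NMB = Q·λ − C with the
willingness-to-pay default λ = AU$50,000/QALY. Two comparison modes:
against the surveillance baseline (default, matching how such analyses
are usually tabulated) and the sequential efficiency frontier, which
removes dominated strategies, enforces increasing sequential ICERs
(extended dominance), and flags the NMB-optimal choice.

## Sensitivity analysis

One-way analysis re-runs a strategy pair at the ends of a parameter
range (default ±40% of the base value, i.e. mean ± 2 SE at the default
20% relative SE; clipped to validity with a warning) and ranks
parameters by ICER swing. Threshold finding brackets the λ-crossing and
solves by Brent bisection; a bracket with no sign change returns a
no-crossing result rather than raising, since the question "does any
plausible value flip the decision" legitimately has the answer "no".

The PSA draws every uncertain input independently — gamma for costs and
rates, beta for probabilities and utilities, hyper-parameters by method
of moments from (mean, SE); no correlation structure is imposed because
none is specified by the source material. Default SE is 20% of the mean
(capped below the beta feasibility bound). Draw i uses the substream
`SeedSequence(seed, spawn_key=(i,))`, so increasing the number of draws
extends rather than reshuffles the sample. Acceptability curves evaluate
NMB per draw on a λ grid (default 0–100,000 in steps of 1,000); exact
NMB ties split the win equally, so fractions sum to 1 by construction.

## Problem sizes and numerical notes

The default suite runs the cohort engine over 70 cycles of an 11-state
matrix (milliseconds per strategy). The microsimulation oracle uses 1e5
individuals; calibration parameter recovery uses 20 random ground-truth
sets; the PSA convergence check uses 5000 draws restricted to linearly
entering inputs (costs, utilities), for which the PSA mean is an
unbiased estimate of the deterministic point — probability inputs enter
nonlinearly and would confound a mean-convergence check with
transformation bias. Row-stochasticity is validated to 1e-9; occupancy
conservation to 1e-9; the rate↔probability round-trip holds to 1e-12.

## Known limitations

- Costs/utilities and downstream cancer-pathway probabilities ship as
  documented placeholders (above); absolute economic outputs change once
  sourced values are loaded, though the machinery and the calibrated
  natural history do not.
- Background mortality is age-constant; no life-table ageing.
- Advanced-cancer care is a payoff bundle, not a treatment sub-model.
- The cohort statistics take the printed group totals as exact; no
  patient-level reanalysis (Cox regression, Kaplan–Meier) is in scope.
- PSA draws are independent across parameters.
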