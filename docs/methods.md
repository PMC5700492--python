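# Methods

## Scope and question

`wmcea` implements a decision-analytic Markov cohort model that
estimates the cost-effectiveness of single-agent ibrutinib versus the
current therapeutic pathway (CTP — a mix of six chemo-immunotherapy
regimens: FCR, BOR, RCHOP, BDR, DRC, BR) in relapsed/refractory
Waldenström macroglobulinemia, from the perspective of the Italian
National Health Service. Effectiveness is measured in life-years
gained (LYG), not QALYs; the headline output is the incremental
cost-effectiveness ratio ΔC/ΔE in €/LYG, judged against a
willingness-to-pay threshold of €60,000/LYG.

## Model structure

Five mutually exclusive health states: initial treatment, first
subsequent treatment, second subsequent treatment, best supportive
care (BSC), and death (absorbing). The cohort (age 65 at entry, 75 kg,
1.8 m² body surface) starts in initial treatment and is propagated in
4-week cycles — exactly 13 per year so that year boundaries fall on
cycle boundaries; the 15-year base-case horizon is 195 cycles.

Progression out of the initial state follows a parametric
time-to-progression curve: Weibull S(t) = exp(−(t/λ)^k) for the
ibrutinib arm, with the CTP curve derived under proportional hazards
from the hazard ratio HR = 0.25 (95% CI 0.11–0.57), i.e.
S_CTP = S_ibr^(1/HR). For a Weibull base this is again a Weibull with
scale λ·HR^(1/k). A log-logistic projection (S = 1/(1+(t/λ)^k)) is
available as a scenario; its parameters are anchored to the base-case
Weibull at t = 1 and 3 years because the alternative projection's own
parameters are not published.

Within a cycle, death and progression compete: the death probability q
is applied first, progression p is resolved among survivors. Of the
progressors, 70% move to the next treatment line and 30% directly to
BSC (the published post-progression pathway shares sum to 70%).
Subsequent lines are memoryless with constant per-line exit hazards;
exits split 70/30 again from line 1, and line 2 exits go to BSC. No
tunnel states are used.

Mortality: pre-progression mortality on ibrutinib equals
general-population mortality (the published assumption); the CTP arm
carries a calibrated pre-progression excess hazard, and BSC carries a
calibrated excess hazard on top of the life table. The life table is
synthetic — a Gompertz–Makeham annual probability
q(a) = 2·10⁻⁴ + 3·10⁻⁵·e^(0.09a), giving q(65) ≈ 1.1% and
q(85) ≈ 6.3%, in line with recent Italian general-population
magnitudes — because no specific life table is named in the source
analysis.

Life years count state membership at cycle start (no half-cycle
correction; the choice is isolated in `life_years` and can be
flipped). Both effect and cost streams discount at 3%/year as
(1+r)^(−kΔ), independently configurable.

## Costing (activity-based)

All prices are ex-factory drug unit prices and national DRG/outpatient
tariffs. IV doses are rounded up to whole vials per administration
(e.g. rituximab 375 mg/m² × 1.8 m² = 675 mg → 7 × 100 mg vials); oral
drugs are costed per capsule-day (ibrutinib 420 mg/day = 3 × 140 mg
capsules → €5,661.60 per 28-day cycle at full dose intensity). Each IV
administration day is costed at the €371 day-hospital tariff.

Reported components mirror the published four-row layout: drug,
administration, severe adverse events (SAE), and total
post-progression costs. Because the published table has no separate
monitoring row and its components sum exactly to its totals,
pre-progression monitoring is folded into the SAE/management row and
post-progression monitoring into the post-progression row.

Treatment-course timing: the initial state is entered only at model
start, so time in state equals model time. Chemo-immunotherapy is
costed as a fixed 6-cycle course — acquisition, administration, SAE
management and monitoring accrue only during the course window, with
watch-and-wait afterwards — while continuous ibrutinib accrues until
progression. This front-loads CTP spending, which is what the
published undiscounted/discounted cost ratio of the CTP arm (≈1.017)
requires. Subsequent-line states carry the post-progression mix-weighted
regimen cost plus monitoring for as long as they are occupied; BSC
carries monitoring only; death costs nothing.

Regimen schedules (doses, administrations per cycle, course lengths)
are editable configuration assembled from standard WM regimen
references; only the unit prices are printed inputs. Their aggregate
cost consequence is reconciled by the calibrated cost scales, so the
results do not depend on schedule details.

## Calibration of unpublished inputs

The published analysis prints its result aggregates but not the
inputs behind them. `wmcea.calibration` reconstructs an internally
consistent input set whose model outputs match every published
aggregate in scope: per-arm discounted and undiscounted life years,
the per-arm discounted cost components, the per-arm undiscounted
totals, and the ICERs of the base case and the two single-stream
0%-discount rows. The rows that vary the hazard ratio or the
projection family are deliberately excluded — their generating
mechanism is ambiguous (the published CTP life years *rise* as the HR
falls, which plain proportional hazards cannot produce; the calibrated
CTP pre-progression excess mortality offers one mechanism — earlier
progression means less exposure to that excess — but we do not claim
it is the original one).

The fit is two-stage:

* **Inner stage (closed form).** Given the cohort traces, the cost
  knobs are linear in the discounted component targets and are solved
  exactly: per-arm SAE-rate scale plus pre-progression monitoring
  bundle, CTP drug and administration scales, and a shared
  post-progression regimen scale and monitoring bundle (2×2 solve,
  clipped to non-negative values when needed).
* **Outer stage (nonlinear).** Seven parameters — Weibull shape and
  scale, two subsequent-line exit hazards, CTP pre-progression and BSC
  excess mortality, and the ibrutinib effective cost intensity — are
  fitted by bounded least squares on relative residuals from a
  Latin-hypercube multistart, followed by a Nelder–Mead minimax polish
  (least squares minimises the aggregate error; the convergence
  criterion is on the worst single target).

Plausibility bounds: Weibull shape 0.5–3, scale 0.5–15 years,
subsequent-line mean dwell 0.25–8 years, excess hazards ≤ 2/year,
per-event SAE incidence ≤ 0.1/cycle, cost intensity 0.6–1.05. The
ibrutinib *effective cost intensity* (fitted 0.70) bundles mean
relative dose intensity with pre-progression treatment interruption
and discontinuation; without it the fixed-price drug component pins
the discounted time on treatment and makes the published undiscounted
aggregates unattainable.

The shipped `calibrated.json` reproduces all seventeen targets with a
worst relative residual of 0.461% (the 0.5% criterion corresponds to
the published "rounded numbers from the model simulation" footnote).
All multistart runs reach the same basin; identified boundary
solutions are reported rather than hidden:

* subsequent-line dwell hazards sit at the 0.25-year minimum mean
  dwell (the published CTP cost timing pushes post-progression
  spending as early as possible);
* the post-progression monitoring bundle solves to €0/cycle — only the
  per-state cost totals are identified, not their split between
  regimen cost and monitoring;
* the CTP pre-progression management bundle is large (≈€2,900 per
  on-course cycle) because the published CTP SAE aggregate (€21,978)
  exceeds what per-event incidences capped at 0.1/cycle can carry over
  a 6-cycle course; the residual is carried in the bundle.

No claim is made of recovering the original unpublished parameter
values — different parameter sets can reproduce the same aggregates,
and the calibration reports residuals for every target so such
multiplicity is visible.

## Sensitivity analysis

**Deterministic (one-way).** Built-in scenarios: horizon 10/20 years,
0% discounting of effects or of costs, log-logistic projection, HR
0.22/0.19, zero subsequent-line treatment costs (survival untouched —
the published row shows unchanged life years), post-progression
efficacy ±20% (implemented as ±20% on mean dwell time, i.e. hazards
scaled by the inverse), and ibrutinib price ±20%. Scenarios are
declarative overrides applied to immutable parameter objects, so the
base set is never mutated; percent changes are computed from unrounded
ICERs.

**Probabilistic.** The sampling distributions are not published;
defaults are the conventional choices: lognormal HR with log-sd
matched to the printed 95% CI ((ln 0.57 − ln 0.11)/(2·1.96) ≈ 0.42),
gamma on monitoring bundles and cost scales (SE = 20% of the mean),
beta (method of moments, SE = 20% of the mean) on per-cycle SAE
incidences, and lognormal with log-sd 0.1 on the survival shape/scale,
dwell hazards and excess mortality — the 0.1 is our choice of a
moderate structural uncertainty, stated here and configurable. Every
draw is validated and the stream is reproducible by seed. The
cost-effectiveness acceptability curve reports the fraction of draws
with positive net monetary benefit λ·ΔE − ΔC. With these defaults the
model is cost-effective at €60,000/LYG in ~72% of draws; the published
analysis reports 81% (Results) and 84% (abstract) under its own,
unpublished, distributions — no target is pinned to this figure.

## Numerical choices and problem sizes

Cycle probabilities are conditional survival ratios
1 − S((k+1)Δ)/S(kΔ), clipped to [0, 1], returning 1 once S reaches 0.
The engine propagates exact row-stochastic matrices; traces are
validated to row sums within 1e-12. Cost accumulation is
occupancy-weighted with per-cycle discount factors; internal
arithmetic is full precision and whole-euro/2-decimal rounding happens
only at render time, with the ICER always computed from unrounded
increments.

Test and analysis problem sizes are chosen for desk-scale runs: the
microsimulation oracle uses 10⁵ simulated patients on a 3-cycle
example (agreement within 3 Monte-Carlo standard errors); HR-sampling
quantiles are checked on 10⁵ draws (±0.01 against the printed CI);
the analysis PSA uses 2,000 draws (CEAC standard error ≈ 1 point);
calibration uses 16 Latin-hypercube starts for the shipped bundle and
6 for the round-trip test.

## What the synthetic inputs do and do not show

The synthetic half of the parameter bundle (PFS parameters, dwell
hazards, excess mortality, SAE incidences, monitoring bundles, cost
scales, life table) emulates the *aggregate* behaviour of the original
model, not patient-level reality: passing tests demonstrate that the
implementation is internally consistent and that an input set exists
which reproduces the published aggregates through this structure. They
do not validate the clinical inputs themselves, the proportional
hazards assumption, the Weibull extrapolation beyond trial follow-up,
or the published HR (taken as given; the underlying patient-level Cox
regression is out of scope). Known limitations: no QALYs/utilities, no
societal perspective or indirect costs, memoryless subsequent lines,
no vial sharing, and a synthetic rather than official life table.
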