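# Methods

This note documents the model implemented by `afibcea`: its structure and
assumptions, the parameters and their defaults, the synthetic-data
generator's scope, numerical conventions, and the design choices made
where the published description of the source analysis was ambiguous or
under-determined. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Decision problem and model structure

Two rhythm-control strategies for adults (< 75 years) with newly diagnosed
non-valvular AF and at least one stroke risk factor are compared from a
healthcare-provider perspective: catheter ablation versus adherent
antiarrhythmic-drug (AAD) therapy. Effectiveness is measured in
quality-adjusted life years (QALYs = life-years × state utility), costs in
2019 US dollars, both discounted at 4.5%/yr over a 20-year horizon, and
the verdict is the ICER against a willingness-to-pay of $32,000/QALY
(≈ Korean GDP per capita).

**States.** `EVENT_FREE_AF`; acute one-year states for HF
hospitalisation/unplanned visit, MI, ischaemic stroke, ICH and GI bleeding;
chronic `POST_*` states for the first four (GI bleeding is transient:
survivors return to event-free AF the next cycle); `POST_PROC_STROKE`
(ablation only); absorbing `DEAD`.

**Periprocedural tree (ablation, cycle 0).** Branch probabilities from raw
counts (stroke/TIA 88/2,131; tamponade 37/2,131; 30-day death 2/2,131;
they sum to the printed 127/2,131 major-complication rate). Fatal
periprocedural strokes use the 3/88 case fatality. One-off branch costs:
$1,879.4 (no complication — also assigned to the death branch, since the
procedure was performed; no death-branch cost is published), $6,187.9
(stroke/TIA), $5,189.8 (tamponade); expected upfront cost $2,114.80.
Survivors of stroke enter `POST_PROC_STROKE`; everyone else alive enters
event-free AF. The tree consumes no calendar time and is discounted at
exponent 0.

**Annual transitions.** From every alive, non-transient state the cohort
faces the five arm-specific event risks *p_k* (first-year probabilities
carried forward as constant annual risks — the only rates published; this
also encodes that recurrent events are possible from post-event states,
with most-recent-event dominance). An event is fatal with the pooled case
fatality *f_k*; survivors move to the event's acute state. Non-event death
uses the residual

    r = max(0, m − Σ_k p_k · f_k)

where *m* is the arm's printed annual all-cause mortality. Rationale: *m*
is all-cause and already contains event deaths; subtracting the expected
event-death mass avoids double counting. In the ablation arm the printed
event-fatality mass (1.40%/yr) exceeds *m* (0.52%/yr), so the floor binds
and the realised death flux is Σ p_k f_k — see §6. The GI-transient state
faces the same total one-cycle death hazard and otherwise returns to
event-free AF (its contract is exactly one cycle).

**Accrual.** One-year cycles, no half-cycle correction (none is described
for the source analysis). Costs and utilities accrue on end-of-cycle
occupancy; cycle *t* is discounted by (1 + ρ)^−t, t = 1 for the first
Markov year.

## 2. Parameters

Packaged defaults (`afibcea/data/table1_params.yaml`) store probabilities
as raw `events/denominator` counts so binomial uncertainty is recoverable.
Ablation first-year denominators are 2,129 = 2,131 − 2 periprocedural
deaths (the tree precedes year 1). Utilities: event-free AF 0.95
(0.93–0.98), HF 0.73 (0.54–0.91), MI 0.73 (0.58–0.88), stroke 0.60
(0.54–0.65), ICH 0.67 (0.54–0.80); GI bleeding carries the event-free
utility; `POST_PROC_STROKE` the stroke utility; death 0.

Costs: per-year event costs by arm (acute year and, under the default
convention, every subsequent year in the post-event state — the published
costs are labelled "per year"); event-free maintenance $1,016.8
(ablation) / $1,221.5 (AADs) per year; $1,774.8/yr after periprocedural
stroke. The switch `post_event_cost="event_free"` reverts post-event years
to the maintenance cost; the published labelling is ambiguous between the
two readings, so both are first-class (the default is the literal
"per-year" reading, which also reproduces the published cost totals far
better). Korean-won inputs convert at 1,298.7 KRW/$ (2019).

Run settings: horizon 20 years, discount 4.5%, WTP $32,000/QALY — all
overridable per run.

## 3. Economics

ΔC and ΔE are ablation-minus-AAD differences of unrounded discounted
totals; the ICER is reported from unrounded totals and rounded only for
presentation (on the published *rounded* totals, 2,399/0.5 = 4,798,
whereas the study's unrounded model gives 4,738.51 — the package follows
the unrounded convention). Sign patterns that make the ratio
uninformative are labelled: *dominant* (ΔC ≤ 0, ΔE ≥ 0), *dominated*
(ΔC ≥ 0, ΔE ≤ 0), *equivalent*, *undefined* (ΔE = 0 ≠ ΔC).
`cost_effective` is NMB ≥ 0, which coincides with "dominant or
ICER ≤ WTP" wherever the ICER is informative and extends correctly to the
southwest quadrant.

## 4. Sensitivity analysis

**One-way DSA.** Utilities swing over their printed 95% CIs; costs over
the 2.5–97.5 percentiles of the moment-matched gamma (no cost CIs are
published, so the PSA distribution supplies the interval); transition
probabilities over ±10% of the base value; the discount rate is swept
separately over 0–7%. Values outside a parameter's support are clamped
with a warning. The tornado table reports the ICER at each end and the
absolute spread, widest first.

**PSA.** Families follow the published assignment: truncated-to-[0, 1]
normal for event and periprocedural probabilities (SE = binomial SE from
the raw counts), beta for all-cause mortality and case fatalities
(α = events, β = non-events; zero or full counts degenerate to a point
mass), beta for utilities by moment-matching the printed 95% CI
(SD = width/3.92), gamma for costs by moment-matching the mean with a
coefficient of variation of 0.5 (configurable; no spread is published).
The post-periprocedural-stroke annual cost has no published distribution
and stays fixed. Parameters are drawn jointly independently (no
correlation structure is described); utilities and fatalities are shared
across arms within a replicate. Summaries: replicate means with 2.5–97.5
percentile intervals (the published interval construction is unstated),
per-replicate ICER distribution, the CEAC (share of replicates with
WTP·ΔE − ΔC > 0 on a $0–100,000 grid, $1,000 steps) and CE-plane quadrant
shares. Everything is reproducible from a seed.

## 5. Synthetic claims data, cohort selection, estimation

The generator emulates the statistical skeleton of a national claims
extract: defaults of 2,131 ablation / 8,048 AAD patients, age 62 ± 9
truncated to [18, 74], 57% male; per-arm first-year event risks, pooled
case fatalities and annual mortality at the packaged values; gamma event
costs (CV 0.5); event days uniform over days 0–364 (only first-year risks
matter, so timing granularity is free); periprocedural events on day 0;
per-type draws independent (published event counts are marginal, so one
patient may contribute to several). Fatal events set the death day;
non-event deaths are drawn at the configured mortality minus the expected
event-death mass, floored at zero. AAD dispensings follow a 30-day refill
cadence stretched by a per-patient Beta(8.5, 1.5) adherence level
(mean 0.85), putting realistic mass on both sides of the 0.80 MPR
threshold.

It does **not** emulate diagnosis codes, providers, billing line items,
seasonality, or correlated comorbidity — so a green pipeline test
establishes that the selection/estimation logic is correct on data with
the assumed marginal structure, not that it is robust to real claims
messiness.

Cohort selection applies, in order: age 18–74 at index; no model event in
the 365 days before index; no death or model event in days [0, 42) ("six
weeks" = 42 days, half-open); arm split by ablation marker; the AAD arm
additionally requires ≥ 1 AAD dispensing (any duration — no minimum
exposure is specified) and MPR ≥ 0.80 over the first 365 days, where MPR
is the day-wise union of supply intervals divided by the window, capped at
1 (exactly 0.80 is included; the exclusion rule is "less than 80%").

Estimation rebuilds the parameter blocks from records: numerators are
patients with ≥ 1 event of the type in days [0, 365); the ablation
denominator removes periprocedural deaths (death ≤ day 30 with no model
event); fatality pools both arms per type; costs are per-event-type means
with empirical SEs; the arm comparison uses Pearson's chi-square without
continuity correction (the uncorrected statistic reproduces the published
footnote p-values, e.g. MI 0.103, GI bleeding 0.010). Utilities,
procedure and maintenance costs are not observable in the event schema and
are carried from a base parameter set.

## 6. Known limitations and the base-case discrepancy

With the packaged inputs this implementation yields (20 years, 4.5%
discount) AADs $37,802 / 9.29 QALYs and ablation $40,861 / 8.83 QALYs:
costs and the cost difference are close to the published totals, but the
incremental QALY has the **opposite sign** (ablation dominated rather than
gaining 0.5 QALYs). This is a property of the published inputs, not a
numerical artefact: the printed first-year event probabilities are
uniformly higher in the ablation arm (HF 29.97 vs 16.40 %/yr — plausibly
an ascertainment artefact of post-procedure utilisation), and carrying
them forward makes ablation accrue more time in low-utility states, while
the pooled case fatality forces its death flux (1.40%/yr) above its
printed all-cause mortality (0.52%/yr). A systematic search over the
admissible structural conventions (which states face event risks, how
fatality and all-cause mortality compose, transient-event variants, both
cost conventions, accrual timing) found no configuration that reproduces a
positive QALY gap together with the published cost levels; the source
analysis states that events were analysed over three years and run as an
individual-level simulation in commercial decision-modelling software, so
its effective inputs evidently include unpublished rates. The structural switches are retained and
documented rather than tuned; the acceptance suite asserts the published
conclusions where they are reachable and reports the computed values
honestly where they are not.

Consequences of the same inconsistency: the configured ablation all-cause
mortality is unattainable inside the synthetic generator (the floor rule
makes realised mortality equal the event-death mass), so parameter
recovery compares mortality against the generative value
1 − (1 − r)·Π(1 − p_k f_k).

Other limitations, by construction: no repeat ablations or arm crossover;
no age-dependent background mortality (all mortality comes from the
cohort's own first-year data; the starting age of 62 is recorded in the
trace only); constant hazards beyond year 1; no indirect/societal costs;
no distinction among ablation technologies; cohort-level algebra assumes
per-type risks sum (with mortality) to ≤ 1 per state, validated on input.

## 7. Verification

The transition algebra's correctness oracle is an independently coded
patient-level microsimulation (tests) of the same generative process:
per-cycle occupancies must agree within Monte-Carlo error at 10⁶ patients
(≥ 99% of binomial comparisons inside 3 SE and all inside 5 SE, restricted
to expected counts ≥ 5 where the normal approximation holds — with ~10³
comparisons a correct engine still produces the occasional 3-SE
excursion). Mass conservation, dominance/NMB identities, cascade
monotonicity, seeded determinism of the generator and PSA, and recovery of
generating parameters from 50,000-patient synthetic cohorts are covered by
property-based and example tests.
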