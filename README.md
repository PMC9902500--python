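# afibcea

Health-economic evaluation of two rhythm-control strategies for newly
diagnosed non-valvular atrial fibrillation (AF): **catheter ablation**
versus **antiarrhythmic drugs (AADs)**. The package implements, as a
tested and reusable library, a 20-year annual-cycle Markov cohort model
with a periprocedural decision tree, incremental cost-effectiveness
economics, one-way (tornado) and probabilistic sensitivity analysis, and
the upstream claims-data stages — cohort selection with a medication
possession ratio (MPR) rule and parameter estimation from patient-level
records — backed by a synthetic claims generator so the full pipeline runs
without access to the original (non-public) Korean national claims
extract.

It is written for health-economics and outcomes researchers who want a
scriptable, auditable alternative to spreadsheet/TreeAge decision models.

## The model

Each strategy's cohort moves through twelve health states in one-year
cycles: event-free AF; acute years of heart-failure (HF) hospitalisation,
myocardial infarction (MI), ischaemic stroke, intracranial haemorrhage
(ICH) and gastrointestinal (GI) bleeding; chronic post-event states; a
post periprocedural-stroke state; and death. From every alive state the
cohort faces competing annual risks: arm-specific first-year event
probabilities *p&#8342;* (an event of type *k* is fatal with case fatality
*f&#8342;*), plus a residual non-event death probability

&nbsp;&nbsp;&nbsp;&nbsp;*r* = max(0, *m* − Σ&#8342; *p&#8342;* *f&#8342;*),

where *m* is the arm's annual all-cause mortality (the subtraction avoids
double-counting event deaths). GI bleed survivors return to event-free AF
after one cycle; other survivors enter the event's chronic state. The
ablation arm first passes through a decision tree over periprocedural
stroke/TIA, cardiac tamponade, 30-day death and uncomplicated procedure,
each branch carrying its one-off procedure cost.

Cycle *t* accrues, on end-of-cycle occupancy, a cost Σ&#8347; occ(*s*)·c(*s*)
and a QALY Σ&#8347; occ(*s*)·u(*s*), both discounted by (1+ρ)⁻ᵗ with
ρ = 4.5%/yr. The incremental cost-effectiveness ratio is
ICER = ΔC/ΔE (ablation minus AADs, unrounded totals), judged against a
willingness-to-pay (WTP) threshold of $32,000/QALY; the net monetary
benefit is NMB = WTP·ΔE − ΔC.

The packaged default parameters (`afibcea.table1_params()`) are the
published estimates from a nationwide Korean claims cohort (2,131 ablation
/ 8,048 AAD patients): raw event counts, case fatalities, literature
utilities with 95% CIs, and 2019 US-dollar costs (1,298.7 KRW/$).

## Worked example

```python
import afibcea as af

params = af.table1_params()
results = af.run_both_arms(params)
for arm in ("aads", "ablation"):
    r = results[arm]
    print(f"{arm:9s} cost={r.total_cost:10.1f}  qaly={r.total_qaly:.3f}")
ce = af.compute_icer(results["ablation"], results["aads"], params.wtp)
print(f"dC={ce.delta_cost:.1f} dE={ce.delta_effect:.4f} "
      f"label={ce.label} nmb={ce.nmb:.0f}")
```

prints

```
aads      cost=   37801.7  qaly=9.289
ablation  cost=   40861.1  qaly=8.834
dC=3059.4 dE=-0.4552 label=dominated nmb=-17625
```

Over 20 discounted years the drug strategy costs $37,802 for 9.29 QALYs
per patient and the ablation strategy $40,861 for 8.83 QALYs: with this
parameter set ablation is *dominated* (costlier, fewer QALYs), because the
published first-year event probabilities — carried forward as constant
annual risks — are uniformly higher after ablation (HF hospitalisation
29.97 vs 16.40 %/yr) while the mortality advantage is absorbed by the
case-fatality decomposition. The source study reported the opposite
incremental-QALY sign from the same printed inputs; `docs/methods.md`
documents why no admissible structure reconciles the two and how the
structural switches (`post_event_cost`, the mortality decomposition)
behave.

Sensitivity analysis in three lines:

```python
af.discount_sweep(params)                      # ICER at 0/3/7% discounting
af.one_way_dsa(params, af.default_dsa_ranges(params))   # tornado table
af.run_psa(params, n_reps=10_000, seed=7)      # PSA + CEAC + quadrants
```

The tornado's widest bar is the cost of HF hospitalisation/unplanned
visits (as in the source study); the 10,000-replicate PSA gives mean arm
costs/QALYs of $40,796 / 8.83 (ablation) and $37,759 / 9.29 (AADs), with
95% uncertainty intervals from the 2.5–97.5 replicate percentiles.

The same pipeline is available from the shell:

```bash
afibcea all --out run1 --seed 42 --psa-reps 10000   # simulate → select →
                                                    # estimate → model → DSA → PSA
afibcea run --out ce.json                           # base case only
afibcea dsa --out tornado.csv --plot tornado.png
```

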