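# Default model parameters for the ablation vs antiarrhythmic-drug (AAD)
# rhythm-control cost-effectiveness model. Probabilities are stored as raw
# event counts over denominators (first-year risks from a Korean claims
# cohort of 2,131 ablation and 8,048 AAD patients); costs are 2019 US $.
event_probs:
  ablation:            # denominator 2,129 = 2,131 minus 2 periprocedural deaths
    HF_HOSP:         [638, 2129]
    MI:              [28, 2129]
    ISCHEMIC_STROKE: [71, 2129]
    ICH:             [13, 2129]
    GI_BLEED:        [86, 2129]
  aads:
    HF_HOSP:         [1320, 8048]
    MI:              [74, 8048]
    ISCHEMIC_STROKE: [163, 8048]
    ICH:             [42, 8048]
    GI_BLEED:        [237, 8048]
mortality:             # annual all-cause mortality, first year
  ablation:          [11, 2129]
  aads:              [101, 8048]
periprocedural:        # decision-tree branches, ablation arm only
  major_complication: [127, 2131]
  PROC_STROKE_TIA:    [88, 2131]
  TAMPONADE:          [37, 2131]
  death_30d:          [2, 2131]
fatality:              # case fatality conditional on the event, pooled arms
  HF_HOSP:         [50, 1958]
  MI:              [8, 102]
  ISCHEMIC_STROKE: [16, 234]
  PROC_STROKE_TIA: [3, 88]
  ICH:             [14, 55]
  GI_BLEED:        [12, 323]
utilities:             # value and 95% CI, literature-derived
  EVENT_FREE:      [0.95, 0.93, 0.98]
  HF_HOSP:         [0.73, 0.54, 0.91]
  MI:              [0.73, 0.58, 0.88]
  ISCHEMIC_STROKE: [0.60, 0.54, 0.65]
  ICH:             [0.67, 0.54, 0.80]
procedure_costs:       # one-off, per periprocedural branch (US $)
  no_complication: 1879.4
  PROC_STROKE_TIA: 6187.9
  TAMPONADE:       5189.8
event_costs:           # per patient-year with the event (US $)
  ablation:
    HF_HOSP:         3217.5
    MI:              6545.8
    ISCHEMIC_STROKE: 7643.9
    ICH:             21238.3
    GI_BLEED:        3739.9
  aads:
    HF_HOSP:         3556.4
    MI:              5955.6
    ISCHEMIC_STROKE: 7991.3
    ICH:             9398.1
    GI_BLEED:        4418.0
event_free_cost:       # annual maintenance cost of event-free AF (US $)
  ablation: 1016.8
  aads:     1221.5
post_proc_stroke_annual_cost: 1774.8   # annual cost after periprocedural TIA/stroke
discount_rate: 0.045
horizon: 20            # years
wtp: 32000.0           # US $ per QALY
krw_per_usd: 1298.7    # 2019 exchange rate
post_event_cost: event # structural switch: post-event years carry the
                       # per-year event cost ("event") or revert to the
                       # event-free maintenance cost ("event_free")
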