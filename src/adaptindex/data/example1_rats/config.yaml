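# Swimming-rat study: 4 groups (B untrained control, C trained, D untrained +
# eleutherosides, E trained + eleutherosides), destructive sampling at rest
# (F1, doubling as the intact baseline for the control group) and immediately
# after a 15-min loaded swim (F2). No recovery state was sampled.
#
# Stability coefficients are the published ones (computed from the control
# group's rest cohort, e.g. 0.913 = 1 - 1.2/13.8 for hexokinase); keeping
# them as supplied isolates the index arithmetic from rounding of S.
design: case3
weighting: stability
include_recovery: false
alpha: 0.05
confidence: 0.95
stability_source:
  policy: supplied
  # provenance of the supplied values: reference_group B at state F1
  group: B
  state: F1
metadata:
  conditioning_factor: "14-day swim training and/or eleutheroside injections (5 mg/kg s.c. twice daily)"
  provoking_load: "15-min swim with 6% body-weight load, water 29-31 C"
  species: "male Wistar rats"
parameters:
  - name: "11-HCS"
    category: adaptive
    units: "ug per 100 mL plasma"
    stability: 0.778
  - name: hexokinase
    category: homeostatic
    units: "nM NADPH per mg protein per min (gastrocnemius)"
    stability: 0.913
  - name: lactate
    category: homeostatic
    units: "mmol per L blood"
    stability: 0.672
  - name: ammonia
    category: homeostatic
    units: "ug per 100 mL blood"
    stability: 0.893
  - name: glycogen
    category: homeostatic
    units: "mg per 100 g muscle"
    stability: 0.694
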