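# Race-horse study: two groups of 6 horses (g1 robust, g2 weak functional
# status), measured at baseline (F1, no conditioning factor so F0 = F1),
# immediately after a race at ~80% maximal intensity (F2), and after 1 h of
# rest (F3). Recovery terms are included.
#
# Weighting is "none": the published group totals equal the unweighted sums
# of the published per-parameter fraction columns, so this fixture pins that
# mode to reproduce them. The published per-group S values (each group's own
# baseline, 1 - SD/mean) are kept for reporting.
#
# Perspiration was also recorded (semi-quantitatively, "No" to "+++") but
# was not taken into the analysis; it is therefore not a parameter here.
design: case3
weighting: none
include_recovery: true
alpha: 0.05
confidence: 0.95
stability_source:
  policy: supplied
  state: F1
metadata:
  provoking_load: "race at ~80% of maximal intensity, recovery measured 1 h later"
  species: "race horses, n = 6 per group"
parameters:
  - name: P95
    category: adaptive
    units: "uA (blood oxygen release capacity at 95% HbO2)"
    stability: {g1: 0.963, g2: 0.967}
  - name: P50
    category: adaptive
    units: "uA (blood oxygen release capacity at 50% HbO2)"
    stability: {g1: 0.971, g2: 0.970}
  - name: hemoglobin
    category: adaptive
    units: "g per 100 mL blood"
    stability: {g1: 0.988, g2: 0.987}
  - name: heart_rate
    category: adaptive
    units: "beats per min"
    stability: {g1: 0.960, g2: 0.925}
  - name: lactate
    category: homeostatic
    units: "mg per 100 mL blood"
    stability: {g1: 0.424, g2: 0.493}
  - name: reserve_alkalinity
    category: homeostatic
    units: "mg per 100 mL blood"
    stability: {g1: 0.965, g2: 0.954}
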