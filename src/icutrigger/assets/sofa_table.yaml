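# SOFA organ-dysfunction cut-points (standard published scale).
# For worse: low  -> subscore = number of thresholds the value lies strictly below.
# For worse: high -> subscore = number of thresholds the value meets or exceeds.
# Units match the analyte enum of the data model.
organs:
  respiratory:
    analyte: PAO2_FIO2_ratio
    worse: low
    thresholds: [400, 300, 200, 100]
  coagulation:
    analyte: PLATELETS_per_uL
    worse: low
    thresholds: [150000, 100000, 50000, 20000]
  hepatic:
    analyte: BILIRUBIN_mg_dL
    worse: high
    thresholds: [1.2, 2.0, 6.0, 12.0]
  cardiovascular:
    analyte: MAP_mmHg
    worse: low
    thresholds: [70]
    # MAP alone distinguishes only 0 vs 1; scores 2-4 require vasopressor
    # support, represented by the on_support flag (capped at 2 without doses).
    on_support_score: 2
  neurological:
    analyte: GCS_points
    worse: low
    thresholds: [15, 13, 10, 6]
  renal:
    analyte: CREATININE_mg_dL
    worse: high
    thresholds: [1.2, 2.0, 3.5, 5.0]
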