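# Adapted Global Trigger Tool catalog: 28 triggers in three modules
# (21 medication, 3 care, 4 laboratory-test-results).
# All threshold comparisons are strict: a value exactly at the threshold
# does not fire.
triggers:
  # ----- medication module (21) -----
  - id: ptt_gt_50
    name: "PTT > 50 s"
    module: MEDICATION
    rule: LAB_THRESHOLD
    params: {analyte: PTT_s, direction: GT, threshold: 50}
  - id: inr_gt_3
    name: "INR > 3"
    module: MEDICATION
    rule: LAB_THRESHOLD
    params: {analyte: INR, direction: GT, threshold: 3}
  - id: blood_glucose_lt_50
    name: "Blood glucose < 50 mg/dL"
    module: MEDICATION
    rule: LAB_THRESHOLD
    params: {analyte: GLUCOSE_mg_dL, direction: LT, threshold: 50}
  - id: bun_cr_2x
    name: "Rising BUN or serum creatinine 2x over baseline"
    module: MEDICATION
    rule: RELATIVE_CHANGE
    params: {analytes: [BUN_mg_dL, CREATININE_mg_dL], mode: RISE_FOLD, magnitude: 2.0}
  - id: ondansetron
    name: "Ondansetron administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [ondansetron, zofran]}
  - id: bromopride
    name: "Bromopride administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [bromopride]}
  - id: metoclopramide
    name: "Metoclopramide administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [metoclopramide, plasil]}
  - id: phytomenadione
    name: "Phytomenadione (vitamin K) administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [phytomenadione, vitamin k, phytonadione]}
  - id: flumazenil
    name: "Flumazenil administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [flumazenil]}
  - id: naloxone
    name: "Naloxone administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [naloxone]}
  - id: protamine
    name: "Protamine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [protamine]}
  - id: dexchlorpheniramine
    name: "Dexchlorpheniramine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [dexchlorpheniramine]}
  - id: hydroxyzine
    name: "Hydroxyzine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [hydroxyzine]}
  - id: diphenhydramine
    name: "Diphenhydramine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [diphenhydramine]}
  - id: loratadine
    name: "Loratadine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [loratadine]}
  - id: hydrocortisone
    name: "Hydrocortisone administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [hydrocortisone]}
  - id: methylprednisolone
    name: "Methylprednisolone administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [methylprednisolone]}
  - id: promethazine
    name: "Promethazine administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [promethazine]}
  - id: prednisone
    name: "Prednisone administration"
    module: MEDICATION
    rule: MED_ADMINISTERED
    params: {drugs: [prednisone]}
  - id: oversedation_hypotension
    name: "Over-sedation / hypotension (MAP < 70)"
    module: MEDICATION
    rule: VITAL_THRESHOLD
    params: {analyte: MAP_mmHg, direction: LT, threshold: 70}
  - id: abrupt_medication_stop
    name: "Abrupt medication stop"
    module: MEDICATION
    rule: ABRUPT_STOP
    params: {}
  # ----- care module (3) -----
  - id: hb_ht_drop_25
    name: "Decrease in Hb or Ht of 25% or greater"
    module: CARE
    rule: RELATIVE_CHANGE
    params: {analytes: [HEMOGLOBIN_g_dL, HEMATOCRIT_pct], mode: DROP_PCT, magnitude: 0.25}
  - id: patient_fall
    name: "Patient fall"
    module: CARE
    rule: NOTE_EVENT
    params: {kind: PATIENT_FALL}
  - id: skin_rash
    name: "Skin rash"
    module: CARE
    rule: NOTE_EVENT
    params: {kind: SKIN_RASH}
  # ----- laboratory test results module (4) -----
  - id: sodium_lt_135
    name: "Sodium < 135 mEq/L"
    module: LAB
    rule: LAB_THRESHOLD
    params: {analyte: SODIUM_mEq_L, direction: LT, threshold: 135}
  - id: potassium_lt_3
    name: "Potassium < 3.0 mmol/L"
    module: LAB
    rule: LAB_THRESHOLD
    params: {analyte: POTASSIUM_mmol_L, direction: LT, threshold: 3.0}
  - id: potassium_gt_5_5
    name: "Potassium > 5.5 mmol/L"
    module: LAB
    rule: LAB_THRESHOLD
    params: {analyte: POTASSIUM_mmol_L, direction: GT, threshold: 5.5}
  - id: platelets_lt_50000
    name: "Platelets < 50,000/uL"
    module: LAB
    rule: LAB_THRESHOLD
    params: {analyte: PLATELETS_per_uL, direction: LT, threshold: 50000}
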