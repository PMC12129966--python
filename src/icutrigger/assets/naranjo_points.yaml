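# Naranjo ADR probability scale: per-question points for yes / no / unknown,
# and the score bands for the causality categories.
questions:
  - {n: 1,  text: "Are there previous conclusive reports on this reaction?",                      yes: 1,  no: 0,  unknown: 0}
  - {n: 2,  text: "Did the adverse event appear after the suspected drug was administered?",      yes: 2,  no: -1, unknown: 0}
  - {n: 3,  text: "Did the reaction improve when the drug was discontinued or an antagonist given?", yes: 1, no: 0, unknown: 0}
  - {n: 4,  text: "Did the reaction reappear when the drug was readministered?",                  yes: 2,  no: -1, unknown: 0}
  - {n: 5,  text: "Are there alternative causes that could on their own have caused the reaction?", yes: -1, no: 2, unknown: 0}
  - {n: 6,  text: "Did the reaction reappear when a placebo was given?",                          yes: -1, no: 1,  unknown: 0}
  - {n: 7,  text: "Was the drug detected in blood at concentrations known to be toxic?",          yes: 1,  no: 0,  unknown: 0}
  - {n: 8,  text: "Was the reaction more severe when the dose was increased, or less severe when decreased?", yes: 1, no: 0, unknown: 0}
  - {n: 9,  text: "Did the patient have a similar reaction to the same or similar drugs in any previous exposure?", yes: 1, no: 0, unknown: 0}
  - {n: 10, text: "Was the adverse event confirmed by any objective evidence?",                   yes: 1,  no: 0,  unknown: 0}
# category = definite if score >= definite_min, probable if >= probable_min,
# possible if >= possible_min, else doubtful
bands:
  definite_min: 9
  probable_min: 5
  possible_min: 1
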