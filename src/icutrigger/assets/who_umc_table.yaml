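# WHO-UMC causality assessment as an ordered decision table.
# Facts:
#   temporal_plausibility: yes | no | unknown
#   alternative_causes:    present | excluded | unknown
#   dechallenge:           positive | none | unknown
#   rechallenge:           positive | none | unknown
#   data_sufficient:       true | false
# The first rule whose conditions all match decides the category. '*' matches
# any value. Rules are ordered from strongest evidence down, so adding
# supporting evidence can only move an assessment to an earlier (stronger)
# rule, never a weaker one.
rules:
  - when: {data_sufficient: "false"}
    category: unassessable_unclassifiable
  - when: {temporal_plausibility: "no"}
    category: unlikely
  - when: {temporal_plausibility: "yes", alternative_causes: excluded, dechallenge: positive, rechallenge: positive}
    category: certain
  - when: {temporal_plausibility: "yes", alternative_causes: excluded, dechallenge: positive}
    category: probable
  - when: {temporal_plausibility: "yes", alternative_causes: unknown, dechallenge: positive}
    category: probable
  - when: {temporal_plausibility: "yes"}
    category: possible
  - when: {temporal_plausibility: unknown}
    category: conditional_unclassified
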