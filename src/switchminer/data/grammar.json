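{
  "comment": "Ordered switch-pattern rules. {FROM}/{TO} bind drug-mention slots; patterns run on a lowercased, punctuation-stripped token stream. Priority = list order (earlier wins on the same ordered drug pair). 'family' groups rules by the core pattern family they extend.",
  "rules": [
    {"rule_id": "switch_from_to", "family": "switch", "pattern": "\\bswitch(?:ed|ing|es)?\\s+(?:\\w+\\s+){0,3}?(?:over\\s+)?from\\s+{FROM}\\s+(?:\\w+\\s+){0,3}?(?:over\\s+)?to\\s+{TO}\\b"},
    {"rule_id": "moving_from_to", "family": "move", "pattern": "\\bmov(?:ed|ing|e)\\s+(?:\\w+\\s+){0,3}?from\\s+{FROM}\\s+(?:\\w+\\s+){0,3}?to\\s+{TO}\\b"},
    {"rule_id": "stop_start", "family": "stop_start", "pattern": "\\bstopp(?:ed|ing)\\s+{FROM}\\s+(?:and\\s+|then\\s+)?(?:\\w+\\s+){0,3}?start(?:ed|ing)\\s+(?:on\\s+)?{TO}\\b"},
    {"rule_id": "switch_to_from", "family": "switch", "pattern": "\\bswitch(?:ed|ing|es)?\\s+(?:\\w+\\s+){0,2}?to\\s+{TO}\\s+from\\s+{FROM}\\b"},
    {"rule_id": "went_from_to", "family": "switch", "pattern": "\\bwent\\s+from\\s+{FROM}\\s+(?:\\w+\\s+){0,3}?to\\s+{TO}\\b"},
    {"rule_id": "changed_from_to", "family": "switch", "pattern": "\\bchang(?:ed|ing)\\s+(?:\\w+\\s+){0,2}?from\\s+{FROM}\\s+(?:\\w+\\s+){0,2}?to\\s+{TO}\\b"},
    {"rule_id": "transitioned_from_to", "family": "move", "pattern": "\\btransition(?:ed|ing)?\\s+from\\s+{FROM}\\s+(?:\\w+\\s+){0,2}?to\\s+{TO}\\b"},
    {"rule_id": "quit_started", "family": "stop_start", "pattern": "\\bquit(?:ting)?\\s+{FROM}\\s+(?:and\\s+|then\\s+)?start(?:ed|ing)\\s+(?:on\\s+)?{TO}\\b"},
    {"rule_id": "dropped_for", "family": "stop_start", "pattern": "\\bdropp(?:ed|ing)\\s+{FROM}\\s+for\\s+{TO}\\b"},
    {"rule_id": "replaced_with", "family": "stop_start", "pattern": "\\breplac(?:ed|ing)\\s+{FROM}\\s+with\\s+{TO}\\b"},
    {"rule_id": "traded_for", "family": "stop_start", "pattern": "\\btrad(?:ed|ing)\\s+{FROM}\\s+for\\s+{TO}\\b"},
    {"rule_id": "gave_up_for", "family": "stop_start", "pattern": "\\bgave\\s+up\\s+{FROM}\\s+for\\s+{TO}\\b"}
  ]
}
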