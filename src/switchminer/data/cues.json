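{
  "comment": "Cue lexicons for reason, theme, category and sentiment classification. reason_order fixes the precedence when several reason cues co-occur in the clause window (most frequent published category first).",
  "reason_order": ["SIDE_EFFECTS", "LACK_OF_EFFICACY", "PHYSICIAN_ADVICE", "EASE_OF_USE", "QOL_WORSENING", "SAFETY_CONCERNS", "INSURANCE", "COST", "OTHER"],
  "reason_cues": {
    "SIDE_EFFECTS": ["side effect", "side effects", "site reaction", "site reactions", "flu-like symptoms", "nausea"],
    "LACK_OF_EFFICACY": ["wasn't working", "was not working", "not working", "stopped working", "efficacy", "kept relapsing", "still relapsing", "more effective"],
    "PHYSICIAN_ADVICE": ["neurologist", "my neuro ", "doctor", "physician", "doc said"],
    "EASE_OF_USE": ["easier", "ease of use", "a pill", "no more needles", "convenient"],
    "QOL_WORSENING": ["quality of life"],
    "SAFETY_CONCERNS": ["safety", "pml"],
    "INSURANCE": ["insurance"],
    "COST": ["cost", "copay", "expensive", "price", "afford"],
    "OTHER": ["personal reasons", "other reasons"]
  },
  "theme_order": ["COST", "EFFICACY", "SIDE_EFFECTS", "ADHERENCE"],
  "theme_cues": {
    "COST": ["cost", "copay", "expensive", "price", "insurance", "afford"],
    "EFFICACY": ["works", "working", "efficacy", "relapse", "relapsing", "effective"],
    "SIDE_EFFECTS": ["side effect", "side effects", "site reaction", "nausea", "flu-like"],
    "ADHERENCE": ["doses", "dose", "forget to take", "missed dose", "adherence", "skip"]
  },
  "sentiment_positive": ["great", "love", "loving", "amazing", "happy", "better", "good", "easier", "thankful", "relieved"],
  "sentiment_negative": ["horrible", "awful", "worse", "hate", "bad", "terrible", "unbearable", "expensive", "miserable", "scary"],
  "seeking_openers": ["has anyone", "does anyone", "is anyone", "anyone else", "what", "how", "why", "when", "who", "where", "which", "can anyone", "should i"],
  "spam_cues": ["click here", "buy now", "cheap online", "promo code", "limited offer", "discount code", "order now"]
}
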