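{
  "description": "Canonical therapeutic disease categories for ethnomedicinal efficacy coding, ordered inner-to-outer for ring visualisation.",
  "categories": [
    {"id": "poisoning_intoxication", "label": "Poisoning/intoxication"},
    {"id": "circulatory", "label": "Circulatory disease"},
    {"id": "gastrointestinal", "label": "Gastrointestinal disease"},
    {"id": "nervous_system", "label": "Nervous system disease"},
    {"id": "eye", "label": "Eye disease"},
    {"id": "other_general", "label": "Other/general disease"},
    {"id": "hepatobiliary", "label": "Hepatobiliary disease"},
    {"id": "musculoskeletal", "label": "Musculoskeletal disease"},
    {"id": "oral", "label": "Oral disease"},
    {"id": "ear_nose_throat", "label": "Ear/nose/throat disease"},
    {"id": "pediatric", "label": "Pediatric disease"},
    {"id": "reproductive", "label": "Reproductive system disease"},
    {"id": "respiratory", "label": "Respiratory disease"},
    {"id": "skin", "label": "Skin disease"},
    {"id": "urinary", "label": "Urinary disease"}
  ]
}
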