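{
 "lexicon_id": "debug",
 "disease_terms": {
  "schizophrenia": "F20",
  "major depressive disorder": "F32",
  "depressive episode": "F32",
  "bipolar disorder": "F31",
  "other nonorganic mental disorder": "F28",
  "unspecified nonorganic psychosis": "F29"
 },
 "kinship_terms": {
  "father": ["father", "first"],
  "mother": ["mother", "first"],
  "brother": ["brother", "first"],
  "sister": ["sister", "first"],
  "son": ["son", "first"],
  "daughter": ["daughter", "first"],
  "grandfather": ["grandfather", "second"],
  "grandmother": ["grandmother", "second"],
  "uncle": ["uncle", "second"],
  "aunt": ["aunt", "second"],
  "nephew": ["nephew", "second"],
  "niece": ["niece", "second"],
  "cousin": ["cousin", "third"],
  "great-grandfather": ["great-grandfather", "third"]
 },
 "negation_cues": ["denies", "no family history"],
 "section_cues": ["Family history:"]
}
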