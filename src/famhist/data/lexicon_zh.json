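{
 "lexicon_id": "zh",
 "disease_terms": {
  "精神分裂症": "F20",
  "抑郁症": "F32",
  "抑郁发作": "F32",
  "重度抑郁症": "F32",
  "双相情感障碍": "F31",
  "双相障碍": "F31",
  "躁郁症": "F31",
  "其他非器质性精神障碍": "F28",
  "非器质性精神障碍": "F28",
  "未特定的非器质性精神病": "F29",
  "非器质性精神病": "F29"
 },
 "kinship_terms": {
  "父亲": ["father", "first"],
  "母亲": ["mother", "first"],
  "哥哥": ["brother", "first"],
  "弟弟": ["brother", "first"],
  "姐姐": ["sister", "first"],
  "妹妹": ["sister", "first"],
  "儿子": ["son", "first"],
  "女儿": ["daughter", "first"],
  "祖父": ["grandfather", "second"],
  "祖母": ["grandmother", "second"],
  "外祖父": ["grandfather", "second"],
  "外祖母": ["grandmother", "second"],
  "叔叔": ["uncle", "second"],
  "舅舅": ["uncle", "second"],
  "姑姑": ["aunt", "second"],
  "姨妈": ["aunt", "second"],
  "侄子": ["nephew", "second"],
  "侄女": ["niece", "second"],
  "外甥": ["nephew", "second"],
  "表哥": ["cousin", "third"],
  "表姐": ["cousin", "third"],
  "表弟": ["cousin", "third"],
  "表妹": ["cousin", "third"],
  "堂哥": ["cousin", "third"],
  "堂姐": ["cousin", "third"],
  "堂弟": ["cousin", "third"],
  "堂妹": ["cousin", "third"],
  "曾祖父": ["great-grandfather", "third"],
  "曾祖母": ["great-grandmother", "third"]
 },
 "negation_cues": ["否认", "没有", "未见"],
 "section_cues": ["家族史"]
}
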