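{
  "wt_name": "Opto-mGluR6",
  "wt_pocket": "VIAFYAGAFGIMAWETSCSWYLFVFLFWYSAPAVA",
  "variant_pockets": {
    "ROM17": "WMSSYGVSCGILAWETSCGPVLMCCLFWYTAPAYA",
    "ROM18": "WMSSYGVSCGILAWETSCGPVLMCCLFWYTAPAYA",
    "ROM19": "WMSSYGVSCGILSWETSCGPVLMCCLYWYTAPAYA"
  },
  "shared_mutations": [
    "V75W", "I76M", "A123S", "F126S", "A146G", "G149V", "A150S", "F152C",
    "M157L", "S223G", "W224P", "Y226V", "F241M", "V244C", "F245C", "S290T",
    "V314Y"
  ],
  "rom18_extra": ["F282Y"],
  "rom19_extra": ["F282Y", "A199S"],
  "lambda_max_nm": {
    "Opto-mGluR6": 480,
    "ROM17": 520,
    "ROM18": 550,
    "ROM19": 605
  },
  "lambda_max_alt_nm": {
    "ROM19": 606
  },
  "target_class_by_variant": {
    "ROM17": "520-540",
    "ROM18": "540-557",
    "ROM19": "557-625"
  },
  "spectral_classes": [
    {"label": "332-340", "low_nm": 332, "high_nm": 340, "closed_high": false},
    {"label": "520-540", "low_nm": 520, "high_nm": 540, "closed_high": false},
    {"label": "540-557", "low_nm": 540, "high_nm": 557, "closed_high": false},
    {"label": "557-625", "low_nm": 557, "high_nm": 625, "closed_high": true}
  ]
}
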