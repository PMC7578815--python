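{
  "name": "pozzar2020",
  "n_cases": 271,
  "screening": {"n": 576, "n_est_band": 475, "n_passed": 271},
  "groups": [
    {"label": "hidden_fast", "n": 25,
     "codes": ["HIDDEN_RESPONSE", "TIME_LT5", "ZIP_STATE_MISMATCH"],
     "timing": "sub2", "local_band_n": 25},
    {"label": "hidden_no_ts", "n": 19,
     "codes": ["HIDDEN_RESPONSE"],
     "timing": "invalid", "local_band_n": 0},
    {"label": "fast", "n": 38,
     "codes": ["TIME_LT5", "ZIP_STATE_MISMATCH"],
     "timing": "lt5", "local_band_n": 38},
    {"label": "dup_mid", "n": 70,
     "codes": ["TIME_5TO10", "DUP_TEXT", "ZIP_STATE_MISMATCH"],
     "timing": "5to10", "local_band_n": 65, "dup_pool": "mid"},
    {"label": "dup_slow_zip", "n": 51,
     "codes": ["DUP_TEXT", "ZIP_STATE_MISMATCH"],
     "timing": "normal", "local_band_n": 0, "dup_pool": "slow"},
    {"label": "dup_slow", "n": 17,
     "codes": ["DUP_TEXT"],
     "timing": "normal", "local_band_n": 0, "dup_pool": "slow"},
    {"label": "offshore", "n": 36,
     "codes": ["NONUS_TZ", "STATE_TZ_MISMATCH"],
     "timing": "normal", "local_band_n": 0},
    {"label": "suspicious_only", "n": 15,
     "codes": ["ZIP_STATE_MISMATCH"],
     "timing": "normal", "local_band_n": 0}
  ],
  "dup_seeds": {
    "mid": [
      {"text": "the first choice surgery excision treatment, surgery pathology",
       "count": 6, "item": "o05"}
    ],
    "slow": [
      {"text": "professional and technical personnel carry out film packaging management",
       "count": 2, "item": "o14"}
    ]
  }
}
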