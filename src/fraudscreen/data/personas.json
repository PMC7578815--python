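{
  "legitimate": {
    "completion_mu_log": 2.773,
    "completion_sigma_log": 0.28,
    "hour_low": 8,
    "hour_high": 22,
    "template_reuse_p": 0.0,
    "hidden_p": 0.0,
    "zip_mismatch_p": 0.0,
    "nonus_zone_p": 0.0,
    "straightline_p": 0.0
  },
  "satisficer": {
    "completion_mu_log": 1.946,
    "completion_sigma_log": 0.35,
    "hour_low": 8,
    "hour_high": 22,
    "template_reuse_p": 0.0,
    "hidden_p": 0.0,
    "zip_mismatch_p": 0.0,
    "nonus_zone_p": 0.0,
    "straightline_p": 0.6
  },
  "farm": {
    "completion_mu_log": 1.792,
    "completion_sigma_log": 0.5,
    "hour_low": 0,
    "hour_high": 4,
    "template_reuse_p": 0.8,
    "hidden_p": 0.0,
    "zip_mismatch_p": 0.4,
    "nonus_zone_p": 0.15,
    "straightline_p": 0.3
  },
  "bot": {
    "completion_mu_log": 0.405,
    "completion_sigma_log": 0.3,
    "hour_low": 0,
    "hour_high": 4,
    "template_reuse_p": 0.2,
    "hidden_p": 1.0,
    "zip_mismatch_p": 0.5,
    "nonus_zone_p": 0.3,
    "straightline_p": 0.5
  }
}
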