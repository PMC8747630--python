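cdr0.5:
  P: 8.0
  S: 2.0
  W_total: 1.0
  boost_increment: 1.0
  help_extra_physical: 37.0
  help_extra_verbal: 29.0
  level: cdr0.5
  max_attempts: 3
  noise_dist: logistic
  noise_scale_act: 0.45
  noise_scale_util: 2.0
  similarity_scale: 1.0
  threshold: 0.6153668054945411
  utility_gap:
    default: 4.0
cdr1:
  P: 8.0
  S: 2.0
  W_total: 0.85
  boost_increment: 1.0
  help_extra_physical: 35.0
  help_extra_verbal: 27.0
  level: cdr1
  max_attempts: 3
  noise_dist: logistic
  noise_scale_act: 0.55
  noise_scale_util: 3.0
  similarity_scale: 1.0
  threshold: 0.5368334838850113
  utility_gap:
    default: -4.0
cdr2:
  P: 8.0
  S: 2.0
  W_total: 0.7
  boost_increment: 1.0
  help_extra_physical: 32.0
  help_extra_verbal: 24.0
  level: cdr2
  max_attempts: 3
  noise_dist: logistic
  noise_scale_act: 0.7
  noise_scale_util: 4.0
  similarity_scale: 1.0
  threshold: 0.7566569602413102
  utility_gap:
    default: -23.6
cdr3:
  P: 8.0
  S: 2.0
  W_total: 0.55
  boost_increment: 1.0
  help_extra_physical: 29.0
  help_extra_verbal: 21.0
  level: cdr3
  max_attempts: 3
  noise_dist: logistic
  noise_scale_act: 0.85
  noise_scale_util: 5.0
  similarity_scale: 1.0
  threshold: 1.0826536036235601
  utility_gap:
    default: -30.0
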