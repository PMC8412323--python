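apportionment: per_destination
drug_time_days: 2.0
initial_population:
  G-R: 0
  G-Tp: 7
  G-Tr: 7
  GS-R: 0
  GS-Tp: 3
  GS-Tr: 3
  Q: 80
instability: none
name: drug_resistant_stable
rescue: true
rescue_threshold: 10
resistant_death_decay: true
resistant_death_divisor_days: 20.0
resistant_transitions: true
schema: epilock/scenario/1
states:
  G-R:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 2.2
    trans_post: 0.0
    trans_pre: 0.0
  G-Tp:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 1.0
    trans_post: 1.0
    trans_pre: 1.0
  G-Tr:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 1.0
    trans_post: 1.0
    trans_pre: 1.0
  GS-R:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 2.2
    trans_post: 0.0
    trans_pre: 0.0
  GS-Tp:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 1.0
    trans_post: 1.0
    trans_pre: 1.0
  GS-Tr:
    birth_post: 2.0
    birth_pre: 2.0
    death_post: 2.2
    death_pre: 1.0
    trans_post: 1.0
    trans_pre: 1.0
  Q:
    birth_post: 0.0
    birth_pre: 0.0
    death_post: 2.2
    death_pre: 1.0
    trans_post: 1.0
    trans_pre: 1.0
t_max_days: 20.0
units: rate coefficients in day^-1; times in days
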