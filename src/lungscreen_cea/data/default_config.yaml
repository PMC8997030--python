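# Base-case model inputs for the AI-assisted baseline LDCT screening CEA.
# Probabilities/utilities are fractions; any probability-like value may
# instead be written with an explicit unit, e.g. `pretest_prob: {percent: 2.635}`.
pretest_prob: {percent: 2.635}
start_age: 60
horizon_cycles: 20
discount_rate: 0.03
wtp: 100000.0

cost_fp_followup: 2256.0
cost_resection: 36305.0
cost_post_resection_annual: 4283.0
cost_palliative_annual: 60000.0
cost_undetected: 0.0

utility_no_bc: 1.0
utility_fp: 0.98
utility_resection_year1: 0.79
utility_post_resection: 0.933
utility_undetected: 1.0
utility_palliative: 0.63
utility_dead: 0.0

p_resect_early: 0.75
p_resect_delayed: 0.26
p_death_post_resection: 0.047
p_recurrence: 0.098
p_death_palliative: 0.36
p_death_fp_procedural: 0.001
p_verify_fp_as_no_bc: 1.0
detection_schedule: [0.15, 0.40, 1.0]

strategies:
  ct:
    sensitivity: 0.779
    specificity: 0.877
    screen_cost: 161.0
    ai_cost: 0.0
  ct_ai:
    sensitivity: 0.977
    specificity: 0.984
    screen_cost: 161.0
    ai_cost: 0.0
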