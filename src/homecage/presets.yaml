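# Genotype parameter presets for the agent-based simulator.
#
# WT_like is the reference.  The disease-model presets reproduce the
# *direction* of each reported group contrast, not its magnitude (no
# quantitative effect sizes are available for calibration):
#
#   R6/2_like : more repeat visits (perseveration), lower alternation,
#               more licking (especially in the dark), more immobility,
#               less rearing/climbing, a fraction of animals that stop
#               licking on the task (nonlicker attrition).
#   BACHD_like: fewer corner entries, hypoactive (lower speed, more
#               immobility, less climbing), higher collected-reward
#               efficiency, mildly elevated repeats.
#
# Rates are per hour of light-phase time; the dark multiplier applies
# during the dark phase.  Probabilities are dimensionless in [0, 1].
WT_like:
  visit_rate_per_h: 3.0
  dark_activity_multiplier: 2.0
  perseveration_bias: 0.05
  alternation_competence: 0.70
  lick_rate_per_reward: 25.0
  lick_rate_multiplier_dark: 1.2
  poke_side_accuracy: 0.75
  nosepoke_prob: 0.90
  mean_speed_cm_s: 6.0
  immobile_fraction: 0.35
  climb_rate_per_h: 4.0
  nonlicker_prob: 0.0
R6/2_like:
  visit_rate_per_h: 3.0
  dark_activity_multiplier: 1.7
  perseveration_bias: 0.28
  alternation_competence: 0.45
  lick_rate_per_reward: 35.0
  lick_rate_multiplier_dark: 1.5
  poke_side_accuracy: 0.70
  nosepoke_prob: 0.85
  mean_speed_cm_s: 5.0
  immobile_fraction: 0.50
  climb_rate_per_h: 2.0
  nonlicker_prob: 0.10
BACHD_like:
  visit_rate_per_h: 1.8
  dark_activity_multiplier: 2.0
  perseveration_bias: 0.12
  alternation_competence: 0.55
  lick_rate_per_reward: 25.0
  lick_rate_multiplier_dark: 1.2
  poke_side_accuracy: 0.75
  nosepoke_prob: 0.97
  mean_speed_cm_s: 3.5
  immobile_fraction: 0.55
  climb_rate_per_h: 1.5
  nonlicker_prob: 0.0
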