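# Calibrated study-condition defaults for the synthetic cohort generator.
# Version 1: moment-matched to the published group summaries (averaged
# D-score group means/SDs, FAST slope-difference means/SDs, lesbian-group
# per-block slope means, practice-gate failure rate of 10/58).
n_straight: 33
n_lesbian: 25
seed: 0

# IRAP log-normal latency model
base_log_latency: 7.313        # log ms (~1500 ms median)
participant_sd: 0.15           # random intercept SD, log scale
residual_log_sd: 0.25          # trial noise SD, log scale
irap_effect_matrix:            # log-latency increment in the incoherent block
  straight: [0.1050, 0.0735, -0.0341, -0.0394]   # trial-types 1..4
  lesbian: [-0.0111, 0.1084, 0.2168, 0.1612]
effect_participant_sd:         # participant-level shift of the increment
  straight: 0.07
  lesbian: 0.09
long_latency_rate: 0.01
fast_responder_rate: 0.0
fast_responder_trial_rate: 0.25
practice_fail_rate: 0.557      # per practice pair; (10/58)^(1/3) overall

# FAST learning curves
fast_p0: 0.35
fast_pinf: 0.95
fast_learn_rate:
  straight: {straight_block: 0.0150, lesbian_block: 0.0130}
  lesbian: {straight_block: 0.0054, lesbian_block: 0.0271}
fast_kappa_sd: 0.6             # per-participant, per-block log-scale SD
fast_timeout_rate: 0.02

# KSOG
ksog_group_means: {straight: 1.45, lesbian: 4.3}
ksog_group_sds: {straight: 0.55, lesbian: 0.55}
ksog_cell_sd: 0.8
n_ksog_missing_lesbian: 4
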