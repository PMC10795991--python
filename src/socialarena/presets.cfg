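# Cohort presets for the agent-based arena simulator (flat key-value text).
# Units: speeds mm/s, lengths mm, angles rad/step. social_coeff > 0 is
# attraction toward the neighborhood centroid, < 0 avoidance.
#
# mated_like    : low locomotor activity, mild social attraction
# naive_like    : high locomotor activity, mild social attraction
# rejected_like : high locomotor activity, social avoidance

mated_like.n_agents = 10
mated_like.mean_speed = 3.0
mated_like.speed_shape = 2.0
mated_like.turn_sd = 0.25
mated_like.social_coeff = 0.05
mated_like.sensing_radius = 16.0
mated_like.max_turn = 0.5
mated_like.body_a = 1.2
mated_like.body_b = 0.6

naive_like.n_agents = 10
naive_like.mean_speed = 6.0
naive_like.speed_shape = 2.0
naive_like.turn_sd = 0.25
naive_like.social_coeff = 0.05
naive_like.sensing_radius = 16.0
naive_like.max_turn = 0.5
naive_like.body_a = 1.2
naive_like.body_b = 0.6

rejected_like.n_agents = 10
rejected_like.mean_speed = 6.0
rejected_like.speed_shape = 2.0
rejected_like.turn_sd = 0.25
rejected_like.social_coeff = -0.10
rejected_like.sensing_radius = 16.0
rejected_like.max_turn = 0.5
rejected_like.body_a = 1.2
rejected_like.body_b = 0.6
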