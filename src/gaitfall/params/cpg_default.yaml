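# Default network constants for the 14-neuron walker CPG.
#
# Everything here is the frozen calibration of the package: the coupling
# matrix, the torque-channel map for the 18 transfer coefficients p_k,
# the sensory-feedback gains and the absolute neural time constants.
# The per-model quantities (u0, tau ratio, p_k values, noise) live in
# gaitfall.models; this file holds what is shared by all gait models.

schema: 1

beta: 2.5

# Absolute inner-state time constant tau (s), uniform over neurons.
# tau' follows from the gait model's tau/tau' ratio.  Per-model overrides
# set the oscillator period so cadence lands in the human range.
tau_default: 0.0053724937839842645

# Coupling weights, listed as "target <- source: weight".  Pairs within
# one oscillator inhibit each other; left and right hip oscillators
# inhibit their mirror neuron (antiphase coordination); hip neurons
# excite the ipsilateral knee and ankle neuron of the same function
# (descending coordination).  Unlisted entries are zero.
weights:
  - [trunk_f,  trunk_e,  -2.0]
  - [trunk_e,  trunk_f,  -2.0]
  - [hip_r_e,  hip_r_f,  -2.0]
  - [hip_r_f,  hip_r_e,  -2.0]
  - [hip_l_e,  hip_l_f,  -2.0]
  - [hip_l_f,  hip_l_e,  -2.0]
  - [knee_r_e, knee_r_f, -2.0]
  - [knee_r_f, knee_r_e, -2.0]
  - [knee_l_e, knee_l_f, -2.0]
  - [knee_l_f, knee_l_e, -2.0]
  - [ankle_r_e, ankle_r_f, -2.0]
  - [ankle_r_f, ankle_r_e, -2.0]
  - [ankle_l_e, ankle_l_f, -2.0]
  - [ankle_l_f, ankle_l_e, -2.0]
  - [hip_r_f,  hip_l_f,  -1.0]
  - [hip_l_f,  hip_r_f,  -1.0]
  - [hip_r_e,  hip_l_e,  -1.0]
  - [hip_l_e,  hip_r_e,  -1.0]
  - [knee_r_f, hip_r_f,   0.6]
  - [knee_l_f, hip_l_f,   0.6]
  - [knee_r_e, hip_r_e,   0.6]
  - [knee_l_e, hip_l_e,   0.6]
  - [ankle_r_f, hip_r_f,  0.6]
  - [ankle_l_f, hip_l_f,  0.6]
  - [ankle_r_e, hip_r_e,  0.6]
  - [ankle_l_e, hip_l_e,  0.6]

# Torque-channel map: one line per additive term,
#   [channel k (1-based), joint, neuron, sign, gate]
# gate: none | stance | swing | contra_stance | contra_swing
# (stance/swing refer to the joint's own side; scaled by foot load).
channels:
  - [1, trunk, trunk_e, 4.459025612401524, none]
  - [2, trunk, trunk_f, -0.5737508266608952, none]
  - [3, hip_r, hip_r_f, 0.7036773437161383, swing]
  - [3, hip_l, hip_l_f, 0.7036773437161383, swing]
  - [4, knee_r, knee_r_f, -0.06573646334608226, swing]
  - [4, knee_l, knee_l_f, -0.06573646334608226, swing]
  - [5, hip_r, hip_r_e, -0.5716347188923384, stance]
  - [5, hip_l, hip_l_e, -0.5716347188923384, stance]
  - [6, knee_r, knee_r_e, 6.517107809968453, none]
  - [6, knee_l, knee_l_e, 6.517107809968453, none]
  - [7, ankle_r, ankle_r_f, 0.2950606100258039, none]
  - [7, ankle_l, ankle_l_f, 0.2950606100258039, none]
  - [8, ankle_r, ankle_r_e, -0.22000539354551704, stance]
  - [8, ankle_l, ankle_l_e, -0.22000539354551704, stance]
  - [9, knee_r, knee_r_e, 2.4603008177076418, stance]
  - [9, knee_l, knee_l_e, 2.4603008177076418, stance]
  - [10, hip_r, hip_r_f, 0.192925030915138, none]
  - [10, hip_l, hip_l_f, 0.192925030915138, none]
  - [11, hip_r, hip_r_e, -0.9003277980572275, none]
  - [11, hip_l, hip_l_e, -0.9003277980572275, none]
  - [12, knee_r, knee_r_f, -0.2257215482565025, none]
  - [12, knee_l, knee_l_f, -0.2257215482565025, none]
  - [13, ankle_r, ankle_r_e, -0.28791977626388576, contra_stance]
  - [13, ankle_l, ankle_l_e, -0.28791977626388576, contra_stance]
  - [14, ankle_r, ankle_r_f, 0.7426804397991702, swing]
  - [14, ankle_l, ankle_l_f, 0.7426804397991702, swing]
  - [15, hip_r, hip_r_f, 0.24775102175797145, contra_stance]
  - [15, hip_l, hip_l_f, 0.24775102175797145, contra_stance]
  - [16, knee_r, knee_r_e, 0.5953014711293608, contra_swing]
  - [16, knee_l, knee_l_e, 0.5953014711293608, contra_swing]
  - [17, ankle_r, ankle_r_f, 0.4094340537736341, stance]
  - [17, ankle_l, ankle_l_f, 0.4094340537736341, stance]
  - [18, hip_r, hip_r_e, -0.9888726461133728, contra_swing]
  - [18, hip_l, hip_l_e, -0.9888726461133728, contra_swing]

# Global gain applied to the whole active-torque map (calibrates the
# overall muscle strength of the walker without touching the relative
# p_k structure).
torque_scale: 1.0

# Sensory-feedback gains (see gaitfall.cpg.sensory_feedback):
#   [trunk verticality, hip inter-thigh posture, hip load transfer,
#    knee load, ankle load, pelvis righting, late-swing retraction,
#    retraction threshold (rad), pelvis pitch-rate damping,
#    speed-dependent step-length gain (rad per m/s)]
feedback_gains: [76.82035550993756, 1.1519776559938124, 8.820059981590173, 2.0893538527833155, 0.9382797153422071, 69.31607253802301, 453.6777944372122, 0.10385353547418352, 1.3447860524337454, 0.22820612131735024]
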