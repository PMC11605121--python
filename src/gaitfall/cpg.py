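"""Central pattern generator: a 14-neuron Matsuoka oscillator network.

One two-neuron oscillator sits at each of the seven joints (trunk, hips,
knees, ankles); the two neurons drive the flexor and extensor muscle
systems of that joint.  Each neuron is a leaky integrator with an
adaptation (self-inhibition) state:

    tau_i  du_i/dt = -u_i - beta f(v_i) + sum_j w_ij f(u_j) + u0 + S_i
    tau'_i dv_i/dt = -v_i + f(u_i)
    f(u) = max(0, u)

``u0`` is the nonspecific tonic drive (white noise is added to it as a
percentage, see :mod:`gaitfall.models`), ``S_i`` the sensory feedback.
Any direct input from other neurons is carried by the weighted coupling
sum; there is no separate pathway.  The coupling term is implemented as
``sum_j w_ij f(u_j)``; a literal-reading switch replacing ``f(u_j)`` by
``f(u_i)`` (which turns the sum into a self-term) is kept for comparison
only.

Rectified neuron outputs are converted to the seven joint torques through
18 weighted channels with transfer coefficients ``p_k``.  Channels may be
load-gated: a term is scaled by how much weight the joint's own (or the
contralateral) foot currently bears, which lets stance support and swing
shaping use the same oscillator with different gains.

Neuron index convention (0-based):

====  ==========================  ====  ==========================
idx   role                        idx   role
====  ==========================  ====  ==========================
0     trunk extensor              7     R knee extensor
1     trunk flexor                8     L knee flexor
2     R hip flexor                9     L knee extensor
3     R hip extensor              10    R ankle dorsiflexor
4     L hip flexor                11    R ankle plantarflexor
5     L hip extensor              12    L ankle dorsiflexor
6     R knee flexor               13    L ankle plantarflexor
====  ==========================  ====  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import JOINT_NAMES

__all__ = [
    "CPGParameters",
    "NeuralState",
    "JointLimits",
    "NEURON_NAMES",
    "rectify",
    "neuron_derivatives",
    "active_torques",
    "passive_torques",
    "sensory_feedback",
]

N_NEURONS = 14
N_JOINTS = 7
N_CHANNELS = 18

NEURON_NAMES = (
    "trunk_e", "trunk_f",
    "hip_r_f", "hip_r_e", "hip_l_f", "hip_l_e",
    "knee_r_f", "knee_r_e", "knee_l_f", "knee_l_e",
    "ankle_r_f", "ankle_r_e", "ankle_l_f", "ankle_l_e",
)

# Gate codes for torque-channel terms.
GATE_NONE = 0          # always on
GATE_STANCE = 1        # scaled by ipsilateral foot load (0..1)
GATE_SWING = 2         # scaled by 1 - ipsilateral foot load
GATE_CONTRA_STANCE = 3
GATE_CONTRA_SWING = 4

#: Which side each joint belongs to: +1 right, -1 left, 0 midline (trunk).
JOINT_SIDE = (0, +1, -1, +1, -1, +1, -1)

#: Thigh angle (rad, forward of vertical) beyond which the late-swing
#: retraction reflex engages.
RETRACT_THRESHOLD = 0.20


@dataclass
class NeuralState:
    """Inner states ``u`` and adaptation states ``v`` of the 14 neurons."""

    u: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))
    v: np.ndarray = field(default_factory=lambda: np.zeros(N_NEURONS))

    def copy(self) -> "NeuralState":
        return NeuralState(self.u.copy(), self.v.copy())

    @property
    def outputs(self) -> np.ndarray:
        return np.maximum(0.0, self.u)


@dataclass
class CPGParameters:
    """All constants of the oscillator network and its torque mapping.

    ``tau`` and ``tau_a`` are the inner-state and adaptation time
    constants (s); their ratio is the gait model's signature.  ``weights``
    is the 14x14 coupling matrix (zero diagonal).  ``p`` holds the 18
    torque transfer coefficients; the channel-term arrays define, for each
    additive term, which channel/neuron/joint it connects, its sign, and
    its load gate.  ``feedback_gains`` are the sensory gains (see
    :func:`sensory_feedback`).
    """

    tau: np.ndarray                  # (14,) s
    tau_a: np.ndarray                # (14,) s
    beta: float
    weights: np.ndarray              # (14, 14)
    u0: float
    noise_pct: float                 # SD of white noise, % of u0
    p: np.ndarray                    # (18,)
    term_channel: np.ndarray         # (n_terms,) int, 0-based channel index
    term_neuron: np.ndarray          # (n_terms,) int
    term_joint: np.ndarray           # (n_terms,) int
    term_sign: np.ndarray            # (n_terms,) float weight; sign sets direction
    term_gate: np.ndarray            # (n_terms,) int gate code
    feedback_gains: np.ndarray       # (6,): trunk, hip posture, hip load, knee,
                                     #       ankle, pelvis righting
    torque_scale: float = 1.0        # global gain on the active-torque map
    literal_self_coupling: bool = False

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0) or np.any(self.tau_a <= 0):
            raise ValueError("time constants must be strictly positive")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("coupling matrix must have a zero diagonal")
        if np.any(self.p < 0):
            raise ValueError("transfer coefficients p_k must be non-negative")
        ratios = self.tau / self.tau_a
        if not np.allclose(ratios, ratios[0]):
            raise ValueError("tau_i / tau'_i must be uniform across neurons")


def rectify(u):
    """Threshold-linear neuron output f(u) = max(0, u)."""
    return np.maximum(0.0, u)


def neuron_derivatives(
    neural: NeuralState,
    params: CPGParameters,
    feedback: np.ndarray,
    noisy_u0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (du, dv) of the oscillator network."""
    fu = np.maximum(0.0, neural.u)
    fv = np.maximum(0.0, neural.v)
    if params.literal_self_coupling:
        coupling = params.weights.sum(axis=1) * fu
    else:
        coupling = params.weights @ fu
    du = (-neural.u - params.beta * fv + coupling + noisy_u0 + feedback) / params.tau
    dv = (-neural.v + fu) / params.tau_a
    return du, dv


def active_torques(
    outputs: np.ndarray,
    params: CPGParameters,
    load_r: float = 1.0,
    load_l: float = 1.0,
) -> np.ndarray:
    """Joint torques from rectified neuron outputs via the 18 p-channels.

    ``load_r``/``load_l`` are the per-foot load fractions in [0, 1] used
    by the gated channels.  The map is linear in ``outputs`` at fixed
    loads.  Torque sign convention: positive = counterclockwise on the
    distal segment (flexion for hips and ankle dorsiflexion; knee flexion
    is negative).
    """
    ta = np.zeros(N_JOINTS)
    loads = (0.0, load_r, load_l)  # indexed by JOINT_SIDE: 0 -> midline
    for ch, neu, jnt, sgn, gate in zip(
        params.term_channel, params.term_neuron, params.term_joint,
        params.term_sign, params.term_gate,
    ):
        g = 1.0
        side = JOINT_SIDE[jnt]
        if gate == GATE_STANCE:
            g = loads[1] if side > 0 else loads[2]
        elif gate == GATE_SWING:
            g = 1.0 - (loads[1] if side > 0 else loads[2])
        elif gate == GATE_CONTRA_STANCE:
            g = loads[2] if side > 0 else loads[1]
        elif gate == GATE_CONTRA_SWING:
            g = 1.0 - (loads[2] if side > 0 else loads[1])
        ta[jnt] += sgn * params.p[ch] * g * outputs[neu]
    return params.torque_scale * ta


@dataclass
class JointLimits:
    """Viscoelastic joint-limit model plus light always-on viscosity.

    Inside the neutral range only the viscous term ``-b_visc * dtheta``
    acts; beyond a limit a stiff spring ``k_stop`` and damper ``b_stop``
    push the joint back.  Angles are the relative joint angles
    ``theta_distal - theta_proximal`` in the order of ``JOINT_NAMES``.
    """

    lower: np.ndarray = field(default_factory=lambda: np.array(
        [-0.10, -0.45, -0.45, -2.40, -2.40, -0.80, -0.80]))
    upper: np.ndarray = field(default_factory=lambda: np.array(
        [0.10, 1.20, 1.20, 0.00, 0.00, 0.60, 0.60]))
    k_stop: float = 4_000.0
    b_stop: float = 150.0
    b_visc: float = 3.0


# joint -> (proximal segment, distal segment) indices into SEGMENT_NAMES
JOINT_SEGMENTS = ((1, 0), (1, 2), (1, 3), (2, 4), (3, 5), (4, 6), (5, 7))


def joint_angles(theta: np.ndarray) -> np.ndarray:
    """Relative joint angles theta_distal - theta_proximal (7,)."""
    return np.array([theta[d] - theta[p] for p, d in JOINT_SEGMENTS])


def passive_torques(
    theta: np.ndarray,
    theta_dot: np.ndarray,
    limits: JointLimits | None = None,
) -> np.ndarray:
    """Passive joint torque vector (7,) from limits and viscosity.

    The returned torque acts positively (counterclockwise) on the distal
    segment and with opposite sign on the proximal one.  At neutral
    angles with zero rates the result is exactly zero.
    """
    if limits is None:
        limits = JointLimits()
    q = joint_angles(theta)
    qd = joint_angles(theta_dot)
    tp = -limits.b_visc * qd
    over = q - limits.upper
    under = limits.lower - q
    hi = over > 0
    lo = under > 0
    tp[hi] += -limits.k_stop * over[hi] - limits.b_stop * np.maximum(0.0, qd[hi])
    tp[lo] += limits.k_stop * under[lo] - limits.b_stop * np.minimum(0.0, qd[lo])
    return tp


def sensory_feedback(
    theta: np.ndarray,
    load_r: float,
    load_l: float,
    gains: np.ndarray,
    theta_dot: np.ndarray | None = None,
    com_vx: float = 0.0,
) -> np.ndarray:
    """Posture- and load-dependent feedback S_i to the 14 neurons.

    The signals implement the classic entrainment pathways of
    oscillator-driven walkers: trunk-verticality error to the trunk pair,
    inter-thigh angle and contralateral load to the hip pairs, own-side
    load to knee extensor / unload to knee flexor, shank lean during
    stance to the plantarflexor and unload to the dorsiflexor.  The map
    is exactly left/right mirror symmetric.

    ``gains`` = (g_trunk, g_hip_posture, g_hip_load, g_knee, g_ankle,
    g_pelvis, g_retract).  ``g_pelvis`` routes pelvis verticality error
    into the hip neurons, which is how the legs right the torso: a
    forward tilt recruits the hip extensors, a backward tilt the
    flexors.  ``g_retract`` is the late-swing retraction reflex: once an
    unloaded thigh swings past :data:`RETRACT_THRESHOLD`, its hip and
    knee extensor neurons are recruited, capping the stride and
    straightening the leg for landing.
    """
    g_tr, g_hip, g_load, g_knee, g_ank, g_pel, g_ret = gains[:7]
    thr = gains[7] if len(gains) > 7 else RETRACT_THRESHOLD
    g_pd = gains[8] if len(gains) > 8 else 0.0
    c_v = gains[9] if len(gains) > 9 else 0.0
    if theta_dot is None:
        theta_dot = np.zeros_like(theta)
    th_hat = theta[0]
    th_pel = theta[1]
    th_thr, th_thl = theta[2], theta[3]
    th_shr, th_shl = theta[4], theta[5]
    s = np.zeros(N_NEURONS)
    # trunk: positive theta_HAT = backward lean; extensor restores from forward lean
    s[0] = g_tr * max(0.0, -th_hat)
    s[1] = g_tr * max(0.0, th_hat)
    # hips: swing the unloaded, trailing leg forward
    drive_r = g_hip * (th_thl - th_thr) + g_load * (load_l - load_r)
    s[2], s[3] = drive_r, -drive_r
    s[4], s[5] = -drive_r, drive_r
    # pelvis righting through the hips (forward tilt = negative angle)
    s[2] += g_pel * max(0.0, th_pel)
    s[4] += g_pel * max(0.0, th_pel)
    s[3] += g_pel * max(0.0, -th_pel)
    s[5] += g_pel * max(0.0, -th_pel)
    # pelvis pitch-rate damping through the same pathways
    pd = theta_dot[1]
    s[2] += g_pd * max(0.0, pd)
    s[4] += g_pd * max(0.0, pd)
    s[3] += g_pd * max(0.0, -pd)
    s[5] += g_pd * max(0.0, -pd)
    # late-swing retraction reflex
    thr_eff = thr + c_v * com_vx
    ret_r = g_ret * (1.0 - load_r) * max(0.0, th_thr - thr_eff)
    ret_l = g_ret * (1.0 - load_l) * max(0.0, th_thl - thr_eff)
    s[3] += ret_r
    s[5] += ret_l
    # knees: extend under load, release in swing, extend for landing
    s[6], s[7] = g_knee * (1.0 - load_r), g_knee * load_r + ret_r
    s[8], s[9] = g_knee * (1.0 - load_l), g_knee * load_l + ret_l
    # ankles: bidirectional stance ankle strategy (plantarflex against a
    # forward-rolling shank, dorsiflex against a backward lean), and
    # dorsiflex the unloaded foot for toe clearance
    s[10] = g_ank * (1.0 - load_r) + g_ank * load_r * max(0.0, th_shr)
    s[11] = g_ank * load_r * max(0.0, -th_shr)
    s[12] = g_ank * (1.0 - load_l) + g_ank * load_l * max(0.0, th_shl)
    s[13] = g_ank * load_l * max(0.0, -th_shl)
    return s
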