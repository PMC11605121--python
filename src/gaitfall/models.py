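"""Registry of the three gait models and the tonic-drive noise mechanism.

Three named parameterizations of the CPG — ``young`` (young adult),
``elderly_nonfaller`` and ``elderly_faller`` — differ only in the tonic
drive ``u0``, the time-constant ratio ``tau/tau'``, the 18 torque
transfer coefficients ``p_k`` and the white-noise level on ``u0``:

=================   ======  =============  ==========
quantity            young   non-faller     faller
=================   ======  =============  ==========
u0                  7.08    5.16           5.10
tau/tau'            0.036   0.100          0.076
noise (% of u0)     8.50    2.00           0.100
p_k                 base    base           reduced
=================   ======  =============  ==========

The non-faller shares the young p_k column; the faller's p_k are reduced,
most strongly on the swing-shaping channels (hip/knee flexion, swing
dorsiflexion), which is what lowers its foot clearance.  White noise is
multiplicative: each neural update draws ``u0 * (1 + (noise/100) * eps)``
with a single standard-normal ``eps`` shared by all 14 neurons.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import yaml

from .cpg import (
    CPGParameters,
    GATE_CONTRA_STANCE,
    GATE_CONTRA_SWING,
    GATE_NONE,
    GATE_STANCE,
    GATE_SWING,
    N_NEURONS,
    NEURON_NAMES,
)
from .anthropometry import JOINT_NAMES

__all__ = ["GaitModelSpec", "MODEL_NAMES", "build_gait_model", "build_cpg_parameters",
           "noisy_u0", "load_network_config", "export_parameters"]

MODEL_NAMES = ("young", "elderly_nonfaller", "elderly_faller")

_P_YOUNG = np.array(
    [5.00, 10.00, 4.00, 2.00, 15.00, 4.00, 3.00, 2.00, 15.00,
     8.00, 2.00, 3.00, 2.00, 8.00, 1.50, 12.00, 1.00, 7.00]
)
_P_FALLER = np.array(
    [4.75, 9.50, 2.66, 0.86, 12.83, 3.42, 2.85, 1.90, 14.25,
     7.60, 1.90, 2.85, 1.90, 3.92, 0.90, 10.26, 0.86, 5.99]
)

# Per-model absolute inner-state time constant tau (s).  The tau/tau'
# ratio is fixed by the model definition; tau itself is the package's
# cadence calibration (slower oscillators for the elderly models).
_TAU = {"young": 0.0053724937839842645, "elderly_nonfaller": 0.011473076750599548, "elderly_faller": 0.00962730810426266}


@dataclass(frozen=True)
class GaitModelSpec:
    """One named gait parameterization."""

    name: str
    u0: float
    tau_ratio: float        # tau_i / tau'_i, uniform over neurons
    p: np.ndarray           # (18,) transfer coefficients
    noise_pct: float        # SD of white noise on u0, percent of u0

    def __post_init__(self):
        if len(self.p) != 18:
            raise ValueError("expected 18 transfer coefficients")


_REGISTRY = {
    "young": dict(u0=7.08, tau_ratio=0.036, p=_P_YOUNG, noise_pct=8.50),
    "elderly_nonfaller": dict(u0=5.16, tau_ratio=0.100, p=_P_YOUNG, noise_pct=2.00),
    "elderly_faller": dict(u0=5.10, tau_ratio=0.076, p=_P_FALLER, noise_pct=0.100),
}


def build_gait_model(name: str) -> GaitModelSpec:
    """Return the frozen parameter set of one of the three gait models."""
    try:
        kw = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown gait model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None
    return GaitModelSpec(name=name, **kw)


def noisy_u0(spec: GaitModelSpec, rng: np.random.Generator) -> float:
    """One noisy draw of the tonic drive: u0 * (1 + (noise%/100) * eps)."""
    return spec.u0 * (1.0 + spec.noise_pct / 100.0 * rng.standard_normal())


_GATE_CODES = {
    "none": GATE_NONE,
    "stance": GATE_STANCE,
    "swing": GATE_SWING,
    "contra_stance": GATE_CONTRA_STANCE,
    "contra_swing": GATE_CONTRA_SWING,
}


def load_network_config(path=None) -> dict:
    """Load the shared network constants (weights, channel map, gains).

    With no argument, the packaged default parameter file is used.
    """
    if path is None:
        text = resources.files("gaitfall").joinpath("params/cpg_default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if cfg.get("schema") != 1:
        raise ValueError("unsupported network parameter file schema")
    return cfg


def build_cpg_parameters(
    spec: GaitModelSpec,
    network: dict | None = None,
    literal_self_coupling: bool = False,
) -> CPGParameters:
    """Merge a gait model with the shared network constants."""
    cfg = network if network is not None else load_network_config()
    W = np.zeros((N_NEURONS, N_NEURONS))
    for tgt, src, w in cfg["weights"]:
        W[NEURON_NAMES.index(tgt), NEURON_NAMES.index(src)] = float(w)
    ch, neu, jnt, sgn, gate = [], [], [], [], []
    for k, joint, neuron, sign, g in cfg["channels"]:
        ch.append(int(k) - 1)
        jnt.append(JOINT_NAMES.index(joint))
        neu.append(NEURON_NAMES.index(neuron))
        sgn.append(float(sign))
        gate.append(_GATE_CODES[g])
    tau = float(cfg.get("tau_default", 0.115))
    tau = _TAU.get(spec.name, tau)
    tau_vec = np.full(N_NEURONS, tau)
    return CPGParameters(
        tau=tau_vec,
        tau_a=tau_vec / spec.tau_ratio,
        beta=float(cfg["beta"]),
        weights=W,
        u0=spec.u0,
        noise_pct=spec.noise_pct,
        p=np.asarray(spec.p, dtype=float),
        term_channel=np.array(ch, dtype=np.int64),
        term_neuron=np.array(neu, dtype=np.int64),
        term_joint=np.array(jnt, dtype=np.int64),
        term_sign=np.array(sgn, dtype=float),
        term_gate=np.array(gate, dtype=np.int64),
        feedback_gains=np.asarray(cfg["feedback_gains"], dtype=float),
        torque_scale=float(cfg.get("torque_scale", 1.0)),
        literal_self_coupling=literal_self_coupling,
    )


def export_parameters(spec: GaitModelSpec, path) -> None:
    """Dump the fully resolved parameter set to a key-value file."""
    params = build_cpg_parameters(spec)
    doc = {
        "model": spec.name,
        "u0": spec.u0,
        "tau_ratio": spec.tau_ratio,
        "noise_pct": spec.noise_pct,
        "tau": params.tau.tolist(),
        "tau_adaptation": params.tau_a.tolist(),
        "beta": params.beta,
        "p": params.p.tolist(),
        "weights": params.weights.tolist(),
        "feedback_gains": params.feedback_gains.tolist(),
        "torque_scale": params.torque_scale,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
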