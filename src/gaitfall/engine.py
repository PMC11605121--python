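"""Time integration of the coupled mechanical + neural walker system.

Two implementations of the same dynamics live here:

* :func:`integrate_step` — a readable reference path composed from the
  public module functions (:mod:`gaitfall.dynamics`,
  :mod:`gaitfall.contact`, :mod:`gaitfall.cpg`), advancing one fixed
  RK4 step.  Used by tests and for small experiments.
* :func:`simulate_trial` — the production driver: a fused, numba-compiled
  loop over the whole trial that advances the 24 mechanical coordinates,
  their rates and the 28 neural states together, resolves the joint
  constraints through a Schur-complement solve each stage, applies the
  friction cap, resets contact anchors between steps, and records a
  decimated trajectory.  A unit test pins the two paths to each other.

The integrator is fixed-step classical Runge-Kutta at ``dt = 2e-4 s``
(the ground springs at ~27 kN/m set the fastest time scale); contact
anchors, contact flags and the noisy tonic drive are held constant
within a step and updated between steps, which keeps every trial exactly
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .anthropometry import AnthropometricSet, build_anthropometry
from .contact import ContactState, GroundModel, ground_reaction, friction_cap, update_anchors
from .cpg import (
    CPGParameters, JointLimits, NeuralState,
    active_torques, neuron_derivatives, passive_torques, sensory_feedback,
    JOINT_SEGMENTS,
)
from .dynamics import (
    BodyState, NumericalError, assemble_state, compute_accelerations,
    contact_attachments, contact_point_states, joint_attachments, whole_body_com,
)
from .trajectory import Trajectory

__all__ = ["RunConfig", "SimStatus", "simulate_trial", "integrate_step", "initial_conditions"]

#: Vertical force (N) at which a foot counts as fully loaded for the
#: CPG's load gates and sensory feedback.
LOAD_SAT_N = 250.0

BAUMGARTE_ALPHA = 400.0


@dataclass(frozen=True)
class RunConfig:
    """Protocol and numerics for a single trial.

    Defaults implement the standard protocol: walk 15 m; the static
    friction coefficient is unset for the first 5 m and switched on at
    ``switch_x``; falls are scored on hip height < 0.70 m within the
    5-15 m window; slips on stance-foot speed > 0.3 m/s with a 10 ms
    debounce.  The first ``transient_x`` metres are start-up transient
    and excluded from gait metrics.
    """

    dt: float = 2e-4
    integrator: str = "rk4"
    record_every: int = 5          # decimation: 5 -> 1 kHz at default dt
    total_distance: float = 15.0
    switch_x: float = 5.0
    mu_s: float | None = None      # None = friction never set (cap off)
    t_max: float = 40.0
    fall_hip_height: float = 0.70
    slip_speed: float = 0.30
    debounce_s: float = 0.010
    transient_x: float = 2.0
    min_hip_stop: float = 0.35     # hard stop once the walker is down
    init_split: float = 0.180928843922703       # initial fore-aft leg split (rad)
    init_speed: float = 1.2083713679871524        # initial forward CoM speed (m/s)

    def friction_segments(self):
        if self.mu_s is None:
            return []
        return [(self.switch_x, np.inf, self.mu_s)]


@dataclass
class SimStatus:
    """Outcome flags of one integration run."""

    code: int                      # 0 finished, 1 walker down, 2 time out, 3 diverged
    t_end: float
    x_end: float

    @property
    def diverged(self) -> bool:
        return self.code == 3

    @property
    def label(self) -> str:
        return ("finished", "down", "timeout", "diverged")[self.code]


# ----------------------------------------------------------------------
# fused numba path
# ----------------------------------------------------------------------

@njit(cache=True)
def _deriv(q, qd, u, v, u0_now, anchor_x, in_contact,
           mass, inertia, jp, jd, jrp, jrd, cseg, cr,
           kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
           tau, tau_a, beta, W, fbg, p,
           tch, tneu, tjnt, tsgn, tgate, tq_scale,
           lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha):
    x = q[:8]; y = q[8:16]; th = q[16:24]
    xd = qd[:8]; yd = qd[8:16]; thd = qd[16:24]

    # ---- ground reaction at the 4 contact points
    grf = np.zeros((4, 2))
    for n in range(4):
        s = cseg[n]
        c = np.cos(th[s]); sn = np.sin(th[s])
        dx = c * cr[n, 0] - sn * cr[n, 1]
        dy = sn * cr[n, 0] + c * cr[n, 1]
        px = x[s] + dx; py = y[s] + dy
        vx = xd[s] - thd[s] * dy; vy = yd[s] + thd[s] * dx
        pen = -py
        if pen > 0.0:
            ind = 100.0 * pen
            if ind > 1.0:
                ind = 1.0
            ax = anchor_x[n] if in_contact[n] else px
            fgx = (-kgx * (px - ax) - bgx * vx) * ind
            dmp = -vy
            if dmp < 0.0:
                dmp = 0.0
            fgy = (-kgy * py + bgy * dmp) * ind
            if fgy < 0.0:
                fgy = 0.0
            # friction cap from the schedule under the point
            mu = np.nan
            for k in range(fs_x0.shape[0]):
                if fs_x0[k] <= px < fs_x1[k]:
                    mu = fs_mu[k]
                    break
            if mu == mu:  # set
                lim = mu * fgy
                if fgx > lim:
                    fgx = lim
                elif fgx < -lim:
                    fgx = -lim
            grf[n, 0] = fgx
            grf[n, 1] = fgy

    load_r = (grf[0, 1] + grf[1, 1]) / LOAD_SAT_N
    load_l = (grf[2, 1] + grf[3, 1]) / LOAD_SAT_N
    if load_r > 1.0:
        load_r = 1.0
    if load_l > 1.0:
        load_l = 1.0

    # ---- sensory feedback
    s_fb = np.zeros(14)
    g_tr, g_hip, g_load = fbg[0], fbg[1], fbg[2]
    g_knee, g_ank, g_pel, g_ret = fbg[3], fbg[4], fbg[5], fbg[6]
    thr = fbg[7] if fbg.shape[0] > 7 else 0.20
    g_pd = fbg[8] if fbg.shape[0] > 8 else 0.0
    c_v = fbg[9] if fbg.shape[0] > 9 else 0.0
    if c_v != 0.0:
        com_vx = 0.0
        mtot = 0.0
        for sseg in range(8):
            com_vx += mass[sseg] * xd[sseg]
            mtot += mass[sseg]
        com_vx /= mtot
        thr = thr + c_v * com_vx
    th_hat = th[0]
    th_pel = th[1]
    s_fb[0] = g_tr * max(0.0, -th_hat)
    s_fb[1] = g_tr * max(0.0, th_hat)
    drive_r = g_hip * (th[3] - th[2]) + g_load * (load_l - load_r)
    s_fb[2] = drive_r; s_fb[3] = -drive_r
    s_fb[4] = -drive_r; s_fb[5] = drive_r
    s_fb[2] += g_pel * max(0.0, th_pel)
    s_fb[4] += g_pel * max(0.0, th_pel)
    s_fb[3] += g_pel * max(0.0, -th_pel)
    s_fb[5] += g_pel * max(0.0, -th_pel)
    pd = thd[1]
    s_fb[2] += g_pd * max(0.0, pd)
    s_fb[4] += g_pd * max(0.0, pd)
    s_fb[3] += g_pd * max(0.0, -pd)
    s_fb[5] += g_pd * max(0.0, -pd)
    # late-swing retraction reflex (thigh past 0.20 rad while unloaded)
    ret_r = g_ret * (1.0 - load_r) * max(0.0, th[2] - thr)
    ret_l = g_ret * (1.0 - load_l) * max(0.0, th[3] - thr)
    s_fb[3] += ret_r
    s_fb[5] += ret_l
    s_fb[6] = g_knee * (1.0 - load_r); s_fb[7] = g_knee * load_r + ret_r
    s_fb[8] = g_knee * (1.0 - load_l); s_fb[9] = g_knee * load_l + ret_l
    s_fb[10] = g_ank * (1.0 - load_r) + g_ank * load_r * max(0.0, th[4])
    s_fb[11] = g_ank * load_r * max(0.0, -th[4])
    s_fb[12] = g_ank * (1.0 - load_l) + g_ank * load_l * max(0.0, th[5])
    s_fb[13] = g_ank * load_l * max(0.0, -th[5])

    # ---- neural derivatives
    fu = np.maximum(0.0, u)
    fv = np.maximum(0.0, v)
    du = np.empty(14)
    dv = np.empty(14)
    for i in range(14):
        coup = 0.0
        for j in range(14):
            coup += W[i, j] * fu[j]
        du[i] = (-u[i] - beta * fv[i] + coup + u0_now + s_fb[i]) / tau[i]
        dv[i] = (-v[i] + fu[i]) / tau_a[i]

    # ---- joint torques
    ta = np.zeros(7)
    for t in range(tch.shape[0]):
        jnt = tjnt[t]
        gate = tgate[t]
        g = 1.0
        if gate != 0:
            own = load_r if (jnt == 1 or jnt == 3 or jnt == 5) else load_l
            other = load_l if (jnt == 1 or jnt == 3 or jnt == 5) else load_r
            if jnt == 0:
                g = 1.0
            elif gate == 1:
                g = own
            elif gate == 2:
                g = 1.0 - own
            elif gate == 3:
                g = other
            elif gate == 4:
                g = 1.0 - other
        ta[jnt] += tq_scale * tsgn[t] * p[tch[t]] * g * fu[tneu[t]]

    tp = np.zeros(7)
    for j in range(7):
        rel = th[jd[j]] - th[jp[j]]
        reld = thd[jd[j]] - thd[jp[j]]
        tq = -b_visc * reld
        if rel > lim_hi[j]:
            ex = rel - lim_hi[j]
            tq += -k_stop * ex - b_stop * max(0.0, reld)
        elif rel < lim_lo[j]:
            ex = lim_lo[j] - rel
            tq += k_stop * ex - b_stop * min(0.0, reld)
        tp[j] = tq

    # ---- generalized forces
    Q = np.zeros(24)
    for s in range(8):
        Q[8 + s] = -mass[s] * 9.81
    for j in range(7):
        tq = ta[j] + tp[j]
        Q[16 + jd[j]] += tq
        Q[16 + jp[j]] -= tq
    for n in range(4):
        s = cseg[n]
        c = np.cos(th[s]); sn = np.sin(th[s])
        dx = c * cr[n, 0] - sn * cr[n, 1]
        dy = sn * cr[n, 0] + c * cr[n, 1]
        Q[s] += grf[n, 0]
        Q[8 + s] += grf[n, 1]
        Q[16 + s] += dx * grf[n, 1] - dy * grf[n, 0]

    # ---- constraints (Schur complement on the diagonal mass matrix)
    J = np.zeros((14, 24))
    rhs = np.zeros(14)
    for j in range(7):
        pseg = jp[j]; dseg = jd[j]
        cp_ = np.cos(th[pseg]); sp_ = np.sin(th[pseg])
        cd_ = np.cos(th[dseg]); sd_ = np.sin(th[dseg])
        dpx = cp_ * jrp[j, 0] - sp_ * jrp[j, 1]
        dpy = sp_ * jrp[j, 0] + cp_ * jrp[j, 1]
        ddx = cd_ * jrd[j, 0] - sd_ * jrd[j, 1]
        ddy = sd_ * jrd[j, 0] + cd_ * jrd[j, 1]
        r0 = 2 * j
        J[r0, pseg] = 1.0;       J[r0, dseg] = -1.0
        J[r0 + 1, 8 + pseg] = 1.0; J[r0 + 1, 8 + dseg] = -1.0
        J[r0, 16 + pseg] = -dpy;   J[r0 + 1, 16 + pseg] = dpx
        J[r0, 16 + dseg] = ddy;    J[r0 + 1, 16 + dseg] = -ddx
        wp = thd[pseg]; wd = thd[dseg]
        gx = -dpx * wp * wp + ddx * wd * wd
        gy = -dpy * wp * wp + ddy * wd * wd
        Cx = (x[pseg] + dpx) - (x[dseg] + ddx)
        Cy = (y[pseg] + dpy) - (y[dseg] + ddy)
        Cdx = (xd[pseg] - wp * dpy) - (xd[dseg] - wd * ddy)
        Cdy = (yd[pseg] + wp * dpx) - (yd[dseg] + wd * ddx)
        rhs[r0] = -gx - 2.0 * alpha * Cdx - alpha * alpha * Cx
        rhs[r0 + 1] = -gy - 2.0 * alpha * Cdy - alpha * alpha * Cy

    Minv = np.empty(24)
    for s in range(8):
        Minv[s] = 1.0 / mass[s]
        Minv[8 + s] = 1.0 / mass[s]
        Minv[16 + s] = 1.0 / inertia[s]

    JM = J * Minv  # scales columns
    A = JM @ J.T
    b = rhs - JM @ Q
    lam = np.linalg.solve(A, b)
    qdd = Minv * (Q + J.T @ lam)

    return qdd, du, dv, grf


@njit(cache=True)
def _run(q, qd, u, v, anchor_x, in_contact, u0_series, dt, n_steps, rec_every,
         mass, inertia, jp, jd, jrp, jrd, cseg, cr,
         kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
         tau, tau_a, beta, W, fbg, p,
         tch, tneu, tjnt, tsgn, tgate, tq_scale,
         lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha,
         pelvis_hip_r, x_stop, hip_stop,
         rec):
    """Main loop.  ``rec`` is a preallocated (n_rec_max, n_cols) buffer.
    Returns (status, n_recorded, t_end)."""
    n_rec = 0
    t = 0.0
    status = 2
    total_mass = mass.sum()
    half = 0.5 * dt
    for step in range(n_steps):
        # record the current state
        if step % rec_every == 0 and n_rec < rec.shape[0]:
            qdd0, du0, dv0, grf0 = _deriv(
                q, qd, u, v, u0_series[step], anchor_x, in_contact,
                mass, inertia, jp, jd, jrp, jrd, cseg, cr,
                kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
                tau, tau_a, beta, W, fbg, p, tch, tneu, tjnt, tsgn, tgate, tq_scale,
                lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha)
            row = rec[n_rec]
            row[0] = t
            for k in range(24):
                row[1 + k] = q[k]
                row[25 + k] = qd[k]
            for n in range(4):
                row[49 + 2 * n] = grf0[n, 0]
                row[50 + 2 * n] = grf0[n, 1]
            for i in range(14):
                row[57 + i] = max(0.0, u[i])
            n_rec += 1

        u0_now = u0_series[step]
        k1q, k1u, k1v, _ = _deriv(q, qd, u, v, u0_now, anchor_x, in_contact,
                                  mass, inertia, jp, jd, jrp, jrd, cseg, cr,
                                  kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
                                  tau, tau_a, beta, W, fbg, p, tch, tneu, tjnt, tsgn, tgate, tq_scale,
                                  lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha)
        q2 = q + half * qd; qd2 = qd + half * k1q
        u2 = u + half * k1u; v2 = v + half * k1v
        k2q, k2u, k2v, _ = _deriv(q2, qd2, u2, v2, u0_now, anchor_x, in_contact,
                                  mass, inertia, jp, jd, jrp, jrd, cseg, cr,
                                  kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
                                  tau, tau_a, beta, W, fbg, p, tch, tneu, tjnt, tsgn, tgate, tq_scale,
                                  lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha)
        q3 = q + half * qd2; qd3 = qd + half * k2q
        u3 = u + half * k2u; v3 = v + half * k2v
        k3q, k3u, k3v, _ = _deriv(q3, qd3, u3, v3, u0_now, anchor_x, in_contact,
                                  mass, inertia, jp, jd, jrp, jrd, cseg, cr,
                                  kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
                                  tau, tau_a, beta, W, fbg, p, tch, tneu, tjnt, tsgn, tgate, tq_scale,
                                  lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha)
        q4 = q + dt * qd3; qd4 = qd + dt * k3q
        u4 = u + dt * k3u; v4 = v + dt * k3v
        k4q, k4u, k4v, _ = _deriv(q4, qd4, u4, v4, u0_now, anchor_x, in_contact,
                                  mass, inertia, jp, jd, jrp, jrd, cseg, cr,
                                  kgx, kgy, bgx, bgy, fs_x0, fs_x1, fs_mu,
                                  tau, tau_a, beta, W, fbg, p, tch, tneu, tjnt, tsgn, tgate, tq_scale,
                                  lim_lo, lim_hi, k_stop, b_stop, b_visc, alpha)
        q = q + dt / 6.0 * (qd + 2.0 * qd2 + 2.0 * qd3 + qd4)
        qd = qd + dt / 6.0 * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
        u = u + dt / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        t += dt

        # divergence check
        ok = True
        for k in range(24):
            if not np.isfinite(q[k]) or abs(q[k]) > 1e3:
                ok = False
                break
        if not ok:
            status = 3
            break

        # anchor / contact-flag update
        for n in range(4):
            s = cseg[n]
            c = np.cos(q[16 + s]); sn = np.sin(q[16 + s])
            dx = c * cr[n, 0] - sn * cr[n, 1]
            dy = sn * cr[n, 0] + c * cr[n, 1]
            px = q[s] + dx; py = q[8 + s] + dy
            if py < 0.0:
                if in_contact[n] == 0:
                    in_contact[n] = 1
                    anchor_x[n] = px
            else:
                in_contact[n] = 0

        # termination: hip down or distance covered
        cp_ = np.cos(q[17]); sp_ = np.sin(q[17])
        hip_y = q[9] + sp_ * pelvis_hip_r[0] + cp_ * pelvis_hip_r[1]
        com_x = 0.0
        for s in range(8):
            com_x += mass[s] * q[s]
        com_x /= total_mass
        if hip_y < hip_stop:
            status = 1
            break
        if com_x > x_stop:
            status = 0
            break

    return status, n_rec, t, q, qd, u, v


# ----------------------------------------------------------------------
# python wrappers
# ----------------------------------------------------------------------

_REC_COLS = 71  # t + q(24) + qd(24) + grf(8) + neuron outputs(14)


def _pack_params(anthro: AnthropometricSet, params: CPGParameters,
                 ground: GroundModel, limits: JointLimits):
    jt = joint_attachments(anthro)
    jp = np.array([p for p, d, _, _ in jt], dtype=np.int64)
    jd = np.array([d for p, d, _, _ in jt], dtype=np.int64)
    jrp = np.array([rp for _, _, rp, _ in jt])
    jrd = np.array([rd for _, _, _, rd in jt])
    ct = contact_attachments(anthro)
    cseg = np.array([s for s, _ in ct], dtype=np.int64)
    cr = np.array([r for _, r in ct])
    segs = ground.friction_segments
    if segs:
        fs_x0 = np.array([s[0] for s in segs])
        fs_x1 = np.array([s[1] for s in segs])
        fs_mu = np.array([np.nan if s[2] is None else s[2] for s in segs])
    else:
        fs_x0 = np.empty(0); fs_x1 = np.empty(0); fs_mu = np.empty(0)
    return dict(
        mass=anthro.mass, inertia=anthro.inertia,
        jp=jp, jd=jd, jrp=jrp, jrd=jrd, cseg=cseg, cr=cr,
        kgx=ground.k_gx, kgy=ground.k_gy, bgx=ground.b_gx, bgy=ground.b_gy,
        fs_x0=fs_x0, fs_x1=fs_x1, fs_mu=fs_mu,
        tau=params.tau, tau_a=params.tau_a, beta=params.beta,
        W=params.weights, fbg=params.feedback_gains, p=params.p,
        tch=params.term_channel, tneu=params.term_neuron, tjnt=params.term_joint,
        tsgn=params.term_sign, tgate=params.term_gate, tq_scale=params.torque_scale,
        lim_lo=limits.lower, lim_hi=limits.upper,
        k_stop=limits.k_stop, b_stop=limits.b_stop, b_visc=limits.b_visc,
        alpha=BAUMGARTE_ALPHA,
    )


def initial_conditions(anthro: AnthropometricSet, split: float = 0.15,
                       speed: float = 0.9) -> BodyState:
    """Frozen mid-step start: straight right (stance) leg tilted forward
    by ``split`` rad, left leg trailing with a flexed knee so its foot is
    clear of the ground, whole body moving forward at ``speed``.

    Starting inside the gait cycle (single support, trailing leg ready
    to swing) lets the rhythm generator lock on within the first stride.
    """
    theta = np.zeros(8)
    theta[2] = theta[4] = split        # right leg forward, straight
    theta[3] = -split                  # left thigh trailing
    theta[5] = -split - 0.35           # left knee flexed: foot clears ground
    st = assemble_state(anthro, (0.0, 1.0), theta, velocity=(speed, 0.0))
    pos, _ = contact_point_states(st, anthro)
    # right-foot points are entries 0 (heel) and 1 (toe)
    shift = -pos[:2, 1].min() - 0.005  # 5 mm initial penetration of the stance foot
    st = assemble_state(anthro, (0.0, 1.0 + shift), theta, velocity=(speed, 0.0))
    return st


def initial_neural() -> NeuralState:
    """Frozen initial neural phases; breaks left-right symmetry so the
    first swing is deterministic (right leg swings first)."""
    u = np.full(14, 0.01)
    u[4] = 0.5   # left hip flexor primed (left leg starts behind)
    u[3] = 0.5   # right hip extensor primed
    return NeuralState(u=u, v=np.zeros(14))


def _hip_offset(anthro: AnthropometricSet) -> np.ndarray:
    # hip joint (both coincide) relative to the pelvis CoM, body frame
    return np.array([0.0, -anthro.com_offset[1]])


def simulate_trial(
    params: CPGParameters,
    config: RunConfig,
    seed: int,
    anthro: AnthropometricSet | None = None,
    ground: GroundModel | None = None,
    limits: JointLimits | None = None,
    meta: dict | None = None,
) -> tuple[Trajectory, SimStatus]:
    """Run one full trial and return the recorded trajectory.

    Raises :class:`NumericalError` if the integration diverges (the
    caller decides whether to retry at a finer step).
    """
    if config.integrator != "rk4":
        raise ValueError(f"unknown integrator {config.integrator!r} (only 'rk4')")
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    anthro = anthro or build_anthropometry()
    ground = ground or GroundModel(friction_segments=config.friction_segments())
    limits = limits or JointLimits()
    pk = _pack_params(anthro, params, ground, limits)

    state = initial_conditions(anthro, split=config.init_split,
                               speed=config.init_speed)
    neural = initial_neural()
    n_steps = int(np.ceil(config.t_max / config.dt))
    rng = np.random.default_rng(seed)
    u0_series = params.u0 * (
        1.0 + params.noise_pct / 100.0 * rng.standard_normal(n_steps)
    )
    n_rec_max = n_steps // config.record_every + 2
    rec = np.zeros((n_rec_max, _REC_COLS))

    code, n_rec, t_end, q, qd, u, v = _run(
        state.q, state.qd, neural.u, neural.v,
        np.zeros(4), np.zeros(4, dtype=np.int64),
        u0_series, config.dt, n_steps, config.record_every,
        pk["mass"], pk["inertia"], pk["jp"], pk["jd"], pk["jrp"], pk["jrd"],
        pk["cseg"], pk["cr"],
        pk["kgx"], pk["kgy"], pk["bgx"], pk["bgy"],
        pk["fs_x0"], pk["fs_x1"], pk["fs_mu"],
        pk["tau"], pk["tau_a"], pk["beta"], pk["W"], pk["fbg"], pk["p"],
        pk["tch"], pk["tneu"], pk["tjnt"], pk["tsgn"], pk["tgate"], pk["tq_scale"],
        pk["lim_lo"], pk["lim_hi"], pk["k_stop"], pk["b_stop"], pk["b_visc"],
        pk["alpha"],
        _hip_offset(anthro), config.total_distance + 0.2, config.min_hip_stop,
        rec,
    )
    if code == 3:
        raise NumericalError("simulation diverged", time=t_end)

    traj = _frame_from_record(rec[:n_rec], anthro, meta or {})
    x_end = float(traj.col("com_x")[-1]) if n_rec else 0.0
    return traj, SimStatus(code=code, t_end=t_end, x_end=x_end)


def _frame_from_record(rec: np.ndarray, anthro: AnthropometricSet, meta: dict) -> Trajectory:
    """Derive the analysis channels from raw recorded states."""
    n = rec.shape[0]
    q = rec[:, 1:25]; qd = rec[:, 25:49]
    x = q[:, :8]; y = q[:, 8:16]; th = q[:, 16:24]
    xd = qd[:, :8]; yd = qd[:, 8:16]; thd = qd[:, 16:24]
    m = anthro.mass
    mt = m.sum()
    cols = {"t": rec[:, 0]}
    cols["com_x"] = x @ m / mt
    cols["com_y"] = y @ m / mt
    cols["com_vx"] = xd @ m / mt
    cols["com_vy"] = yd @ m / mt
    hip = _hip_offset(anthro)
    c1, s1 = np.cos(th[:, 1]), np.sin(th[:, 1])
    cols["hip_x"] = x[:, 1] + c1 * hip[0] - s1 * hip[1]
    cols["hip_y"] = y[:, 1] + s1 * hip[0] + c1 * hip[1]
    names = ("heel_r", "toe_r", "heel_l", "toe_l")
    for nme, (seg, r) in zip(names, contact_attachments(anthro)):
        cs, sn = np.cos(th[:, seg]), np.sin(th[:, seg])
        dx = cs * r[0] - sn * r[1]
        dy = sn * r[0] + cs * r[1]
        cols[f"{nme}_x"] = x[:, seg] + dx
        cols[f"{nme}_y"] = y[:, seg] + dy
    for nme, (seg, r) in zip(("ankle_r", "ankle_l"),
                             [(6, None), (7, None)]):
        jt = joint_attachments(anthro)
        # ankle joints are entries 5, 6 of the joint table (distal side)
        _, d, _, rd = jt[5 if nme == "ankle_r" else 6]
        cs, sn = np.cos(th[:, d]), np.sin(th[:, d])
        cols[f"{nme}_x"] = x[:, d] + cs * rd[0] - sn * rd[1]
        cols[f"{nme}_y"] = y[:, d] + sn * rd[0] + cs * rd[1]
    cols["foot_r_vx"] = xd[:, 6]
    cols["foot_l_vx"] = xd[:, 7]
    for i, nme in enumerate(("fgx_heel_r", "fgy_heel_r", "fgx_toe_r", "fgy_toe_r",
                             "fgx_heel_l", "fgy_heel_l", "fgx_toe_l", "fgy_toe_l")):
        cols[nme] = rec[:, 49 + i]
    for k in range(24):
        cols[f"q{k}"] = q[:, k]
    for k in range(24):
        cols[f"qd{k}"] = qd[:, k]
    for i in range(14):
        cols[f"neuron_{i}"] = rec[:, 57 + i]
    return Trajectory(pd.DataFrame(cols), dict(meta))


# ----------------------------------------------------------------------
# reference single-step path
# ----------------------------------------------------------------------

def _forces_and_derivs(state: BodyState, neural: NeuralState, contacts: ContactState,
                       params: CPGParameters, anthro: AnthropometricSet,
                       ground: GroundModel, limits: JointLimits, u0_now: float):
    pos, vel = contact_point_states(state, anthro)
    grf = np.zeros((4, 2))
    for n in range(4):
        ax = contacts.anchor_x[n] if contacts.in_contact[n] else pos[n, 0]
        fgx, fgy = ground_reaction(pos[n, 0], pos[n, 1], vel[n, 0], vel[n, 1], ax, ground)
        mu = ground.mu_at(pos[n, 0])
        grf[n, 0] = friction_cap(fgx, fgy, mu)
        grf[n, 1] = fgy
    load_r = min(1.0, (grf[0, 1] + grf[1, 1]) / LOAD_SAT_N)
    load_l = min(1.0, (grf[2, 1] + grf[3, 1]) / LOAD_SAT_N)
    com_vx = float(anthro.mass @ state.xd / anthro.mass.sum())
    s_fb = sensory_feedback(state.theta, load_r, load_l, params.feedback_gains,
                            state.thetad, com_vx)
    du, dv = neuron_derivatives(neural, params, s_fb, u0_now)
    ta = active_torques(neural.outputs, params, load_r, load_l)
    tp = passive_torques(state.theta, state.thetad, limits)
    sol = compute_accelerations(state, ta, tp, grf, anthro, BAUMGARTE_ALPHA)
    qdd = np.concatenate([sol.xdd, sol.ydd, sol.thetadd])
    return qdd, du, dv, grf


def integrate_step(
    state: BodyState,
    neural: NeuralState,
    contacts: ContactState,
    dt: float,
    rng: np.random.Generator | None = None,
    params: CPGParameters | None = None,
    anthro: AnthropometricSet | None = None,
    ground: GroundModel | None = None,
    limits: JointLimits | None = None,
    u0_now: float | None = None,
) -> tuple[BodyState, NeuralState, ContactState]:
    """Advance the coupled system one RK4 step (reference path).

    Contact anchors and the (optionally noisy) tonic drive are held over
    the step; anchors are updated from the new contact-point heights
    afterwards.  Deterministic given the state and the rng's state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    anthro = anthro or build_anthropometry()
    ground = ground or GroundModel()
    limits = limits or JointLimits()
    if params is None:
        raise ValueError("params (CPGParameters) is required")
    if u0_now is None:
        if rng is not None:
            u0_now = params.u0 * (1.0 + params.noise_pct / 100.0 * rng.standard_normal())
        else:
            u0_now = params.u0

    def f(q, qd, u, v):
        st = BodyState.from_q(state.time, q, qd)
        ns = NeuralState(u, v)
        return _forces_and_derivs(st, ns, contacts, params, anthro, ground, limits, u0_now)

    q0, qd0, u0v, v0 = state.q, state.qd, neural.u, neural.v
    k1q, k1u, k1v, _ = f(q0, qd0, u0v, v0)
    h = 0.5 * dt
    k2q, k2u, k2v, _ = f(q0 + h * qd0, qd0 + h * k1q, u0v + h * k1u, v0 + h * k1v)
    k3q, k3u, k3v, _ = f(q0 + h * (qd0 + h * k1q), qd0 + h * k2q,
                         u0v + h * k2u, v0 + h * k2v)
    k4q, k4u, k4v, _ = f(q0 + dt * (qd0 + h * k2q), qd0 + dt * k3q,
                         u0v + dt * k3u, v0 + dt * k3v)
    qd1 = qd0 + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
    q1 = q0 + dt / 6.0 * (qd0 + 2 * (qd0 + h * k1q) + 2 * (qd0 + h * k2q)
                          + (qd0 + dt * k3q))
    u1 = u0v + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
    v1 = v0 + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    new_state = BodyState.from_q(state.time + dt, q1, qd1)
    if not new_state.is_finite():
        raise NumericalError("non-finite state after step", time=state.time + dt)
    new_neural = NeuralState(u1, v1)
    pos, _ = contact_point_states(new_state, anthro)
    new_contacts = update_anchors(contacts, pos[:, 0], pos[:, 1], ground)
    return new_state, new_neural, new_contacts
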