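"""Constrained equations of motion of the four-segment walker.

The walker is modelled with a floating base: generalized coordinates
``Q = [x, y, phi1..phi4]`` where ``(x, y)`` is the stance-toe position.
Ground contact is imposed through velocity-level constraints with
Lagrange multipliers, so a single mass matrix / bias vector serves every
contact phase and the multipliers expose the ground-reaction wrench
directly.

For an absolute-angle planar chain the kinetic energy is

    T = 1/2 m_tot |v_p|^2 + v_p . sum_k b_k phidot_k e'(phi_k)
        + 1/2 sum_k d_k phidot_k^2
        + sum_{k<j} c_kj phidot_k phidot_j cos(phi_k - phi_j)

with constant first/second-moment coefficients ``b_k``, ``c_kj``,
``d_k`` determined by the mass distribution, which yields closed-form
mass-matrix and bias expressions (verified against an independent sympy
Lagrangian derivation in :mod:`flatwalker.symbolic`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Phase, State, joint_angles
from .params import ActuationParams, WalkerParams

__all__ = [
    "ChainCoefficients",
    "JointTorques",
    "GroundReaction",
    "ankle_torque",
    "hip_torque",
    "joint_torques",
    "mass_matrix",
    "bias_forces",
    "generalized_forces",
    "constraint_jacobian",
    "equations_of_motion",
    "ground_reaction",
    "kinetic_energy",
    "potential_energy",
]


# ---------------------------------------------------------------------------
# Chain mass-distribution coefficients


@dataclass(frozen=True)
class ChainCoefficients:
    """First/second mass moments of the chain about each angle coordinate."""

    b: np.ndarray      # (4,)  first moments
    c: np.ndarray      # (4,4) cross second moments (symmetric, zero diag)
    d: np.ndarray      # (4,)  diagonal second moments incl. segment inertia
    m_tot: float
    g: float


def chain_coefficients(p: WalkerParams) -> ChainCoefficients:
    lf, l, dl, df = p.l_f, p.l, p.d_l, p.d_f
    # CoM_i = p_toe + sum_k a[i,k] e(phi_k); masses per row
    a = np.array(
        [
            [lf - df, 0.0, 0.0, 0.0],          # stance-foot CoM  (m_f)
            [lf, dl, 0.0, 0.0],                # stance-leg CoM   (m_l)
            [lf, l, 0.0, 0.0],                 # hip point mass   (m_h)
            [lf, l, l - dl, 0.0],              # swing-leg CoM    (m_l)
            [lf, l, l, lf - df],               # swing-foot CoM   (m_f)
        ]
    )
    m = np.array([p.m_f, p.m_l, p.m_h, p.m_l, p.m_f])
    b = m @ a
    c = a.T @ (m[:, None] * a)
    d = np.diag(c).copy() + np.array([p.j_f, p.j_l, p.j_l, p.j_f])
    np.fill_diagonal(c, 0.0)
    return ChainCoefficients(b=b, c=c, d=d, m_tot=p.m_tot, g=p.g)


def mass_matrix(phi: np.ndarray, co: ChainCoefficients) -> np.ndarray:
    """6x6 mass matrix in coordinates [x, y, phi1..phi4]."""
    s, cph = np.sin(phi), np.cos(phi)
    M = np.zeros((6, 6))
    M[0, 0] = M[1, 1] = co.m_tot
    M[0, 2:] = -co.b * s
    M[1, 2:] = co.b * cph
    M[2:, 0] = M[0, 2:]
    M[2:, 1] = M[1, 2:]
    dphi = phi[:, None] - phi[None, :]
    M[2:, 2:] = co.c * np.cos(dphi)
    M[2:, 2:][np.diag_indices(4)] = co.d
    return M


def bias_forces(phi: np.ndarray, phidot: np.ndarray, co: ChainCoefficients) -> np.ndarray:
    """Velocity-dependent + gravity generalized forces ``h`` with
    ``M qddot + h = Q_applied``."""
    s, cph = np.sin(phi), np.cos(phi)
    w2 = phidot**2
    h = np.zeros(6)
    h[0] = -np.sum(co.b * w2 * cph)
    h[1] = -np.sum(co.b * w2 * s) + co.m_tot * co.g
    dphi = phi[:, None] - phi[None, :]
    h[2:] = (co.c * np.sin(dphi)) @ w2 + co.g * co.b * cph
    return h


def kinetic_energy(state: State, params: WalkerParams) -> float:
    """Total kinetic energy (requires the pin of the current phase)."""
    from .model import forward_kinematics  # velocities need the phase pin

    k = forward_kinematics(state, params)
    v_toe = k.v_toe
    co = chain_coefficients(params)
    M = mass_matrix(state.phi, co)
    qd = np.concatenate([v_toe, state.phidot])
    return 0.5 * qd @ M @ qd


def potential_energy(state: State, params: WalkerParams, anchor=(0.0, 0.0)) -> float:
    from .model import forward_kinematics

    k = forward_kinematics(state, params, anchor)
    p = params
    return p.g * (
        p.m_h * k.hip[1]
        + p.m_l * (k.com_leg_st[1] + k.com_leg_sw[1])
        + p.m_f * (k.com_foot_st[1] + k.com_foot_sw[1])
    )


# ---------------------------------------------------------------------------
# Torque laws


def ankle_torque(
    angle: float,
    rate: float,
    act: ActuationParams,
    pulse_active: bool = False,
    damper_active: bool = False,
) -> float:
    """Net ankle joint torque (tension convention of the spring law).

    ``angle`` is the signed ankle angle (positive = dorsiflexion) and
    ``rate`` the leg-over-foot angular rate, i.e. minus the time
    derivative of ``angle``; with that convention the damper term is
    ``-c_a * rate`` and dissipates energy.  The pulse torque ``T_a`` adds
    only while ``pulse_active`` (between ankle reversal and toe-off).
    """
    if act.k_a < 0:
        raise ValueError("negative ankle stiffness")
    tau = act.k_a * angle
    if pulse_active:
        tau += act.T_a
    return tau


def ankle_damper_torque(rate: float, params: WalkerParams) -> float:
    """Viscous ankle damper torque, ``-c_a * rate`` (same rate convention
    as :func:`ankle_torque`)."""
    return -params.c_a * rate


def hip_torque(state: State, act: ActuationParams) -> float:
    """Signed hip torque conjugate to the hip angle (restoring).

    Magnitude ``k * |hip angle|``: the flexion spring ``k_hf`` acts
    while the hip angle is negative (swing leg behind, before the zero
    crossing) and the retraction spring ``k_hr`` after it; the torque is
    continuous (zero at the crossing) and always drives the hip angle
    toward zero.
    """
    psi = joint_angles(state).hip
    k = act.k_hr if psi > 0 else act.k_hf
    return -k * psi


@dataclass(frozen=True)
class JointTorques:
    """Joint torques (tension convention) and separate damper parts."""

    tau_ankle_stance: float
    tau_hip: float
    tau_ankle_swing: float
    damper_stance: float
    damper_swing: float


def _damper_flags(phase: Phase) -> tuple[bool, bool]:
    """(stance-ankle, swing-ankle) damper activity: a damper acts whenever
    the toe of its foot is off the ground."""
    stance = phase is Phase.HEEL
    swing = True  # the swing/leading toe is airborne in every phase
    return stance, swing


def _joint_torques_arrays(
    phi,
    phidot,
    phase: Phase,
    pulse_active: bool,
    hip_crossed: bool,
    p: WalkerParams,
    act: ActuationParams,
) -> JointTorques:
    """Array-based torque computation (fast path for the integrator)."""
    p1, p2, p3, p4 = phi
    d1, d2, d3, d4 = phidot
    th_st = p1 - p2 - math.pi / 2
    th_sw = p4 - p3 - math.pi / 2
    psi = math.pi - p2 + p3
    psi = (psi + math.pi) % (2 * math.pi) - math.pi
    damp_st, damp_sw = _damper_flags(phase)
    rate_st = d2 - d1
    rate_sw = d3 - d4
    tau1 = act.k_a * th_st + (act.T_a if pulse_active else 0.0)
    tau3 = act.k_a * th_sw
    k_h = act.k_hr if psi > 0 else act.k_hf
    return JointTorques(
        tau_ankle_stance=tau1,
        tau_hip=-k_h * psi,
        tau_ankle_swing=tau3,
        damper_stance=-p.c_a * rate_st if damp_st else 0.0,
        damper_swing=-p.c_a * rate_sw if damp_sw else 0.0,
    )


def joint_torques(state: State, params: WalkerParams, act: ActuationParams) -> JointTorques:
    """All joint torques at ``state`` including damper contributions."""
    return _joint_torques_arrays(
        state.phi, state.phidot, state.phase, state.pulse_active,
        state.hip_crossed, params, act,
    )


def generalized_forces(torques: JointTorques) -> np.ndarray:
    """Map joint torques to generalized forces on [x, y, phi1..phi4].

    Each joint torque acts as an equal-and-opposite pair on the two
    segments it connects: ankle tension ``tau`` pulls ``phi1`` down and
    ``phi2`` up (mirrored at the swing ankle), the hip torque ``u`` acts
    as ``+u`` on the swing leg and ``-u`` on the stance leg.
    """
    t1 = torques.tau_ankle_stance + torques.damper_stance
    t3 = torques.tau_ankle_swing + torques.damper_swing
    u = torques.tau_hip
    Q = np.zeros(6)
    Q[2] = -t1
    Q[3] = t1 - u
    Q[4] = u + t3
    Q[5] = -t3
    return Q


# ---------------------------------------------------------------------------
# Contact constraints

# Constraint rows are built from point Jacobians of the chain:
#   toe   = (x, y)
#   heel  = toe + l_f e(phi1)
#   heel2 = toe + l_f e(phi1) + l e(phi2) + l e(phi3)   (swing/leading heel)
# plus the pure angle row phi1 (flat-foot lock).

_POINT_COEFFS = {
    "toe": (),
    "heel": ((2, "l_f"),),
    "heel2": ((2, "l_f"), (3, "l"), (4, "l")),
    "toe2": ((2, "l_f"), (3, "l"), (4, "l"), (5, "l_f")),
}


def _point_jacobian(name: str, phi: np.ndarray, p: WalkerParams):
    """(J, Jdot_qdot_term) rows for a chain point; J is 2x6."""
    J = np.zeros((2, 6))
    J[0, 0] = 1.0
    J[1, 1] = 1.0
    for col, attr in _POINT_COEFFS[name]:
        r = getattr(p, attr)
        a = phi[col - 2]
        J[0, col] = -r * math.sin(a)
        J[1, col] = r * math.cos(a)
    return J


def _point_jdot(name: str, phi: np.ndarray, phidot: np.ndarray, p: WalkerParams):
    Jd = np.zeros((2, 6))
    for col, attr in _POINT_COEFFS[name]:
        r = getattr(p, attr)
        a = phi[col - 2]
        w = phidot[col - 2]
        Jd[0, col] = -r * math.cos(a) * w
        Jd[1, col] = -r * math.sin(a) * w
    return Jd


#: Constraint sets per phase, as (kind, name) rows; kind "point" pins a
#: chain point, kind "angle" locks phi1 (flat foot).
PHASE_CONSTRAINTS = {
    Phase.HEEL: (("point", "heel"),),
    Phase.FOOT: (("point", "heel"), ("angle", "phi1")),
    Phase.TOE: (("point", "toe"),),
    Phase.DOUBLE: (("point", "toe"), ("point", "heel2")),
    Phase.FOOT_DOUBLE: (("point", "heel"), ("angle", "phi1"), ("point", "heel2")),
}


def constraint_jacobian(phase: Phase, phi, phidot, p: WalkerParams):
    """Stacked constraint Jacobian ``J`` and ``Jdot`` for a phase."""
    rows_J, rows_Jd = [], []
    for kind, name in PHASE_CONSTRAINTS[phase]:
        if kind == "point":
            rows_J.append(_point_jacobian(name, phi, p))
            rows_Jd.append(_point_jdot(name, phi, phidot, p))
        else:  # angle row: phi1
            r = np.zeros((1, 6))
            r[0, 2] = 1.0
            rows_J.append(r)
            rows_Jd.append(np.zeros((1, 6)))
    return np.vstack(rows_J), np.vstack(rows_Jd)


# ---------------------------------------------------------------------------
# EOM and ground reactions


def base_velocity(phase: Phase, phi, phidot, p: WalkerParams) -> np.ndarray:
    """Stance-toe (chain root) velocity implied by the phase's pin."""
    if phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        return -p.l_f * phidot[0] * np.array([-math.sin(phi[0]), math.cos(phi[0])])
    return np.zeros(2)


def _eom_arrays(
    phi,
    phidot,
    phase: Phase,
    pulse_active: bool,
    hip_crossed: bool,
    p: WalkerParams,
    act: ActuationParams,
    co: ChainCoefficients,
):
    """KKT solve on raw arrays; returns (qddot(6), lam, torques)."""
    qd = np.concatenate([base_velocity(phase, phi, phidot, p), phidot])
    M = mass_matrix(phi, co)
    h = bias_forces(phi, phidot, co)
    torques = _joint_torques_arrays(phi, phidot, phase, pulse_active, hip_crossed, p, act)
    Q = generalized_forces(torques)
    J, Jd = constraint_jacobian(phase, phi, phidot, p)
    m = J.shape[0]
    KKT = np.zeros((6 + m, 6 + m))
    KKT[:6, :6] = M
    KKT[:6, 6:] = -J.T
    KKT[6:, :6] = J
    rhs = np.concatenate([Q - h, -Jd @ qd])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"singular mass/constraint system: {exc}") from exc
    return sol[:6], sol[6:], torques


def equations_of_motion(
    state: State,
    params: WalkerParams,
    act: ActuationParams,
    co: ChainCoefficients | None = None,
):
    """Accelerations and constraint multipliers for the current phase.

    Solves the KKT system ``[M -J^T; J 0] [qddot; lam] = [Q - h; -Jdot qdot]``
    in the floating-base coordinates.  Returns ``(qddot, lam, torques)``
    where ``qddot`` is the 6-vector ``[xddot, yddot, phiddot1..4]`` and
    ``lam`` the contact-force multipliers (ground action on the walker).
    """
    co = co or chain_coefficients(params)
    return _eom_arrays(
        state.phi, state.phidot, state.phase, state.pulse_active,
        state.hip_crossed, params, act, co,
    )


@dataclass(frozen=True)
class GroundReaction:
    """Contact forces (and CoP when the foot is flat) from the multipliers.

    ``force_trailing`` acts at the trailing/stance contact (heel in HEEL
    and FOOT, toe in TOE/DOUBLE); ``force_leading`` at the leading heel
    during double stance; ``cop_x`` is the center-of-pressure position
    along a flat stance foot, ``None`` otherwise.
    """

    force_trailing: np.ndarray
    force_leading: np.ndarray | None
    cop_x: float | None
    moment: float | None


def ground_reaction(
    state: State, lam: np.ndarray, params: WalkerParams, anchor=(0.0, 0.0)
) -> GroundReaction:
    """Resolve constraint multipliers into contact forces and CoP."""
    from .model import forward_kinematics

    phase = state.phase
    if phase is Phase.HEEL or phase is Phase.TOE:
        return GroundReaction(lam[:2].copy(), None, None, None)
    if phase is Phase.DOUBLE:
        return GroundReaction(lam[:2].copy(), lam[2:4].copy(), None, None)
    # flat-foot phases: heel force + angle-constraint moment -> CoP
    F = lam[:2]
    mu = lam[2]
    kin = forward_kinematics(state, params, anchor)
    lead = lam[3:5].copy() if phase is Phase.FOOT_DOUBLE else None
    if abs(F[1]) < 1e-12:
        cop = math.nan
    else:
        cop = kin.heel[0] + mu / F[1]
    return GroundReaction(F.copy(), lead, cop, mu)
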