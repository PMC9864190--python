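"""State, contact phases, kinematics and step relabeling.

Coordinates: each segment angle ``phi_i`` is measured counterclockwise
from the +x axis, for the vector from the segment's proximal to its
distal joint, with the chain rooted at the stance toe:

    1 = stance foot (toe -> heel/ankle)
    2 = stance leg  (ankle -> hip)
    3 = swing leg   (hip -> ankle)
    4 = swing foot  (heel/ankle -> toe)

Gravity acts in -y and the ground is y = 0.  The canonical standing pose
is ``phi = [pi, pi/2, -pi/2, 0]``: both feet flat, legs vertical.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import WalkerParams

__all__ = [
    "Phase",
    "State",
    "JointAngles",
    "Kinematics",
    "FLAT_FOOT_ANGLE",
    "standing_state",
    "forward_kinematics",
    "joint_angles",
    "relabel_step",
]

#: Stance-foot angle when the foot lies flat on the ground (toe->heel = -x).
FLAT_FOOT_ANGLE = math.pi


class Phase(enum.Enum):
    """Ground-contact phase of the walker.

    HEEL: stance heel pinned, foot rotating (after contralateral toe-off).
    FOOT: flat foot — heel pinned and foot angle held at ``pi``.
    TOE: stance toe pinned, heel off the ground (pre-emptive push-off).
    DOUBLE: trailing toe and leading heel both pinned (double stance).
    FOOT_DOUBLE: flat trailing foot plus leading heel, a transient
    configuration entered only when heel strike occurs before the center
    of pressure has reached the toe.
    """

    HEEL = "heel"
    FOOT = "foot"
    TOE = "toe"
    DOUBLE = "double"
    FOOT_DOUBLE = "foot_double"


@dataclass
class State:
    """Generalized coordinates of the walker at one instant.

    ``phi``/``phidot`` are the four absolute segment angles and their
    rates; ``phase`` the active contact phase; ``t`` dimensionless time.
    ``pulse_active`` flags the ankle pulse torque (on between ankle
    reversal and toe-off); ``hip_crossed`` latches the hip angle's first
    zero crossing of the step (flexion -> retraction spring switch).
    """

    phi: np.ndarray
    phidot: np.ndarray
    phase: Phase = Phase.HEEL
    t: float = 0.0
    pulse_active: bool = False
    hip_crossed: bool = False

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float).reshape(4)
        self.phidot = np.asarray(self.phidot, dtype=float).reshape(4)
        if not (np.all(np.isfinite(self.phi)) and np.all(np.isfinite(self.phidot))):
            raise ValueError("state angles/rates must be finite")

    @property
    def q(self) -> np.ndarray:
        """8-vector [phi1..phi4, phidot1..phidot4]."""
        return np.concatenate([self.phi, self.phidot])

    @classmethod
    def from_q(cls, q, **kw) -> "State":
        q = np.asarray(q, dtype=float).reshape(8)
        return cls(phi=q[:4], phidot=q[4:], **kw)

    def copy(self, **changes) -> "State":
        out = replace(self, **changes)
        out.phi = out.phi.copy()
        out.phidot = out.phidot.copy()
        return out


@dataclass(frozen=True)
class JointAngles:
    """Signed joint angles (zero in the canonical standing pose).

    ``ankle_stance = phi1 - phi2 - pi/2`` (positive = dorsiflexion),
    ``ankle_swing = phi4 - phi3 - pi/2`` (mirrored convention),
    ``hip = pi - phi2 + phi3`` wrapped to (-pi, pi], positive when the
    swing leg is ahead of the stance leg.
    """

    ankle_stance: float
    ankle_swing: float
    hip: float


def standing_state(phase: Phase = Phase.FOOT) -> State:
    """Canonical standing pose: both feet flat, legs vertical, at rest."""
    return State(
        phi=np.array([math.pi, math.pi / 2, -math.pi / 2, 0.0]),
        phidot=np.zeros(4),
        phase=phase,
    )


def joint_angles(state: State) -> JointAngles:
    """Signed ankle and hip joint angles of ``state``."""
    p1, p2, p3, p4 = state.phi
    hip = math.pi - p2 + p3
    hip = (hip + math.pi) % (2 * math.pi) - math.pi  # wrap to (-pi, pi]
    if hip == -math.pi:
        hip = math.pi
    return JointAngles(
        ankle_stance=p1 - p2 - math.pi / 2,
        ankle_swing=p4 - p3 - math.pi / 2,
        hip=hip,
    )


# ---------------------------------------------------------------------------
# Forward kinematics


def _e(phi):
    return np.array([math.cos(phi), math.sin(phi)])


def _eperp(phi):
    return np.array([-math.sin(phi), math.cos(phi)])


@dataclass
class Kinematics:
    """Positions and velocities of the joints and centers of mass.

    All positions are 2-vectors in ground coordinates; velocities are
    their exact time derivatives.  ``com`` is the whole-body CoM.
    """

    toe: np.ndarray
    heel: np.ndarray
    hip: np.ndarray
    ankle_swing: np.ndarray
    toe_swing: np.ndarray
    com_foot_st: np.ndarray
    com_leg_st: np.ndarray
    com_leg_sw: np.ndarray
    com_foot_sw: np.ndarray
    com: np.ndarray
    v_toe: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v_heel: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v_hip: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v_ankle_swing: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v_toe_swing: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v_com: np.ndarray = field(default_factory=lambda: np.zeros(2))


def anchor_to_toe(state: State, params: WalkerParams, anchor) -> np.ndarray:
    """Stance-toe position given the pinned contact point of the phase.

    In HEEL/FOOT(+FOOT_DOUBLE) phases the pinned point is the heel; in
    TOE/DOUBLE it is the toe itself.
    """
    anchor = np.asarray(anchor, dtype=float)
    if state.phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        return anchor - params.l_f * _e(state.phi[0])
    if state.phase in (Phase.TOE, Phase.DOUBLE):
        return anchor
    raise ValueError(f"unknown phase {state.phase!r}")


def forward_kinematics(
    state: State, params: WalkerParams, anchor=(0.0, 0.0)
) -> Kinematics:
    """Joint and CoM positions/velocities for ``state``.

    ``anchor`` is the ground position of the pinned contact point for the
    current phase (heel in HEEL/FOOT, toe in TOE/DOUBLE); the pinned
    point has zero velocity.
    """
    p = params
    toe = anchor_to_toe(state, p, anchor)
    phi, phidot = state.phi, state.phidot
    e = [_e(a) for a in phi]
    ep = [_eperp(a) for a in phi]

    heel = toe + p.l_f * e[0]
    hip = heel + p.l * e[1]
    a2 = hip + p.l * e[2]
    toe2 = a2 + p.l_f * e[3]
    c1 = toe + (p.l_f - p.d_f) * e[0]
    c2 = heel + p.d_l * e[1]
    c3 = hip + (p.l - p.d_l) * e[2]
    c4 = a2 + (p.l_f - p.d_f) * e[3]

    # velocity of the chain root (toe) from the pin constraint
    if state.phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        v_toe = -p.l_f * phidot[0] * ep[0]
    else:
        v_toe = np.zeros(2)
    v_heel = v_toe + p.l_f * phidot[0] * ep[0]
    v_hip = v_heel + p.l * phidot[1] * ep[1]
    v_a2 = v_hip + p.l * phidot[2] * ep[2]
    v_toe2 = v_a2 + p.l_f * phidot[3] * ep[3]
    v_c1 = v_toe + (p.l_f - p.d_f) * phidot[0] * ep[0]
    v_c2 = v_heel + p.d_l * phidot[1] * ep[1]
    v_c3 = v_hip + (p.l - p.d_l) * phidot[2] * ep[2]
    v_c4 = v_a2 + (p.l_f - p.d_f) * phidot[3] * ep[3]

    com = (p.m_h * hip + p.m_l * (c2 + c3) + p.m_f * (c1 + c4)) / p.m_tot
    v_com = (p.m_h * v_hip + p.m_l * (v_c2 + v_c3) + p.m_f * (v_c1 + v_c4)) / p.m_tot

    return Kinematics(
        toe=toe, heel=heel, hip=hip, ankle_swing=a2, toe_swing=toe2,
        com_foot_st=c1, com_leg_st=c2, com_leg_sw=c3, com_foot_sw=c4, com=com,
        v_toe=v_toe, v_heel=v_heel, v_hip=v_hip, v_ankle_swing=v_a2,
        v_toe_swing=v_toe2, v_com=v_com,
    )


def relabel_step(state: State) -> State:
    """Swap leg/foot roles at a step boundary (toe-off).

    Re-expresses the same physical configuration in the chain rooted at
    the new stance foot: segments 1<->4 and 2<->3 exchange roles, each
    angle shifting by pi because the proximal->distal direction reverses.
    The map is an exact involution.
    """
    p1, p2, p3, p4 = state.phi
    d1, d2, d3, d4 = state.phidot
    return State(
        phi=np.array([p4 + math.pi, p3 + math.pi, p2 - math.pi, p1 - math.pi]),
        phidot=np.array([d4, d3, d2, d1]),
        phase=state.phase,
        t=state.t,
        pulse_active=False,
        hip_crossed=False,
    )
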