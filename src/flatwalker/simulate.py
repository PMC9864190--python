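"""Event-driven integration of strides: phases, events, impact maps.

A stride runs from one toe-off to the next.  Starting phase is
HEEL (the new stance heel was pinned at the preceding heel strike), and
the phase sequence is

    HEEL -(toe strike)-> FOOT -(heel-off)-> TOE -(heel strike)-> DOUBLE
    -(toe-off)-> relabel,

with the three-phase variant skipping TOE when heel strike arrives
before the center of pressure reaches the toe.  Impacts (toe strike,
heel strike) are instantaneous and inelastic: the generalized
impulse-momentum equations are solved over all active contacts, and the
impulsive work equals half the dot product of each contact's pre-impact
velocity with its impulse.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import (
    ChainCoefficients,
    _eom_arrays,
    base_velocity,
    chain_coefficients,
    constraint_jacobian,
    ground_reaction,
    mass_matrix,
)
from .model import FLAT_FOOT_ANGLE, Phase, State
from .params import ActuationParams, WalkerParams

__all__ = [
    "StrideFailure",
    "StrideError",
    "ImpactResult",
    "PhaseSegment",
    "StrideResult",
    "impulsive_work",
    "impact_map",
    "simulate_stride",
]

#: Abort guards: these mark infeasible strides, not errors.
T_MAX_STRIDE = 10.0
HIP_MIN_HEIGHT = 0.5
MAX_RESTARTS = 12
EVENT_TIE_TOL = 1e-9


class StrideFailure(enum.Enum):
    """Why a stride did not complete (infeasibility, not an exception)."""

    FALL = "fall"
    SCUFF = "scuff"
    TIMEOUT = "timeout"
    EVENT_ORDER = "event_order"
    SINGULAR = "singular"


class StrideError(RuntimeError):
    """Raised by callers that require a completed stride."""

    def __init__(self, failure: StrideFailure, t: float):
        super().__init__(f"stride failed: {failure.value} at t={t:.4f}")
        self.failure = failure


def impulsive_work(impulse, v_pre) -> float:
    """Half the dot product of ground-reaction impulse and pre-impact
    contact velocity: ``1/2 (S_x v_x- + S_y v_y-)``."""
    S = np.asarray(impulse, dtype=float)
    v = np.asarray(v_pre, dtype=float)
    return 0.5 * float(S @ v)


@dataclass
class ImpactResult:
    """Outcome of an instantaneous inelastic impact.

    ``impulses`` holds the generalized impulse of every constraint row of
    the post-impact contact set; ``contact_impulse``/``contact_v_pre``
    the Cartesian impulse and pre-impact velocity of the colliding point
    (toe for a toe strike, leading heel for a heel strike).
    """

    label: str
    t: float
    state_pre: State
    state_post: State
    impulses: np.ndarray
    contact_impulse: np.ndarray
    contact_v_pre: np.ndarray
    work: float
    ke_pre: float
    ke_post: float


@dataclass
class PhaseSegment:
    """One continuously integrated span of a stride."""

    phase: Phase
    t0: float
    t1: float
    sol: object  # scipy OdeSolution (dense output over [t0, t1])
    anchor: np.ndarray
    pulse_active: bool
    hip_crossed: bool

    def sample(self, n: int):
        t = np.linspace(self.t0, self.t1, n)
        y = self.sol(t)
        return t, y


@dataclass
class StrideResult:
    """One toe-off -> toe-off step of the walker.

    ``end_state`` is the final state after leg relabeling, expressed at
    the next stride's section; ``step_length`` is the advance of the
    ground heel-contact position over the cycle and ``speed`` is
    ``step_length / period``.
    """

    segments: list[PhaseSegment] = field(default_factory=list)
    events: dict = field(default_factory=dict)
    impacts: list[ImpactResult] = field(default_factory=list)
    failure: StrideFailure | None = None
    failure_time: float = math.nan
    four_phase: bool | None = None
    step_length: float = math.nan
    period: float = math.nan
    end_state: State | None = None
    start_state: State | None = None
    scuffs: int = 0

    @property
    def ok(self) -> bool:
        return self.failure is None

    @property
    def speed(self) -> float:
        return self.step_length / self.period

    @property
    def collision_loss(self) -> float:
        """Kinetic energy lost at impacts (positive number)."""
        return -sum(im.work for im in self.impacts)

    def require_ok(self) -> "StrideResult":
        if not self.ok:
            raise StrideError(self.failure, self.failure_time)
        return self


# ---------------------------------------------------------------------------
# Impact map


def _kinetic_energy_v(phi, v6, co: ChainCoefficients) -> float:
    return 0.5 * float(v6 @ mass_matrix(phi, co) @ v6)


def impact_map(
    state: State,
    new_phase: Phase,
    params: WalkerParams,
    co: ChainCoefficients | None = None,
    label: str = "impact",
) -> ImpactResult:
    """Resolve an instantaneous inelastic impact.

    Solves ``M (v+ - v-) = J^T S`` with ``J v+ = 0`` over the constraint
    rows of ``new_phase`` (newly and already constrained contacts
    together); positions are unchanged.  Already-static contacts carry
    zero pre-impact velocity and therefore contribute no impulsive work.
    """
    co = co or chain_coefficients(params)
    p = params
    phi, phidot = state.phi, state.phidot
    v_pre = np.concatenate([base_velocity(state.phase, phi, phidot, p), phidot])
    M = mass_matrix(phi, co)
    J, _ = constraint_jacobian(new_phase, phi, phidot, p)
    m = J.shape[0]
    KKT = np.zeros((6 + m, 6 + m))
    KKT[:6, :6] = M
    KKT[:6, 6:] = -J.T
    KKT[6:, :6] = J
    rhs = np.concatenate([M @ v_pre, np.zeros(m)])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"singular contact Jacobian: {exc}") from exc
    v_post, S = sol[:6], sol[6:]
    c_pre = J @ v_pre  # pre-impact velocity of each constraint row
    work = 0.5 * float(S @ c_pre)

    # Cartesian impulse / velocity at the colliding point for reporting.
    if label == "toe_strike":
        # angle-row impulse mu about the heel <-> vertical impulse mu/l_f
        # at the toe (foot flat at impact, toe ahead of the heel).
        mu = S[2]
        contact_S = np.array([0.0, mu / p.l_f])
        contact_v = np.array([0.0, p.l_f * phidot[0]])
    else:
        contact_S = S[-2:].copy()
        contact_v = c_pre[-2:].copy()

    post = state.copy(phase=new_phase)
    post.phidot = v_post[2:].copy()
    return ImpactResult(
        label=label,
        t=state.t,
        state_pre=state.copy(),
        state_post=post,
        impulses=S,
        contact_impulse=contact_S,
        contact_v_pre=contact_v,
        work=work,
        ke_pre=_kinetic_energy_v(phi, v_pre, co),
        ke_post=_kinetic_energy_v(phi, v_post, co),
    )


# ---------------------------------------------------------------------------
# Event functions


try:
    from ._fast import HAVE_NUMBA, lam_fast, pack_params, rhs_fast
    from ._fast import DOUBLE as _C_DOUBLE
    from ._fast import FOOT as _C_FOOT
    from ._fast import FOOT_DOUBLE as _C_FOOT_DOUBLE
    from ._fast import HEEL as _C_HEEL
    from ._fast import TOE as _C_TOE

    _PHASE_CODE = {
        Phase.HEEL: _C_HEEL,
        Phase.FOOT: _C_FOOT,
        Phase.TOE: _C_TOE,
        Phase.DOUBLE: _C_DOUBLE,
        Phase.FOOT_DOUBLE: _C_FOOT_DOUBLE,
    }
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _make_rhs(phase, pulse, crossed, p, act, co):
    if HAVE_NUMBA:
        P = pack_params(p, act, co)
        code = _PHASE_CODE[phase]

        def rhs(t, y):
            return rhs_fast(y, code, pulse, crossed, P)

        return rhs

    def rhs(t, y):
        qdd, _, _ = _eom_arrays(y[:4], y[4:], phase, pulse, crossed, p, act, co)
        return np.concatenate([y[4:], qdd[2:]])

    return rhs


def _lam(y, phase, pulse, crossed, p, act, co):
    if HAVE_NUMBA:
        return lam_fast(y, _PHASE_CODE[phase], pulse, crossed, pack_params(p, act, co))
    _, lam, _ = _eom_arrays(y[:4], y[4:], phase, pulse, crossed, p, act, co)
    return lam


def _heel2_height(y, anchor, phase, p):
    phi = y[:4]
    if phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        y_heel = anchor[1]
    else:
        y_heel = anchor[1] + p.l_f * math.sin(phi[0])
    return y_heel + p.l * (math.sin(phi[1]) + math.sin(phi[2]))


def _hip_height(y, anchor, phase, p):
    phi = y[:4]
    if phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        return anchor[1] + p.l * math.sin(phi[1])
    return anchor[1] + p.l_f * math.sin(phi[0]) + p.l * math.sin(phi[1])


def _build_events(phase, anchor, pulse, crossed, p, act, co):
    """Terminal event functions for one phase; returns (names, funcs)."""
    names, funcs = [], []
    if HAVE_NUMBA:
        P = pack_params(p, act, co)
        code = _PHASE_CODE[phase]

        def lamf(y):
            return lam_fast(y, code, pulse, crossed, P)

    else:

        def lamf(y):
            return _lam(y, phase, pulse, crossed, p, act, co)

    def add(name, f, direction, terminal=True):
        f.terminal = terminal
        f.direction = direction
        names.append(name)
        funcs.append(f)

    add("fall", lambda t, y: _hip_height(y, anchor, phase, p) - HIP_MIN_HEIGHT, -1)

    if phase is Phase.HEEL:
        add("toe_strike", lambda t, y: y[0] - FLAT_FOOT_ANGLE, -1)
    if phase in (Phase.FOOT, Phase.FOOT_DOUBLE):

        def heel_off(t, y):
            lam = lamf(y)
            F, mu = lam[:2], lam[2]
            toe_x = anchor[0] - p.l_f * math.cos(y[0])
            cop_x = anchor[0] + mu / F[1] if abs(F[1]) > 1e-12 else toe_x
            return toe_x - cop_x

        add("heel_off", heel_off, -1)
    if phase in (Phase.FOOT, Phase.TOE):
        add("heel_strike", lambda t, y: _heel2_height(y, anchor, phase, p), -1)
        if act.T_a != 0.0 and not pulse:
            add("ankle_reversal", lambda t, y: y[4] - y[5], -1)
    if phase in (Phase.DOUBLE, Phase.FOOT_DOUBLE):

        def toe_off(t, y):
            lam = lamf(y)
            return lam[1]  # vertical force at the trailing contact pin

        add("toe_off", toe_off, -1)
        add("lead_toe_strike", lambda t, y: y[3] - 0.0, -1)
    if act.k_hf > 0 or act.k_hr > 0:
        # record-only: the sign-switched hip spring is continuous in
        # torque, so the crossing needs no integration restart
        add("hip_cross", lambda t, y: math.pi - y[1] + y[2], 0, terminal=False)

    return names, funcs


_EVENT_PRIORITY = {
    "fall": -1,
    "toe_off": 0,
    "toe_strike": 1,
    "heel_off": 2,
    "heel_strike": 3,
    "ankle_reversal": 4,
    "hip_cross": 5,
    "lead_toe_strike": 6,
}


# ---------------------------------------------------------------------------
# Stride integration


def simulate_stride(
    q0: State,
    params: WalkerParams,
    act: ActuationParams,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    t_max: float = T_MAX_STRIDE,
    co: ChainCoefficients | None = None,
    max_step: float = np.inf,
    start_phase: Phase = Phase.HEEL,
    stop_at_heel_strike: bool = False,
) -> StrideResult:
    """Integrate one full step from a post-toe-off state.

    ``q0`` is the state just after toe-off (phase HEEL, stance heel
    pinned at the origin).  Integration uses an adaptive Runge-Kutta(4,5)
    scheme with the given tolerances, stopping at each phase-changing
    event; impacts are applied by :func:`impact_map`.  On success the
    returned stride carries the relabeled end state; guard violations
    (fall, timeout, out-of-order contact) set ``failure`` instead.
    """
    p = params
    co = co or chain_coefficients(p)
    res = StrideResult(start_state=q0.copy())
    phase = start_phase
    pulse = bool(q0.pulse_active)
    crossed = bool(q0.hip_crossed)
    anchor = np.array([0.0, 0.0])
    y = np.concatenate([q0.phi, q0.phidot]).astype(float)
    t = 0.0
    t_end = t_max
    heel_strike_seen = False
    restarts = 0
    # The pulse switch-on can be masked by a coinciding terminal event
    # (the integrator keeps only roots up to the earliest terminal one);
    # track the stance-ankle rate sign across restarts to catch it.
    thd_sign = None

    def fail(code, tf):
        res.failure = code
        res.failure_time = tf
        return res

    while True:
        if restarts > MAX_RESTARTS:
            return fail(StrideFailure.EVENT_ORDER, t)
        rhs = _make_rhs(phase, pulse, crossed, p, act, co)

        # An event can already be past its trigger when a phase (or the
        # pulse) switches on -- e.g. the pulse torque jumping the CoP
        # beyond the toe, or the trailing toe unloading at heel strike.
        # Such crossings produce no sign change for the integrator, so
        # they are handled immediately.
        name = None
        try:
            if phase in (Phase.FOOT, Phase.FOOT_DOUBLE):
                lam = _lam(y, phase, pulse, crossed, p, act, co)
                Fy, mu = lam[1], lam[2]
                toe_x = anchor[0] - p.l_f * math.cos(y[0])
                cop_x = anchor[0] + mu / Fy if abs(Fy) > 1e-12 else toe_x
                if toe_x - cop_x <= 0:
                    name = "heel_off"
            elif phase is Phase.DOUBLE:
                lam = _lam(y, phase, pulse, crossed, p, act, co)
                if lam[1] <= 0:
                    name = "toe_off"
        except (ArithmeticError, np.linalg.LinAlgError):
            return fail(StrideFailure.SINGULAR, t)

        if name is None:
            names, funcs = _build_events(phase, anchor, pulse, crossed, p, act, co)
            try:
                sol = solve_ivp(
                    rhs, (t, t_end), y, method="RK45", rtol=rtol, atol=atol,
                    events=funcs, dense_output=True, max_step=max_step,
                )
            except (ArithmeticError, np.linalg.LinAlgError):
                return fail(StrideFailure.SINGULAR, t)
            if not sol.success:
                return fail(StrideFailure.SINGULAR, t)

            # earliest terminal event (tie-break in canonical contact order)
            fired = [
                (te[0], _EVENT_PRIORITY[names[i]], names[i], i)
                for i, te in enumerate(sol.t_events)
                if len(te) and names[i] != "hip_cross"
            ]
            for i, te in enumerate(sol.t_events):
                if names[i] == "hip_cross" and len(te):
                    res.events.setdefault("hip_cross", float(te[0]))
            if not fired:
                if len(sol.t) > 1:
                    res.segments.append(
                        PhaseSegment(phase, t, sol.t[-1], sol.sol, anchor.copy(), pulse, crossed)
                    )
                return fail(StrideFailure.TIMEOUT, sol.t[-1])
            t_min = min(r[0] for r in fired)
            near = [r for r in fired if r[0] - t_min <= EVENT_TIE_TOL]
            near.sort(key=lambda r: r[1])  # canonical contact order on ties
            t_ev = near[0][0]
            name = near[0][2]
            y_ev = sol.y_events[near[0][3]][0].copy()

            # A terminal event can mask the pulse switch-on in the same
            # integration step (the integrator keeps only roots up to
            # the earliest terminal one); catch it by the sign change of
            # the stance-ankle rate.
            if act.T_a != 0.0 and not pulse and phase in (Phase.FOOT, Phase.TOE):
                s_now = math.copysign(1.0, y[4] - y[5])
                if thd_sign == 1.0 and s_now == -1.0 and name != "ankle_reversal":
                    res.events.setdefault("ankle_reversal", t)
                    pulse = True
                thd_sign = s_now

            if t_ev > t:
                res.segments.append(
                    PhaseSegment(phase, t, t_ev, sol.sol, anchor.copy(), pulse, crossed)
                )
            t, y = t_ev, y_ev

        if name == "fall":
            return fail(StrideFailure.FALL, t)
        if name == "lead_toe_strike":
            return fail(StrideFailure.EVENT_ORDER, t)
        if name == "ankle_reversal":
            res.events.setdefault("ankle_reversal", t)
            pulse = True
            restarts += 1
            continue
        state_ev = State.from_q(y, phase=phase, t=t, pulse_active=pulse, hip_crossed=crossed)

        if name == "toe_strike":
            if heel_strike_seen:
                return fail(StrideFailure.EVENT_ORDER, t)
            res.events["toe_strike"] = t
            im = impact_map(state_ev, Phase.FOOT, p, co, label="toe_strike")
            res.impacts.append(im)
            y[:4] = im.state_post.phi
            y[0] = FLAT_FOOT_ANGLE  # project exactly onto the flat-foot manifold
            y[4:] = im.state_post.phidot
            y[4] = 0.0
            phase = Phase.FOOT
            continue

        if name == "heel_off":
            res.events["heel_off"] = t
            # anchor moves from the heel to the toe contact point
            anchor = anchor - p.l_f * np.array([math.cos(y[0]), math.sin(y[0])])
            phase = Phase.TOE if phase is Phase.FOOT else Phase.DOUBLE
            continue

        if name == "heel_strike":
            if y[6] >= 0:  # swing leg not rotating clockwise: foot scuffing
                res.scuffs += 1
                restarts += 1
                # nudge past the crossing and keep integrating
                y = y + 1e-10 * rhs(t, y)
                t = t + 1e-10
                continue
            heel_strike_seen = True
            res.events["heel_strike"] = t
            res.four_phase = phase is Phase.TOE
            if stop_at_heel_strike:
                # return the smooth pre-impact state (heel-strike section)
                if phase is Phase.TOE:
                    heel2_x = (
                        anchor[0]
                        + p.l_f * math.cos(y[0])
                        + p.l * (math.cos(y[1]) + math.cos(y[2]))
                    )
                else:
                    heel2_x = anchor[0] + p.l * (math.cos(y[1]) + math.cos(y[2]))
                res.step_length = heel2_x
                res.period = t
                res.end_state = state_ev
                return res
            new_phase = Phase.DOUBLE if phase is Phase.TOE else Phase.FOOT_DOUBLE
            im = impact_map(state_ev, new_phase, p, co, label="heel_strike")
            res.impacts.append(im)
            y[4:] = im.state_post.phidot
            # step length: advance of the ground heel-contact point
            if phase is Phase.TOE:
                heel2_x = (
                    anchor[0]
                    + p.l_f * math.cos(y[0])
                    + p.l * (math.cos(y[1]) + math.cos(y[2]))
                )
            else:
                heel2_x = anchor[0] + p.l * (math.cos(y[1]) + math.cos(y[2]))
            res.step_length = heel2_x
            phase = new_phase
            if phase is Phase.FOOT_DOUBLE:
                # three-phase gait: heel-off normally follows at once; let
                # the CoP event decide on the next iteration
                pass
            continue

        if name == "toe_off":
            res.events["toe_off"] = t
            if phase is Phase.FOOT_DOUBLE:
                res.events.setdefault("heel_off", t)
            res.period = t
            end = State.from_q(y, phase=phase, t=t, pulse_active=pulse, hip_crossed=crossed)
            from .model import relabel_step

            res.end_state = relabel_step(end)
            res.end_state.phase = Phase.HEEL
            if "heel_off" not in res.events:
                res.events["heel_off"] = t
            return res

        raise AssertionError(f"unhandled event {name}")
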