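"""Work integration, energy audit, and metabolic cost of transport.

Joint powers are evaluated on the integrator's dense output and
integrated with a sign-split trapezoid rule, so positive and negative
actuator work accumulate separately.  The metabolic work of a step is

    W_met = eta_plus * W_plus + eta_minus * W_minus

with inverse efficiencies eta_plus = 4 (positive work) and
eta_minus = -0.83 (negative work), and the metabolic cost of transport
is W_met / (m_tot g s) with step length s (m_tot = g = 1 in
dimensionless units).  Damper losses are bookkept separately and do not
enter the metabolic cost; collision losses enter only implicitly,
through the positive work needed to compensate them over a periodic
cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import _damper_flags, chain_coefficients, mass_matrix
from .model import Phase
from .params import ActuationParams, EfficiencyParams, WalkerParams
from .simulate import StrideResult

__all__ = [
    "EnergyBreakdown",
    "joint_work",
    "mcot",
    "energy_audit",
    "stride_energetics",
    "segment_powers",
]

#: samples per phase segment for work quadrature (refinement factor)
N_QUAD = 1200


@dataclass
class EnergyBreakdown:
    """Per-stride mechanical/metabolic energy ledger.

    Work terms are signed (W- <= 0 <= W+); ``w_impulsive`` is the total
    collision work (<= 0), ``w_damper`` the ankle-damper work (<= 0,
    excluded from the metabolic cost), ``w_gravity`` the gravity work.
    """

    w_plus_ankle: float = 0.0
    w_minus_ankle: float = 0.0
    w_plus_hip: float = 0.0
    w_minus_hip: float = 0.0
    w_damper: float = 0.0
    w_impulsive: float = 0.0
    w_gravity: float = 0.0
    step_length: float = math.nan
    period: float = math.nan
    metabolic_work: float = math.nan
    mcot: float = math.nan
    audit_residual: float = math.nan

    @property
    def w_plus(self) -> float:
        return self.w_plus_ankle + self.w_plus_hip

    @property
    def w_minus(self) -> float:
        return self.w_minus_ankle + self.w_minus_hip

    @property
    def collision_loss(self) -> float:
        return -self.w_impulsive

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "w_plus_ankle", "w_minus_ankle", "w_plus_hip", "w_minus_hip",
            "w_damper", "w_impulsive", "w_gravity", "step_length", "period",
            "metabolic_work", "mcot", "audit_residual",
        )}
        return d


def mcot(w_plus: float, w_minus: float, s: float, eff: EfficiencyParams | None = None) -> float:
    """Metabolic cost of transport ``(eta+ W+ + eta- W-) / s``.

    Both terms contribute positively since ``eta_minus`` and ``W-`` are
    both negative.  Total mass and gravity are 1 in dimensionless units.
    """
    if s <= 0:
        raise ValueError("step length must be positive")
    eff = eff or EfficiencyParams()
    return (eff.eta_plus * w_plus + eff.eta_minus * w_minus) / s


def segment_powers(seg, params: WalkerParams, act: ActuationParams, n: int = N_QUAD):
    """Sampled joint/damper powers over one phase segment.

    Returns a dict of time and power arrays.  Actuator power at a joint
    is the torque times the joint angular rate (damper torque excluded
    and accumulated separately).
    """
    t, y = seg.sample(n)
    phi = y[:4]
    phidot = y[4:]
    th_a_dot = phidot[0] - phidot[1]           # stance dorsiflexion rate
    th_sw_dot = phidot[3] - phidot[2]          # swing dorsiflexion rate
    th_a = phi[0] - phi[1] - math.pi / 2
    th_sw = phi[3] - phi[2] - math.pi / 2
    psi = math.pi - phi[1] + phi[2]
    psi_dot = phidot[2] - phidot[1]

    tau1 = act.k_a * th_a + (act.T_a if seg.pulse_active else 0.0)
    tau3 = act.k_a * th_sw
    k_h = np.where(psi > 0, act.k_hr, act.k_hf)
    u = -k_h * psi

    p_ankle_st = -tau1 * th_a_dot
    p_ankle_sw = -tau3 * th_sw_dot
    p_hip = u * psi_dot
    damp_st, damp_sw = _damper_flags(seg.phase)
    p_damp = np.zeros_like(t)
    if damp_st:
        p_damp -= params.c_a * th_a_dot**2
    if damp_sw:
        p_damp -= params.c_a * th_sw_dot**2
    return {
        "t": t,
        "ankle_stance": p_ankle_st,
        "ankle_swing": p_ankle_sw,
        "ankle": p_ankle_st + p_ankle_sw,
        "hip": p_hip,
        "damper": p_damp,
    }


def _signsplit_trapz(t, p):
    plus = np.trapezoid(np.clip(p, 0.0, None), t)
    minus = np.trapezoid(np.clip(p, None, 0.0), t)
    return plus, minus


def joint_work(
    stride: StrideResult,
    params: WalkerParams,
    act: ActuationParams,
    n: int = N_QUAD,
):
    """Positive/negative actuator work per joint and damper work.

    Quadrature: sign-split trapezoid rule on ``n`` samples of the dense
    output of each phase segment.
    """
    wp_ankle = wm_ankle = wp_hip = wm_hip = w_damp = 0.0
    for seg in stride.segments:
        pw = segment_powers(seg, params, act, n)
        a_p, a_m = _signsplit_trapz(pw["t"], pw["ankle"])
        h_p, h_m = _signsplit_trapz(pw["t"], pw["hip"])
        wp_ankle += a_p
        wm_ankle += a_m
        wp_hip += h_p
        wm_hip += h_m
        w_damp += np.trapezoid(pw["damper"], pw["t"])
    return {
        "w_plus_ankle": wp_ankle,
        "w_minus_ankle": wm_ankle,
        "w_plus_hip": wp_hip,
        "w_minus_hip": wm_hip,
        "w_damper": w_damp,
    }


def _potential(phi, anchor, phase, co, params):
    """Potential energy from the chain first moments (vectorized)."""
    if phase in (Phase.HEEL, Phase.FOOT, Phase.FOOT_DOUBLE):
        y_toe = anchor[1] - params.l_f * np.sin(phi[0])
    else:
        y_toe = anchor[1]
    return co.g * (co.m_tot * y_toe + co.b @ np.sin(phi))


def _kinetic(phi, phidot, phase, co, params):
    from .dynamics import base_velocity

    v = np.concatenate([base_velocity(phase, phi, phidot, params), phidot])
    return 0.5 * float(v @ mass_matrix(phi, co) @ v)


def gravity_work(stride: StrideResult, params: WalkerParams) -> float:
    """Work done by gravity over the stride (minus the PE change)."""
    co = chain_coefficients(params)
    w = 0.0
    for seg in stride.segments:
        y0 = seg.sol(seg.t0)
        y1 = seg.sol(seg.t1)
        w += _potential(y0[:4], seg.anchor, seg.phase, co, params) - _potential(
            y1[:4], seg.anchor, seg.phase, co, params
        )
    return w


def energy_audit(
    stride: StrideResult,
    params: WalkerParams,
    act: ActuationParams,
    n: int = N_QUAD,
) -> dict:
    """Mechanical-work ledger of a stride and its closure residual.

    The kinetic energy change over the stride must equal the sum of
    gravity work, joint (actuator) work, damper work, and impulsive
    (collision) work; the returned ``residual`` is dKE minus that sum
    and vanishes for an exactly integrated stride.  Over a periodic
    cycle dKE itself is zero.
    """
    co = chain_coefficients(params)
    works = joint_work(stride, params, act, n)
    w_grav = gravity_work(stride, params)
    w_imp = sum(im.work for im in stride.impacts)
    seg0 = stride.segments[0]
    seg1 = stride.segments[-1]
    y0, y1 = seg0.sol(seg0.t0), seg1.sol(seg1.t1)
    ke0 = _kinetic(y0[:4], y0[4:], seg0.phase, co, params)
    ke1 = _kinetic(y1[:4], y1[4:], seg1.phase, co, params)
    dke = ke1 - ke0
    w_joint = (
        works["w_plus_ankle"] + works["w_minus_ankle"]
        + works["w_plus_hip"] + works["w_minus_hip"]
    )
    residual = dke - (w_grav + w_joint + works["w_damper"] + w_imp)
    return {
        "dKE": dke,
        "w_gravity": w_grav,
        "w_ankle": works["w_plus_ankle"] + works["w_minus_ankle"],
        "w_hip": works["w_plus_hip"] + works["w_minus_hip"],
        "w_damper": works["w_damper"],
        "w_impulsive": w_imp,
        "residual": residual,
        **works,
    }


def stride_energetics(
    stride: StrideResult,
    params: WalkerParams,
    act: ActuationParams,
    eff: EfficiencyParams | None = None,
    n: int = N_QUAD,
    free_hip_cost: bool = False,
) -> EnergyBreakdown:
    """Full energy breakdown of a completed stride, including MCOT.

    With ``free_hip_cost`` the hip actuator's work is excluded from the
    metabolic cost (the symmetric-hip-spring thought experiment); the
    mechanical ledger is unchanged.
    """
    eff = eff or EfficiencyParams()
    audit = energy_audit(stride, params, act, n)
    s = stride.step_length
    if free_hip_cost:
        wp, wm = audit["w_plus_ankle"], audit["w_minus_ankle"]
    else:
        wp = audit["w_plus_ankle"] + audit["w_plus_hip"]
        wm = audit["w_minus_ankle"] + audit["w_minus_hip"]
    met = eff.eta_plus * wp + eff.eta_minus * wm
    return EnergyBreakdown(
        w_plus_ankle=audit["w_plus_ankle"],
        w_minus_ankle=audit["w_minus_ankle"],
        w_plus_hip=audit["w_plus_hip"],
        w_minus_hip=audit["w_minus_hip"],
        w_damper=audit["w_damper"],
        w_impulsive=audit["w_impulsive"],
        w_gravity=audit["w_gravity"],
        step_length=s,
        period=stride.period,
        metabolic_work=met,
        mcot=met / s if s > 0 else math.nan,
        audit_residual=audit["residual"],
    )
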