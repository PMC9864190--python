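"""Tidy exports: trajectories, impacts, sweep tables, run manifests."""

from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import _eom_arrays, chain_coefficients, ground_reaction
from .energetics import segment_powers
from .model import Phase, State
from .params import ActuationParams, WalkerParams
from .simulate import StrideResult

__all__ = ["trajectory_frame", "impacts_records", "write_manifest", "DATA_DICTIONARY"]

DATA_DICTIONARY = {
    "t": "dimensionless time since stride start (toe-off)",
    "phi1": "stance-foot angle (rad, CCW from +x, toe->heel vector)",
    "phi2": "stance-leg angle (ankle->hip)",
    "phi3": "swing-leg angle (hip->ankle)",
    "phi4": "swing-foot angle (heel->toe)",
    "dphi1": "stance-foot angular rate",
    "dphi2": "stance-leg angular rate",
    "dphi3": "swing-leg angular rate",
    "dphi4": "swing-foot angular rate",
    "phase": "contact phase label",
    "pulse_active": "ankle pulse torque active",
    "Fx": "horizontal ground-reaction force at the trailing/stance contact",
    "Fy": "vertical ground-reaction force at the trailing/stance contact",
    "Fx_lead": "horizontal force at the leading heel (double stance only)",
    "Fy_lead": "vertical force at the leading heel (double stance only)",
    "cop_x": "center of pressure along a flat stance foot (NaN otherwise)",
    "tau_ankle_stance": "stance ankle actuator torque (spring + pulse)",
    "tau_ankle_swing": "swing ankle actuator torque",
    "tau_hip": "hip actuator torque (restoring, conjugate to hip angle)",
    "p_ankle": "total ankle actuator power",
    "p_hip": "hip actuator power",
    "p_damper": "ankle damper power (dissipative)",
    "v": "target or achieved dimensionless walking speed",
    "k_a": "ankle spring stiffness",
    "T_a": "ankle pulse torque",
    "k_hf": "hip flexion spring stiffness",
    "k_hr": "hip retraction spring stiffness",
    "s": "step length",
    "period": "stride period (toe-off to toe-off)",
    "mcot": "metabolic cost of transport (eta+ W+ + eta- W-) / s",
    "w_plus_ankle": "positive ankle actuator work per stride",
    "w_minus_ankle": "negative ankle actuator work per stride",
    "w_plus_hip": "positive hip actuator work per stride",
    "w_minus_hip": "negative hip actuator work per stride",
    "w_damper": "ankle damper work per stride (<= 0)",
    "collision_loss": "kinetic energy lost in heel/toe impacts (>= 0)",
    "metabolic_work": "metabolic work per stride",
    "v_impact_x": "horizontal pre-impact velocity of the leading heel",
    "v_impact_y": "vertical pre-impact velocity of the leading heel",
    "S_x": "horizontal ground-reaction impulse at heel strike",
    "S_y": "vertical ground-reaction impulse at heel strike",
    "w_impulsive_hs": "impulsive work of the heel-strike collision",
    "max_floquet": "largest Floquet multiplier magnitude of the stride map",
    "stable": "max Floquet multiplier < 1",
    "residual5": "max-norm periodicity residual after five chained steps",
    "feasible": "a periodic gait satisfying all constraints was found",
    "four_phase": "heel-off precedes heel strike (toe-constrained phase present)",
}


def trajectory_frame(
    stride: StrideResult,
    params: WalkerParams,
    act: ActuationParams,
    n_per_segment: int = 200,
) -> pd.DataFrame:
    """Tidy per-sample trajectory table of one stride.

    One row per time sample: states, phase, ground-reaction forces,
    center of pressure, joint torques and powers.
    """
    co = chain_coefficients(params)
    frames = []
    for seg in stride.segments:
        t, y = seg.sample(n_per_segment)
        pw = segment_powers(seg, params, act, n_per_segment)
        rows = {
            "t": t,
            **{f"phi{i+1}": y[i] for i in range(4)},
            **{f"dphi{i+1}": y[4 + i] for i in range(4)},
        }
        F = np.zeros((len(t), 2))
        Fl = np.full((len(t), 2), np.nan)
        cop = np.full(len(t), np.nan)
        tau1 = np.zeros(len(t))
        tau3 = np.zeros(len(t))
        tauh = np.zeros(len(t))
        for i in range(len(t)):
            state = State.from_q(
                y[:, i], phase=seg.phase, t=t[i],
                pulse_active=seg.pulse_active, hip_crossed=seg.hip_crossed,
            )
            _, lam, torques = _eom_arrays(
                state.phi, state.phidot, seg.phase, seg.pulse_active,
                seg.hip_crossed, params, act, co,
            )
            gr = ground_reaction(state, lam, params, anchor=seg.anchor)
            F[i] = gr.force_trailing
            if gr.force_leading is not None:
                Fl[i] = gr.force_leading
            if gr.cop_x is not None:
                cop[i] = gr.cop_x
            tau1[i] = torques.tau_ankle_stance
            tau3[i] = torques.tau_ankle_swing
            tauh[i] = torques.tau_hip
        rows.update(
            phase=seg.phase.value,
            pulse_active=seg.pulse_active,
            Fx=F[:, 0], Fy=F[:, 1], Fx_lead=Fl[:, 0], Fy_lead=Fl[:, 1],
            cop_x=cop, tau_ankle_stance=tau1, tau_ankle_swing=tau3,
            tau_hip=tauh, p_ankle=pw["ankle"], p_hip=pw["hip"],
            p_damper=pw["damper"],
        )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def impacts_records(stride: StrideResult) -> list[dict]:
    """Impacts of a stride as JSON-ready records."""
    out = []
    for im in stride.impacts:
        out.append(
            {
                "label": im.label,
                "t": im.t,
                "work": im.work,
                "ke_pre": im.ke_pre,
                "ke_post": im.ke_post,
                "contact_impulse": list(map(float, im.contact_impulse)),
                "contact_v_pre": list(map(float, im.contact_v_pre)),
                "impulses": list(map(float, im.impulses)),
            }
        )
    return out


def write_manifest(out_dir: Path, config: dict, t_start: float, status: str) -> Path:
    """Run manifest: config hash, package version, seed, wall time."""
    from . import __version__

    canon = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "version": __version__,
        "seed": config.get("seed"),
        "wall_time_s": time.time() - t_start,
        "status": status,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
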