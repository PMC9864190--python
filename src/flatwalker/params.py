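"""Model, actuation and efficiency parameters for the flat-feet walker.

All quantities are dimensionless: masses are normalized by total mass,
lengths by leg length, time by sqrt(l/g), torque/stiffness by m*g*l,
work by m*g*l.  A dimensionless speed of 1 corresponds to about 3.1 m/s
for a 1 m leg.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "WalkerParams",
    "ActuationParams",
    "EfficiencyParams",
    "default_params",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class WalkerParams:
    """Segment masses, geometry and inertias of the four-segment walker.

    The walker is a planar chain: stance foot (toe -> heel/ankle), stance
    leg (ankle -> hip), swing leg (hip -> ankle) and swing foot
    (heel/ankle -> toe).  The hip and torso are a point mass at the hip.

    Attributes
    ----------
    m_tot : total mass (1 by normalization).
    m_h : hip + torso point mass.
    m_l : mass of each leg.
    m_f : mass of each foot.
    l : leg length (1 by normalization).
    d_l : distance of the leg CoM from the ankle, so the CoM sits
        ``l - d_l`` below the hip.
    l_f : foot length (heel to toe).
    d_f : distance of the foot CoM from the toe-side end (midfoot by
        default).
    j_l, j_f : leg / foot moments of inertia about their own CoM.  Set to
        uniform slender-rod values ``m L^2 / 12`` by default; ``0`` gives
        the point-mass limit.
    c_a : ankle damper coefficient (active when the corresponding toe is
        off the ground).
    g : gravitational constant (1 by normalization).
    """

    m_tot: float = 1.0
    m_h: float = 0.658
    m_l: float = 0.161
    m_f: float = 0.01
    l: float = 1.0
    d_l: float = 0.645
    l_f: float = 0.15
    d_f: float = 0.075
    j_l: float = 0.161 / 12.0
    j_f: float = 0.01 * 0.15**2 / 12.0
    c_a: float = 0.01
    g: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_tot", "m_h", "m_l", "m_f", "l", "l_f", "j_l", "j_f", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.d_l <= self.l):
            raise ValueError("d_l must lie within the leg")
        if not (0 <= self.d_f <= self.l_f):
            raise ValueError("d_f must lie within the foot")
        total = self.m_h + 2 * self.m_l + 2 * self.m_f
        if abs(total - self.m_tot) > 1e-9:
            raise ValueError(
                f"masses must sum to m_tot: m_h + 2*m_l + 2*m_f = {total} != {self.m_tot}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WalkerParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class ActuationParams:
    """Actuation parameters: ankle spring/pulse and hip switching springs.

    ``k_a`` is the ankle spring stiffness, ``T_a`` the constant pulse
    torque active from ankle reversal (peak dorsiflexion) until toe-off.
    ``k_hf`` / ``k_hr`` are the hip flexion / retraction spring
    stiffnesses, active before / after the hip angle's zero crossing of
    the current step.
    """

    k_a: float = 0.0
    T_a: float = 0.0
    k_hf: float = 0.0
    k_hr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_a", "k_hf", "k_hr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ActuationParams":
        return cls(**d)


@dataclass(frozen=True)
class EfficiencyParams:
    """Inverse efficiencies of positive / negative muscle-like work.

    Defaults: positive work costs 1/0.25 = 4 units of metabolic energy
    per unit of work, negative work costs 1/1.2, i.e. eta_minus = -0.83.
    """

    eta_plus: float = 4.0
    eta_minus: float = -1.0 / 1.2

    def __post_init__(self) -> None:
        if self.eta_plus <= 0:
            raise ValueError("eta_plus must be positive")
        if self.eta_minus >= 0:
            raise ValueError("eta_minus must be negative")


def default_params() -> WalkerParams:
    """Canonical parameter set of the flat-feet walker (dimensionless)."""
    return WalkerParams()


def load_params(path: str | Path) -> WalkerParams:
    """Load walker parameters from a flat YAML/JSON key-value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return WalkerParams.from_dict(d)


def dump_params(params: WalkerParams, path: str | Path) -> None:
    """Write walker parameters to a flat YAML or JSON key-value file."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
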