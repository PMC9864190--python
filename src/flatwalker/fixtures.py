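"""Canonical gait fixtures and shooting seeds.

``seed_guess(v)`` supplies the deterministic initial guess schedule for
the periodic-gait shooting solver: post-toe-off states of known
periodic gaits, stored at a few speeds and interpolated linearly in
between.  ``make_fixtures`` regenerates the canonical fixture gaits
(ankle-only optimum at v = 0.47, retraction gait at v = 0.38, low-speed
gait at v = 0.21) by running the optimizer and stores full records for
regression tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

#: Post-toe-off fixed-point states of ankle-only periodic gaits, used as
#: shooting seeds: v -> (q0 (8 values), k_a, T_a).  Filled from solved
#: gaits; intermediate speeds interpolate.
_SEED_TABLE: dict[float, tuple[list[float], float, float]] = {}

_SEED_PATH = Path(__file__).parent / "data" / "seeds.json"


def _load_seeds() -> dict:
    global _SEED_TABLE
    if not _SEED_TABLE and _SEED_PATH.exists():
        raw = json.loads(_SEED_PATH.read_text())
        _SEED_TABLE = {
            float(v): (rec["q0"], rec["k_a"], rec["T_a"]) for v, rec in raw.items()
        }
    return _SEED_TABLE


def seed_guess(v: float):
    """Initial (q0, T_a) guess for a periodic gait at speed ``v``."""
    q0, _, T_a = seed_guess_full(v)
    return q0, T_a


def seed_guess_full(v: float):
    """Initial (q0, k_a, T_a) guess, interpolated from stored seeds."""
    table = _load_seeds()
    if table:
        vs = np.array(sorted(table))
        if v <= vs[0]:
            q0, k_a, T_a = table[vs[0]]
            return np.array(q0), k_a, T_a
        if v >= vs[-1]:
            q0, k_a, T_a = table[vs[-1]]
            return np.array(q0), k_a, T_a
        i = int(np.searchsorted(vs, v))
        v0, v1 = vs[i - 1], vs[i]
        w = (v - v0) / (v1 - v0)
        q0a, ka_a, Ta = table[v0]
        q0b, ka_b, Tb = table[v1]
        return (
            (1 - w) * np.array(q0a) + w * np.array(q0b),
            (1 - w) * ka_a + w * ka_b,
            (1 - w) * Ta + w * Tb,
        )
    q0, T_a = _heuristic_guess(v)
    return q0, 0.6, T_a


def _heuristic_guess(v: float):
    """Geometry-based fallback guess when no stored seed is available."""
    s = 0.5 + 2.4 * (v - 0.16)
    beta = float(np.arcsin(min(s / 2.0, 0.95)))
    q0 = np.array([
        np.pi + 0.15,            # stance foot toe-up after heel strike
        np.pi / 2 + beta,        # stance leg behind vertical
        -np.pi / 2 - beta,       # swing leg trailing
        -0.3,                    # swing foot toe-down after push-off
        -0.8,                    # foot rotating down onto the ground
        -v / 1.0,                # leg rotating forward over the heel
        -0.3,
        -0.3,
    ])
    return q0, 0.05


def make_fixtures(out_dir=None, verbose: bool = False) -> dict:
    """Regenerate the canonical fixture gaits by optimization.

    Produces the ankle-only optima at a high and a low speed plus the
    best retraction gait at the medium speed, each solved from the
    packaged seeds.  Returns a dict of fixture records; with ``out_dir``
    also writes them as JSON.  Raises if any fixture search is
    infeasible.
    """
    from .gait import OptimizationScenario, optimize_gait, sweep_hip_stiffness

    fixtures = {}
    for name, v in [("ankle_only_v047", 0.47), ("ankle_only_v021", 0.21)]:
        _, ka, _ = seed_guess_full(v)
        grid = tuple(np.round(np.arange(ka - 0.05, ka + 0.06, 0.05), 3))
        res = optimize_gait(
            OptimizationScenario(mode="ankle_only", v=v, k_a_grid=grid),
            verbose=verbose,
        )
        if res.best is None:
            raise RuntimeError(f"fixture search infeasible: {name}")
        fixtures[name] = _gait_to_record(res.best)
    # retraction gait at v = 0.38 (zero flexion, best retraction on a grid)
    _, ka, _ = seed_guess_full(0.38)
    df = sweep_hip_stiffness(0.38, "retraction", [0.0, 0.002, 0.003],
                             k_a_grid=(round(ka, 3),))
    ok = df[df.feasible]
    if len(ok):
        row = ok.loc[ok.mcot.idxmin()]
        fixtures["retraction_v038"] = {k: _tolist(row[k]) for k in row.index}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "fixtures.json").write_text(json.dumps(fixtures, indent=2, default=_tolist))
    return fixtures


def _tolist(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def _gait_to_record(gait) -> dict:
    return {
        "q0": gait.q0.tolist(),
        "k_a": gait.act.k_a,
        "T_a": gait.act.T_a,
        "k_hf": gait.act.k_hf,
        "k_hr": gait.act.k_hr,
        "speed": gait.speed,
        "mcot": gait.mcot,
        "step_length": gait.energy.step_length,
        "period": gait.energy.period,
        "max_floquet": gait.max_floquet,
        "residual5": gait.residual5,
        "energy": gait.energy.to_dict(),
    }
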