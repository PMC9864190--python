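import json
from pathlib import Path

import numpy as np
import pytest

from flatwalker.gait import find_periodic_gait
from flatwalker.model import Phase, State
from flatwalker.params import ActuationParams, WalkerParams
from flatwalker.simulate import simulate_stride

SEEDS = Path(__file__).resolve().parents[1] / "src" / "flatwalker" / "data" / "seeds.json"


@pytest.fixture(scope="session")
def params():
    return WalkerParams()


@pytest.fixture(scope="session")
def seed_record():
    """Stored fixed-point record of an ankle-only periodic gait."""
    recs = json.loads(SEEDS.read_text())
    v = sorted(recs, key=lambda k: abs(float(k) - 0.40))[0]
    return float(v), recs[v]


@pytest.fixture(scope="session")
def periodic_gait(params, seed_record):
    """A verified ankle-only periodic gait (re-solved from the stored seed)."""
    v, rec = seed_record
    act = ActuationParams(k_a=rec["k_a"], T_a=rec["T_a"])
    gait = find_periodic_gait(
        params, act, np.asarray(rec["q0"]), v_target=v, solve_pulse=True,
    )
    assert gait is not None, "fixture gait did not converge"
    return gait


@pytest.fixture(scope="session")
def fixture_stride(periodic_gait, params):
    """One accurately integrated stride of the fixture gait."""
    s0 = State.from_q(periodic_gait.q0, phase=Phase.HEEL)
    stride = simulate_stride(s0, params, periodic_gait.act, rtol=1e-10, atol=1e-10)
    return stride.require_ok()
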