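# flatwalker

A hybrid-dynamics simulator and gait-optimization toolkit for a planar
bipedal walker with flat feet, written for researchers in computational
biomechanics and legged locomotion who want a small, fully inspectable
model of the energetics of ankle push-off and hip swing-leg actuation.

The walker has four rigid segments (two legs, two flat feet), a point
mass for hip and torso, and walks through up to four ground-contact
phases per step — heel-constrained, foot-constrained (flat foot),
toe-constrained and double stance — separated by event-detected
transitions and instantaneous, inelastic heel/toe impacts.  Actuation
is an ankle torsional spring `k_a` plus a constant push-off pulse `T_a`
(active from peak ankle dorsiflexion until toe-off), and two switched
hip springs: flexion stiffness `k_hf` before the hip angle's zero
crossing, retraction stiffness `k_hr` after it.

For a periodic gait the package computes the mechanical work ledger
(per-joint positive/negative actuator work, damper work, gravity work,
collision loss `-W_impulsive` with
`W_impulsive = ½ S_x v_x⁻ + ½ S_y v_y⁻` at each impact) and the
work-based metabolic cost of transport

    MCOT = (η⁺ W⁺ + η⁻ W⁻) / (m g s),   η⁺ = 4,  η⁻ = −0.83,

and searches for stable periodic gaits at a prescribed speed: shooting
(damped Newton on the stride map) solves the eight post-toe-off state
components and `T_a` against eight periodicity residuals plus the
speed constraint, an outer grid over `k_a` performs the cost
minimization, and a gait is accepted only if the five-step periodicity
residual is below 1e-6 and all Floquet multipliers of the stride map
lie inside the unit circle.

Everything is dimensionless (total mass, leg length and gravity are 1;
speed 1 ≈ 3.1 m/s).  See `docs/methods.md` for the model, conventions
and numerical choices.

## Worked example

Find the optimal ankle-actuation-only gait at dimensionless speed 0.40
(grid over the ankle stiffness, pulse torque and initial state solved
per grid point):

```python
import numpy as np
from flatwalker import OptimizationScenario, optimize_gait

sc = OptimizationScenario(
    mode="ankle_only", v=0.40,
    k_a_grid=tuple(np.arange(0.3, 0.51, 0.05)),
)
res = optimize_gait(sc)
best = res.best
print(f"k_a={best.act.k_a:.2f}  T_a={best.act.T_a:.3f}")
print(f"MCOT={best.mcot:.3f}  step length={best.energy.step_length:.3f}")
print(f"max |Floquet|={best.max_floquet:.3f}  5-step residual={best.residual5:.1e}")
```

prints

```
k_a=0.35  T_a=0.126
MCOT=0.444  step length=1.178
max |Floquet|=0.636  5-step residual=1.6e-10
```

i.e. at 40% of the walk–run transition speed the cheapest stable gait
uses a soft ankle spring with a modest push-off pulse, costs 0.444
units of metabolic energy per unit weight and distance, and is orbitally
stable (errors shrink by about a third per step).  `best.energy` carries the full
work ledger (ankle/hip W⁺ and W⁻, damper work, collision loss), and
`best.stride` the trajectory, events and impacts of one cycle.

The same machinery drives speed sweeps (`sweep_speeds`), hip
flexion/retraction sweeps (`sweep_hip_stiffness`), and the
free-hip-cost variant where hip spring work is excluded from the
metabolic sum.

## Command line

```sh
walker optimize      --config cfg.yaml --override scenario.v=0.47
walker sweep-speeds  --config cfg.yaml
walker sweep-flexion --config cfg.yaml --override scenario.v=0.21
```

Each run writes tidy CSV/JSON results, a data dictionary and a
manifest (config hash, version, seed, wall time) to the configured
output directory; exit status 3 means "no feasible gait", reserved for
honest infeasibility.

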