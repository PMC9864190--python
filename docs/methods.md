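# Methods

## The model

`flatwalker` simulates a planar bipedal walker built from four rigid
segments — two straight legs and two flat feet — joined by three
frictionless hinges (one hip, two ankles), with the hip and torso lumped
into a point mass at the hip joint.  Everything is dimensionless:
masses are normalized by the total mass, lengths by the leg length,
time by `sqrt(l/g)`, torques and stiffnesses by `m g l`, and work by
`m g l`; a dimensionless speed of 1 corresponds to roughly 3.1 m/s for
human proportions.

Configuration is described by four absolute segment angles, measured
counterclockwise from the +x axis along each segment's proximal-to-
distal direction, with the chain numbered from the stance toe: stance
foot, stance leg, swing leg, swing foot.  The canonical standing pose
is `phi = [pi, pi/2, -pi/2, 0]`.

Default parameters (dimensionless): hip+torso mass 0.658, leg mass
0.161, foot mass 0.01, leg length 1, leg CoM 0.645 from the ankle,
foot length 0.15 with CoM at midfoot, ankle damper coefficient 0.01.
The leg-CoM convention places the CoM 0.355 below the hip, matching
both anthropometry and the identity that the two leg-segment CoM
distances from their distal ends sum to the leg length.  Segment
moments of inertia are not part of the canonical table; the default is
the uniform-slender-rod value `m L^2 / 12` per segment, configurable
down to the point-mass limit `j = 0`.

## Contact phases and hybrid dynamics

A stride (toe-off to contralateral toe-off) passes through up to four
contact phases: heel-constrained (stance heel pinned, foot rotating),
foot-constrained (foot flat: heel pinned plus a locked foot angle),
toe-constrained (toe pinned, heel risen), and double stance (trailing
toe and leading heel pinned).  A gait is *four-phase* when heel-off
(the center of pressure reaching the toe) precedes the contralateral
heel strike and *three-phase* when heel-off follows immediately after
it.

The equations of motion use a floating base — generalized coordinates
`[x, y, phi1..phi4]` with `(x, y)` the stance-toe position — and
enforce each phase's contacts through velocity-level constraints with
Lagrange multipliers (KKT solve per evaluation).  This keeps one mass
matrix and bias vector for every phase and exposes the ground-reaction
wrench directly as the multipliers: the trailing/leading contact
forces, and in the flat-foot phase the heel force plus a constraint
moment that yields the center of pressure `x_cop = x_heel + mu / F_y`.
For a planar chain in absolute angles, mass matrix and bias have short
closed forms in the chain's first and second mass moments; these are
hand-derived, implemented in numpy and in a numba-compiled fast path,
and cross-checked in the test suite against an independent sympy
Euler–Lagrange derivation (`flatwalker.symbolic`) to 1e-10 on random
states.

Positions are projected exactly onto the constraint manifold at phase
entries (e.g. the flat-foot angle after a toe strike); within a phase,
constraint drift is bounded by the integration tolerance.

### Events

Phase transitions are located by the integrator's event detection
(scipy `solve_ivp`, RK45):

- **toe strike** — the stance foot angle reaches flat (`phi1 = pi`,
  crossing downward);
- **heel-off** — the CoP reaches the toe of the flat stance foot;
- **heel strike** — the leading heel height crosses zero while the
  swing leg rotates clockwise (`dphi3 < 0`); downward crossings with
  `dphi3 >= 0` are foot-scuffing and are ignored (integration
  continues through them, with a counter);
- **toe-off** — the vertical constraint force at the trailing toe
  crosses zero (ends the stride; legs are then relabeled);
- **ankle reversal** — the stance-ankle dorsiflexion rate crosses zero
  from above (peak dorsiflexion), switching the pulse torque on;
- **hip-angle zero crossing** — record-only (non-terminal): the
  flexion/retraction stiffness switch follows the sign of the hip
  angle inside the torque law and is continuous, so no restart is
  needed.

Two robustness details matter in practice.  First, simultaneous events
(within 1e-9) are processed in the canonical contact order (toe-off,
toe strike, heel-off, heel strike).  Second, a discrete switch can put
an event *past* its threshold instantaneously — the pulse torque jumps
the CoP beyond the toe, or the push-off has already unloaded the
trailing toe when the leading heel strikes.  Such crossings produce no
sign change for the integrator and are handled immediately at phase
entry.  This is also how the three-phase gait's "heel-off immediately
after heel strike" arises without special-casing.

If heel strike occurs while the trailing foot is still flat and the
post-impact CoP has not yet reached the toe, the simulator passes
through a transient flat-foot double-support configuration until the
CoP does; found periodic gaits leave it within the same integration
step.  A flat stance foot whose CoP falls marginally behind the heel is
not given a separate phase (the foot is held flat); found gaits show
this only as a sub-percent transient after toe strike.

Strides are abandoned (infeasible, with a failure code, not an error)
when the hip drops below 0.5 leg lengths, the stride exceeds 10 time
units, contacts occur out of order (e.g. the leading toe striking
during double stance), or event restarts exceed a cap.

### Impacts

Toe strike and heel strike are instantaneous, perfectly inelastic
impacts (no slip, no bounce): the generalized impulse–momentum
equations `M (v+ - v-) = J^T S`, `J v+ = 0` are solved over all active
contact rows, positions unchanged.  The impulsive work of each impact
equals half the dot product of the pre-impact contact-point velocity
with the ground-reaction impulse, summed over contacts; contacts that
were already static contribute nothing.  The identity
`KE+ - KE- = W_impulsive` holds to 1e-10 and is asserted on random
states in the tests.  Collision loss (a positive number) is minus the
total impulsive work of the cycle.

## Actuation

- **Ankle spring + pulse**: each ankle carries a torsional spring of
  stiffness `k_a` on its signed ankle angle (zero in standing).  The
  stance ankle additionally receives a constant pulse torque `T_a`
  between ankle reversal and toe-off — the push-off.  The swing ankle
  uses the mirrored angle convention and never receives the pulse.
- **Ankle dampers**: a linear viscous torque with coefficient `c_a`
  acts on any ankle whose toe is not in ground contact (the swing foot
  throughout, the leading foot between heel strike and its toe
  strike).  Damper work is bookkept separately from actuator work.
- **Hip springs**: two independent torsional springs act on the
  inter-leg (hip) angle — the flexion spring `k_hf` while the hip
  angle is negative (swing leg behind the stance leg), the retraction
  spring `k_hr` while it is positive.  Both are restoring (torque
  magnitude `k |hip angle|` driving the angle toward zero): the
  flexion spring accelerates the trailing swing leg forward, the
  retraction spring decelerates it past the crossing.  Selecting the
  stiffness by the sign of the hip angle keeps the torque continuous
  (zero at the crossing), so the switch needs no latching; the
  crossing is logged by a record-only integrator event.  An early
  latched variant (flexion until the first crossing, retraction until
  toe-off) re-engaged the retraction spring for re-crossings and
  created a restoring well exactly at the legs-parallel configuration
  — where the swing heel grazes the ground — destabilizing every
  hip-actuated gait; the sign-switched law removes that pathology.
  Dimensionless hip stiffnesses of order 0.001–0.02 (a few Nm/rad for
  human scale) already modulate step length and collision loss
  strongly; larger values destroy the gait.

Torque sign conventions: the scalar ankle torque is the joint tension
conjugate to the (dorsiflexion-positive) ankle angle, so the spring
term is `+k_a * angle`; the damper argument is the leg-over-foot rate
(minus the dorsiflexion rate), making the damper term `-c_a * rate`
and strictly dissipative.  The energy-rate identity
`d(KE)/dt = actuator power + gravity power + damper power` is asserted
against central differences in the tests.

## Energetics

Actuator power at each joint is torque times joint angular rate,
sampled on the integrator's dense output (default 1200 points per
phase segment, configurable) and integrated with a sign-split
trapezoid rule into positive work `W+` and negative work `W-` per
joint.  Gravity work is the potential-energy difference; damper work
is accumulated separately and excluded from the metabolic cost (on
found gaits it is ~1% of collision loss; see the acceptance
computation).  The audit

    dKE = W_gravity + W_ankle + W_hip + W_damper + W_impulsive

closes to better than 1e-5 on fixture strides and is sensitive to a 1%
corruption of a single impulse.

The metabolic cost of transport is

    MCOT = (eta+ W+ + eta- W-) / (m g s),    eta+ = 1/0.25 = 4,
                                             eta- = -1/1.2 = -0.83,

with `s` the step length and `m = g = 1`.  Both terms are positive
costs (negative work has a negative inverse efficiency).  Because a
periodic cycle balances `W+ + W- + W_damper + W_impulsive = 0`,
collision loss is paid implicitly through the positive work that
compensates it.  With `W- = -W+`, the share of metabolic cost spent on
performing negative work is `|eta-| / (eta+ + |eta-|) ~ 17%`.  The
"free hip" variant excludes hip work from the metabolic sum (the
mechanical ledger is unchanged) to reproduce the
conservative-hip-spring thought experiment.

Step length is defined as the advance of the ground heel-contact
position over one cycle (the leading heel's strike position relative
to the previous one), which makes `speed = s / period` the exact
average progression speed for a periodic gait.

## Periodic gaits and stability

A periodic gait is a fixed point of the stride map (simulate one
stride, relabel legs).  Shooting solves the square system

    P(q0) - q0 = 0  (8 equations),   speed(q0) - v = 0  (1 equation)

for the eight post-toe-off state components and the pulse torque `T_a`
by a damped Newton iteration with finite-difference Jacobians and
backtracking; trial points whose stride fails shrink the step.  With
the hip and ankle stiffnesses fixed, the equality constraints use up
all unknowns, so the constrained MCOT minimization reduces to solving
this system per stiffness and grid-searching `k_a` — which is why the
outer optimization is a grid search.  The shooting integrates at
tolerance 1e-8 (the residual must be smooth below the 1e-6 reporting
tolerance); verification re-simulates at 1e-10.

Acceptance of a gait requires (a) the end state after five chained
strides to match `q0` within 1e-6 (max norm) and (b) the largest
Floquet multiplier — eigenvalue magnitude of the stride-map Jacobian
at the post-toe-off section, central differences with step 1e-5 — to
be below 1.  Stability is a filter after solving, not a constraint;
unstable solutions are recorded but never reported as optima.  The
achieved speed must match the target within 1e-4.

Initial guesses come from a packaged table of solved ankle-only
fixed points across speeds (interpolated in speed); sweeps warm-start
each grid point from its nearest solved neighbor (continuation).  The
stride map is deterministic, so repeated runs from the same seeds are
bit-stable on one platform.

When Newton stalls, a relaxation fallback iterates the stride map with
per-stride pulse-torque feedback on the speed error, then freezes the
torque and polishes; it converges exactly to the stable gaits that are
reported.

### The shooting section matters

The post-toe-off state samples the leading foot *mid-slap*: right
after heel strike the light foot rotates down at its spring frequency
(~70 rad per time unit), so two nearby strides that toe off a few
milliseconds apart differ by the full slap amplitude in the foot-rate
coordinates.  At integration tolerance 1e-8 that amplification makes
the shooting residual effectively noisy, which Newton tolerates for
ankle-only gaits but not for hip-actuated ones.  Hip-actuated gaits
are therefore solved at the *pre-heel-strike* section
(`find_periodic_gait_hs`), where every coordinate is smooth because
the slap and the swing-foot relaxation happen strictly inside the map:
the section state is the toe-pinned chain with the leading heel at
ground level (7 free coordinates plus the pulse torque), integration
runs at 1e-11 and the finite-difference step is 1e-5.  The solved
fixed point is mapped back to the standard post-toe-off section for
verification, stability and energetics.

### The two solution branches

At fixed `(k_a, v)` the square system has multiple isolated solutions.
Physically relevant is the branch where the spring stores energy
through late stance and heel-off occurs late (shortly before heel
strike), releasing a push-off burst; it exists for soft ankle springs
(`k_a` roughly 0.3–1.1 in dimensionless units, which corresponds to
the physiological range when scaled by `m g l`).  A second branch with
early heel-off and a long toe-constrained vault exists at stiffer
springs but wastes an order of magnitude more actuator work (the
undamped foot oscillates against the spring during the toe phase, and
large pulse torques leave the swing foot flapping after toe-off); the
grid search discards it on cost.  The default `k_a` grid spans 0–15
with 20 points and is refinable; the sweep drivers use a refined grid
over the soft range plus sparse stiff points, which the methods above
make cheap to verify.

## Numerical choices

- RK45 with `rtol = atol = 1e-6` for reported simulations (1e-8 for
  shooting, 1e-10 for verification and Floquet differencing).
- Quadrature refinement: 1200 samples/segment for sweep tables, 4000
  for audits in the tests; the sign-split trapezoid rule converges to
  ~1e-6 at these sizes (asserted against a refined grid).
- Event ties broken in canonical contact order at 1e-9.
- Degenerate inputs: zero segment inertias are accepted (point-mass
  limit); near-massless segments make the KKT system ill-conditioned
  and are accepted but not recommended below ~1e-6.

## Known divergences from the reference results

Two quantitative reference results for this walker do not reproduce
under the canonical parameter set, and both trace to the same
mechanism.
At toe-off the pulse torque leaves the trailing ankle deflected by
about `T_a / k_a`; the swing-foot spring then relaxes the foot against
the ankle damper, releasing `~T_a^2 / (2 k_a)` of actuator work into
the damper every step.  Because the ankle torque is geometrically
capped by the foot length (the center of pressure cannot pass the
toe), fast gaits cannot substitute spring storage for the pulse, so
this loss is unavoidable: it reaches 0.03–0.04 per step at speeds
above 0.4, i.e. roughly 30% of the collision loss — whereas the
reference value for swing-phase damper losses is below 2% of collision
loss.  Charged at the 4x metabolic price of positive work, it raises
our optimal MCOT at speed 0.47 to 0.59 versus the reference value of
0.41; subtracting the relaxation term analytically reproduces the
reference MCOT-speed curve to within a few percent.  Relatedly, our stable
ankle-only gaits end at speed 0.48 (all candidates above have Floquet
multipliers well outside the unit circle), while the reference range
extends to 0.54.  The segment inertias, which are not part of the
canonical parameter set, are the most plausible source of both gaps; the defaults here are slender-rod
values, and sensitivity runs with other plausible inertias move MCOT
by ~10% without closing either gap.  All directional results —
monotone MCOT and step length in speed, flexion raising collision loss
and cost, retraction lowering both at medium speeds through a smaller
vertical impact velocity, the free symmetric hip spring lowering MCOT
monotonically — reproduce with stable gaits.

## What the gait searches do and do not show

The search explores the deterministic model's limit cycles; it is a
local method with continuation and a stiffness grid, not a global
optimality certificate.  Fixture gaits are regenerated by the same
pipeline (`make_fixtures`), so regression baselines are reproducible
from a clean tree.  Real human walking differs in known ways the model
deliberately omits: no knees or trunk, spring-like rather than
burst-like hip torques, an instantaneous pulse onset at ankle
reversal, and a purely work-based metabolic proxy without force-rate
or activation costs; conclusions about the model therefore transfer to
human gait only qualitatively.
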