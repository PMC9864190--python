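"""Periodic-gait search, Floquet stability, and MCOT optimization.

A periodic gait is a fixed point of the stride map: the post-toe-off
state maps to itself after one step and leg relabeling.  With the
walking speed imposed as an equality constraint, the unknowns (the eight
initial state components and the ankle pulse torque) are exactly matched
by the constraints (eight periodicity residuals plus the speed), so for
fixed spring stiffnesses the constrained MCOT minimization reduces to
solving that square nonlinear system; the ankle stiffness ``k_a`` is
swept on a grid and the stiffness with the lowest-MCOT stable gait wins.

Acceptance of a gait follows two conditions: the end state after five
chained steps must match the initial state within 1e-6, and the largest
Floquet multiplier (eigenvalue of the linearized stride map) must have
magnitude below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import chain_coefficients
from .energetics import EnergyBreakdown, stride_energetics
from .model import Phase, State
from .params import ActuationParams, EfficiencyParams, WalkerParams
from .simulate import (StrideError, StrideFailure, StrideResult, impact_map, simulate_stride)

__all__ = [
    "PeriodicGait",
    "OptimizationScenario",
    "OptimizationResult",
    "stride_map",
    "periodicity_residual",
    "find_periodic_gait",
    "find_periodic_gait_hs",
    "floquet_multipliers",
    "optimize_gait",
    "sweep_speeds",
    "sweep_hip_stiffness",
    "DEFAULT_KA_GRID",
]

#: tolerances: the solver integrates a bit tighter than the reported
#: 1e-6 simulation tolerance so the shooting residuals are smooth;
#: verification (5-step residual, Floquet) uses tighter still.
SOLVE_TOL = 1e-8
VERIFY_TOL = 1e-10
PERIODICITY_TOL = 1e-6
SPEED_TOL = 1e-4
FLOQUET_STEP = 1e-5

#: default ankle-stiffness grid for the outer grid search: ~20 points
#: over 0-15, dense in the soft range where efficient gaits live
DEFAULT_KA_GRID = tuple(np.round(np.arange(0.25, 1.01, 0.05), 3)) + (2.0, 5.0, 10.0, 15.0)


def stride_map(q8, params, act, tol=SOLVE_TOL, q0_template: State | None = None):
    """One application of the stride map; returns (end 8-vector, stride)."""
    s0 = State.from_q(q8, phase=Phase.HEEL)
    stride = simulate_stride(s0, params, act, rtol=tol, atol=tol).require_ok()
    return stride.end_state.q, stride


def periodicity_residual(q0, params, act, n_steps: int = 1, tol=SOLVE_TOL):
    """End-state-minus-initial-state after ``n_steps`` relabeled strides."""
    q = np.asarray(q0, dtype=float).reshape(8)
    for _ in range(n_steps):
        q, _ = stride_map(q, params, act, tol=tol)
    return q - np.asarray(q0, dtype=float)


@dataclass
class PeriodicGait:
    """A verified periodic gait: fixed point, stability and energetics."""

    q0: np.ndarray
    params: WalkerParams
    act: ActuationParams
    stride: StrideResult
    energy: EnergyBreakdown
    floquet: np.ndarray = field(default_factory=lambda: np.array([]))
    residual5: float = math.nan

    @property
    def stable(self) -> bool:
        return bool(len(self.floquet)) and float(np.max(self.floquet)) < 1.0

    @property
    def max_floquet(self) -> float:
        return float(np.max(self.floquet)) if len(self.floquet) else math.nan

    @property
    def speed(self) -> float:
        return self.stride.speed

    @property
    def mcot(self) -> float:
        return self.energy.mcot

    def heel_strike_impact(self):
        for im in self.stride.impacts:
            if im.label == "heel_strike":
                return im
        return None


def _newton_solve(resfun, x0, tol=1e-9, maxiter=40, fd=1e-6):
    """Damped Newton with finite-difference Jacobian and backtracking.

    ``resfun`` returns the residual vector or ``None`` where the stride
    is infeasible; infeasible trial points shrink the step.  Suited to
    shooting problems whose residual is undefined off the walking basin.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = resfun(x)
    if r is None:
        return None, None
    for _ in range(maxiter):
        nr = np.linalg.norm(r, np.inf)
        if nr < tol:
            return x, r
        n = len(x)
        J = np.zeros((len(r), n))
        for j in range(n):
            dx = np.zeros(n)
            dx[j] = fd * max(1.0, abs(x[j]))
            rp = resfun(x + dx)
            if rp is None:
                rp = resfun(x - dx)
                if rp is None:
                    return None, None
                J[:, j] = (r - rp) / dx[j]
            else:
                J[:, j] = (rp - r) / dx[j]
        try:
            d = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            return None, None
        accepted = False
        for a in (1.0, 0.5, 0.25, 0.1, 0.03):
            rn = resfun(x + a * d)
            if rn is not None and np.linalg.norm(rn, np.inf) < nr * (1 - 0.1 * a):
                x, r = x + a * d, rn
                accepted = True
                break
        if not accepted:
            rn = resfun(x + 0.03 * d)
            if rn is None:
                return None, None
            x, r = x + 0.03 * d, rn
    if np.linalg.norm(r, np.inf) < 1e-6:
        return x, r
    return None, None


def _relaxation_solve(
    params, act, q0, v_target, tol=SOLVE_TOL, max_strides=80, outer=14,
):
    """Stable-gait solver: iterate the stride map to its attractor and
    meet the speed constraint by a secant iteration on the pulse torque.

    The stride map contracts the fast foot modes in one step, so plain
    fixed-point iteration is robust where Newton's line search struggles;
    it only converges to stable gaits, which are the ones reported.
    Returns ``(q0, act)`` or ``None``.
    """
    # Stage 1: per-stride pulse-torque feedback keeps the walker alive
    # and drives the average speed to the target through the transient.
    Ta = act.T_a
    q = np.asarray(q0, float).copy()
    gain = 0.5
    settled = 0
    for i in range(max_strides):
        try:
            q1, st = stride_map(q, params, replace(act, T_a=max(Ta, 0.0)), tol=tol)
        except StrideError:
            return None
        d = np.linalg.norm(q1 - q, np.inf)
        q = q1
        err = v_target - st.speed
        Ta = float(np.clip(Ta + gain * err, 0.0, 2.0))
        if abs(err) < 2e-3 and d < 1e-3:
            settled += 1
            if settled >= 3:
                break
        else:
            settled = 0
    else:
        return None

    # Stage 2: frozen-torque relaxation + secant on the pulse torque.
    hist = []
    for _ in range(outer):
        a = replace(act, T_a=max(Ta, 0.0))
        speed = None
        for i in range(max_strides):
            try:
                q1, st = stride_map(q, params, a, tol=tol)
            except StrideError:
                return None
            d = np.linalg.norm(q1 - q, np.inf)
            q = q1
            if d < 5e-7:
                speed = st.speed
                break
        if speed is None:
            return None
        hist.append((Ta, speed))
        if abs(speed - v_target) < 5e-5:
            return q, a
        if len(hist) >= 2 and abs(hist[-1][0] - hist[-2][0]) > 1e-12:
            (t0, v0), (t1, v1) = hist[-2], hist[-1]
            if abs(v1 - v0) < 1e-12:
                return None
            Ta = t1 + (v_target - v1) * (t1 - t0) / (v1 - v0)
        else:
            Ta = Ta * (1.0 + 2.0 * (v_target - speed))
        Ta = float(np.clip(Ta, 0.0, 2.0))
    return None


def find_periodic_gait(
    params: WalkerParams,
    act: ActuationParams,
    q0_guess,
    v_target: float | None = None,
    solve_pulse: bool = False,
    tol: float = SOLVE_TOL,
    eff: EfficiencyParams | None = None,
    free_hip_cost: bool = False,
    verify: bool = True,
    max_nfev: int = 300,
) -> PeriodicGait | None:
    """Solve for a periodic gait by single-stride shooting.

    Unknowns are the eight post-toe-off state components, plus the ankle
    pulse torque ``T_a`` when both ``solve_pulse`` and a ``v_target``
    are given (the speed equality constraint closes the square system).
    Returns ``None`` when the shooting iteration does not converge or
    the stride fails everywhere near the guess.
    """
    q0_guess = np.asarray(q0_guess, dtype=float).reshape(8)
    with_pulse = solve_pulse and v_target is not None
    x0 = np.concatenate([q0_guess, [act.T_a]]) if with_pulse else q0_guess.copy()

    def unpack(x):
        if with_pulse:
            return x[:8], replace(act, T_a=max(float(x[8]), 0.0))
        return x, act

    def residual(x):
        q0, a = unpack(x)
        try:
            q1, stride = stride_map(q0, params, a, tol=tol)
        except StrideError:
            return None
        r = q1 - q0
        if v_target is not None:
            r = np.append(r, 10.0 * (stride.speed - v_target))
        return r

    x, r = _newton_solve(residual, x0, maxiter=max_nfev // 10)
    if x is None and with_pulse:
        relax = _relaxation_solve(params, act, q0_guess, v_target, tol=tol)
        if relax is not None:
            q_rel, a_rel = relax
            x_rel = np.concatenate([q_rel, [a_rel.T_a]])
            x, r = _newton_solve(residual, x_rel, maxiter=8)
            if x is None:
                rr = residual(x_rel)
                if rr is not None and np.linalg.norm(rr, np.inf) < 5e-6:
                    x = x_rel
    if x is None:
        return None
    q0, a = unpack(x)
    try:
        _, stride = stride_map(q0, params, a, tol=tol)
    except StrideError:
        return None
    energy = stride_energetics(stride, params, a, eff=eff, free_hip_cost=free_hip_cost)
    gait = PeriodicGait(q0=q0, params=params, act=a, stride=stride, energy=energy)
    if verify:
        try:
            r5 = periodicity_residual(q0, params, a, n_steps=5, tol=VERIFY_TOL)
        except StrideError:
            return None
        gait.residual5 = float(np.linalg.norm(r5, np.inf))
        gait.floquet = floquet_multipliers(q0, params, a)
    return gait


# ---------------------------------------------------------------------------
# Heel-strike-section shooting
#
# The post-toe-off section samples the leading foot mid-slap, so the
# stride map is violently sensitive in the foot coordinates there.  At
# the pre-heel-strike section every coordinate is smooth (the slap and
# the swing-foot relaxation happen strictly inside the map), which makes
# shooting for hip-actuated gaits tractable.  Section coordinates:
# x = [phi1, phi2, phi4, dphi1..dphi4, T_a]; phi3 follows from the
# section condition (leading heel at ground level, toe-pinned chain).


def _section_state(x, params) -> State:
    lf, l = params.l_f, params.l
    phi1, phi2, phi4 = x[0], x[1], x[2]
    s3 = -(lf * math.sin(phi1) + l * math.sin(phi2)) / l
    if abs(s3) > 1.0:
        raise ArithmeticError("no section state: leading heel cannot reach ground")
    phi3 = math.asin(s3)  # swing leg ahead, pointing down
    return State(
        phi=np.array([phi1, phi2, phi3, phi4]),
        phidot=np.array(x[3:7]),
        phase=Phase.TOE,
        pulse_active=True,
        hip_crossed=True,  # the leading leg is ahead at heel strike
    )


def _state_to_section(state: State, T_a: float) -> np.ndarray:
    return np.concatenate(
        [state.phi[[0, 1, 3]], state.phidot, [T_a]]
    )


def _heelstrike_map(x, params, act, tol=SOLVE_TOL):
    """One cycle of the pre-heel-strike section map.

    Returns ``(x_next, speed, stride)`` where ``stride`` is the
    toe-off-to-heel-strike portion carrying the step length.
    """
    a = replace(act, T_a=max(float(x[7]), 0.0))
    s_pre = _section_state(x, params)
    im = impact_map(s_pre, Phase.DOUBLE, params, label="heel_strike")
    s_db = im.state_post
    s_db.pulse_active = True
    s_db.hip_crossed = s_pre.hip_crossed
    r1 = simulate_stride(
        s_db, params, a, rtol=tol, atol=tol, start_phase=Phase.DOUBLE
    ).require_ok()
    r2 = simulate_stride(
        r1.end_state, params, a, rtol=tol, atol=tol, stop_at_heel_strike=True
    ).require_ok()
    if not r2.four_phase:
        raise StrideError(StrideFailure.EVENT_ORDER, r2.period)
    period = r1.period + r2.period
    speed = r2.step_length / period
    x_next = _state_to_section(r2.end_state, a.T_a)
    return x_next, speed, r2


def find_periodic_gait_hs(
    params: WalkerParams,
    act: ActuationParams,
    q0_guess,
    v_target: float,
    tol: float = 1e-11,
    fd: float = 1e-5,
    eff: EfficiencyParams | None = None,
    free_hip_cost: bool = False,
    verify: bool = True,
    max_nfev: int = 300,
) -> PeriodicGait | None:
    """Shooting at the pre-heel-strike section (four-phase gaits).

    ``q0_guess`` is a post-toe-off state of a nearby gait; it is first
    carried to the section, the square system (7 section residuals plus
    the speed) is solved for the section state and pulse torque, and the
    solution is mapped back to the standard post-toe-off fixed point.
    """
    q0_guess = np.asarray(q0_guess, float).reshape(8)
    try:
        s0 = State.from_q(q0_guess, phase=Phase.HEEL)
        r0 = simulate_stride(
            s0, params, act, rtol=tol, atol=tol, stop_at_heel_strike=True
        ).require_ok()
    except StrideError:
        return None
    if not r0.four_phase:
        return None
    x0 = _state_to_section(r0.end_state, act.T_a)

    def residual(x):
        try:
            x1, speed, _ = _heelstrike_map(x, params, act, tol=tol)
        except (StrideError, ArithmeticError):
            return None
        r = x1[:7] - x[:7]
        return np.append(r, 10.0 * (speed - v_target))

    x, r = _newton_solve(residual, x0, maxiter=max_nfev // 10, fd=fd)
    if x is None:
        return None
    a = replace(act, T_a=max(float(x[7]), 0.0))
    # map the section fixed point back to the post-toe-off section
    try:
        s_pre = _section_state(x, params)
        im = impact_map(s_pre, Phase.DOUBLE, params, label="heel_strike")
        s_db = im.state_post
        s_db.pulse_active = True
        r1 = simulate_stride(
            s_db, params, a, rtol=tol, atol=tol, start_phase=Phase.DOUBLE
        ).require_ok()
        q0 = r1.end_state.q
        _, stride = stride_map(q0, params, a, tol=tol)
    except StrideError:
        return None
    energy = stride_energetics(stride, params, a, eff=eff, free_hip_cost=free_hip_cost)
    gait = PeriodicGait(q0=q0, params=params, act=a, stride=stride, energy=energy)
    if verify:
        try:
            r5 = periodicity_residual(q0, params, a, n_steps=5, tol=VERIFY_TOL)
        except StrideError:
            return None
        gait.residual5 = float(np.linalg.norm(r5, np.inf))
        gait.floquet = floquet_multipliers(q0, params, a)
    return gait


def floquet_multipliers(
    q0, params: WalkerParams = None, act: ActuationParams = None,
    perturbation: float = FLOQUET_STEP, tol: float = VERIFY_TOL,
    map_func=None,
) -> np.ndarray:
    """Sorted eigenvalue magnitudes of the linearized stride map.

    The Jacobian of the stride map at the post-toe-off section is formed
    by central finite differences of size ``perturbation``.  An
    alternative ``map_func(q) -> q'`` replaces the stride map (e.g. for
    synthetic maps in tests).
    """
    q0 = np.asarray(q0, dtype=float).reshape(-1)
    if map_func is None:
        map_func = lambda q: stride_map(q, params, act, tol=tol)[0]
    n = len(q0)
    J = np.zeros((n, n))
    for j in range(n):
        dp = np.zeros(n)
        dp[j] = perturbation
        J[:, j] = (map_func(q0 + dp) - map_func(q0 - dp)) / (2 * perturbation)
    if not np.all(np.isfinite(J)):
        raise ArithmeticError("non-finite stride-map Jacobian")
    mags = np.abs(np.linalg.eigvals(J))
    return np.sort(mags)[::-1]


# ---------------------------------------------------------------------------
# Scenarios, optimization and sweeps


@dataclass
class OptimizationScenario:
    """Configuration of one constrained MCOT optimization.

    ``mode`` selects the actuation strategy: ``ankle_only`` (hip springs
    zero), ``flexion_only`` (retraction zero), or
    ``flexion_plus_retraction``.  ``free_hip_cost`` reproduces the
    symmetric-hip-spring variant where hip work is excluded from MCOT.
    """

    mode: str = "ankle_only"
    v: float = 0.40
    k_a_grid: tuple = DEFAULT_KA_GRID
    k_hf: float = 0.0
    k_hr: float = 0.0
    free_hip_cost: bool = False
    eff: EfficiencyParams = field(default_factory=EfficiencyParams)

    def __post_init__(self):
        if self.mode not in ("ankle_only", "flexion_only", "flexion_plus_retraction"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if len(self.k_a_grid) == 0:
            raise ValueError("k_a grid must be non-empty")
        if self.mode == "ankle_only":
            self.k_hf = 0.0
            self.k_hr = 0.0
        elif self.mode == "flexion_only":
            self.k_hr = 0.0


@dataclass
class OptimizationResult:
    """Outcome of a grid-search optimization at one speed."""

    scenario: OptimizationScenario
    best: PeriodicGait | None
    records: pd.DataFrame
    feasible: bool

    @property
    def mcot(self) -> float:
        return self.best.mcot if self.best is not None else math.nan


def _gait_record(v, k_a, act, gait: PeriodicGait | None) -> dict:
    rec = {
        "v": v, "k_a": k_a, "T_a": act.T_a, "k_hf": act.k_hf, "k_hr": act.k_hr,
        "feasible": gait is not None,
    }
    if gait is None:
        return rec
    e = gait.energy
    im = gait.heel_strike_impact()
    rec.update(
        T_a=gait.act.T_a,
        s=e.step_length, period=e.period, speed=gait.speed, mcot=e.mcot,
        w_plus_ankle=e.w_plus_ankle, w_minus_ankle=e.w_minus_ankle,
        w_plus_hip=e.w_plus_hip, w_minus_hip=e.w_minus_hip,
        w_damper=e.w_damper, collision_loss=e.collision_loss,
        metabolic_work=e.metabolic_work,
        v_impact_x=im.contact_v_pre[0] if im else math.nan,
        v_impact_y=im.contact_v_pre[1] if im else math.nan,
        S_x=im.contact_impulse[0] if im else math.nan,
        S_y=im.contact_impulse[1] if im else math.nan,
        w_impulsive_hs=im.work if im else math.nan,
        max_floquet=gait.max_floquet, stable=gait.stable,
        residual5=gait.residual5, four_phase=gait.stride.four_phase,
    )
    return rec


def optimize_gait(
    scenario: OptimizationScenario,
    params: WalkerParams | None = None,
    q0_guess=None,
    T_a_guess: float | None = None,
    verbose: bool = False,
) -> OptimizationResult:
    """Grid search over ankle stiffness with per-point constraint solving.

    For each ``k_a`` the square system (periodicity + speed) is solved
    for ``(q0, T_a)`` by shooting, warm-starting from the previous grid
    point; gaits failing the five-step or stability checks are recorded
    but excluded from ``best``.  An empty feasible set is reported as an
    infeasibility result, not an exception.
    """
    from .fixtures import seed_guess_full

    params = params or WalkerParams()
    seed_ka = None
    if q0_guess is None:
        q0_guess, seed_ka, T_a_default = seed_guess_full(scenario.v)
        if T_a_guess is None:
            T_a_guess = T_a_default
    if T_a_guess is None:
        T_a_guess = 0.05

    # visit the grid outward from the seed stiffness so every solve
    # warm-starts from its nearest solved neighbor (continuation)
    grid = list(scenario.k_a_grid)
    if seed_ka is None:
        seed_ka = grid[len(grid) // 2]
    order = sorted(range(len(grid)), key=lambda i: abs(grid[i] - seed_ka))

    records = {}
    solved: dict[float, tuple] = {}
    best = None
    for i in order:
        k_a = float(grid[i])
        if solved:
            k_near = min(solved, key=lambda k: abs(k - k_a))
            q_warm, T_warm = solved[k_near]
        else:
            q_warm, T_warm = np.asarray(q0_guess, float), float(T_a_guess)
        act = ActuationParams(k_a=k_a, T_a=T_warm,
                              k_hf=scenario.k_hf, k_hr=scenario.k_hr)
        gait = _solve_hip_gait(
            params, act, q_warm, scenario.v,
            eff=scenario.eff, free_hip_cost=scenario.free_hip_cost,
        )
        if gait is not None and abs(gait.speed - scenario.v) > SPEED_TOL:
            gait = None
        if gait is not None and gait.residual5 > PERIODICITY_TOL:
            gait = None
        records[i] = _gait_record(scenario.v, k_a, act, gait)
        if verbose:
            r = records[i]
            print(f"  k_a={k_a:6.2f} feasible={r['feasible']}"
                  + (f" mcot={r['mcot']:.4f} stable={r['stable']}" if r["feasible"] else ""),
                  flush=True)
        if gait is not None:
            solved[k_a] = (gait.q0.copy(), gait.act.T_a)
            if gait.stable and (best is None or gait.mcot < best.mcot):
                best = gait
    df = pd.DataFrame.from_records([records[i] for i in sorted(records)])
    return OptimizationResult(scenario=scenario, best=best, records=df,
                              feasible=best is not None)


def sweep_speeds(
    scenario: OptimizationScenario,
    speeds,
    params: WalkerParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Optimal gait per speed; returns (tidy table, {speed: result}).

    Speeds are visited outward from the one closest to the seed gait so
    each optimization warm-starts from its neighbor (continuation);
    per-speed infeasibility is recorded and the sweep continues.
    """
    from .fixtures import seed_guess

    params = params or WalkerParams()
    speeds = list(speeds)
    if not speeds:
        return pd.DataFrame(), {}
    order = _continuation_order(speeds)
    results: dict[float, OptimizationResult] = {}
    guesses: dict[float, tuple] = {}
    rows = []
    for v, src in order:
        if src is None or src not in results or results[src].best is None:
            guess = seed_guess(v)
        else:
            b = results[src].best
            guess = (b.q0, b.act.T_a)
        sc = replace(scenario, v=v)
        res = optimize_gait(sc, params, q0_guess=guess[0], T_a_guess=guess[1])
        results[v] = res
        row = {"v": v, "feasible": res.feasible}
        if res.best is not None:
            row.update(_gait_record(v, res.best.act.k_a, res.best.act, res.best))
        rows.append(row)
    df = pd.DataFrame.from_records(sorted(rows, key=lambda r: r["v"]))
    return df, results


def _continuation_order(speeds):
    """Visit order starting mid-grid, expanding outward with warm starts."""
    speeds = sorted(speeds)
    mid = len(speeds) // 2
    order = [(speeds[mid], None)]
    lo, hi = mid - 1, mid + 1
    while lo >= 0 or hi < len(speeds):
        if hi < len(speeds):
            order.append((speeds[hi], speeds[hi - 1]))
            hi += 1
        if lo >= 0:
            order.append((speeds[lo], speeds[lo + 1]))
            lo -= 1
    return order


def _solve_hip_gait(
    params, act, q0_guess, v_target, eff=None, free_hip_cost=False,
    verify=True, max_bisect=4,
) -> PeriodicGait | None:
    """Hip-actuated gait via heel-strike-section shooting with
    bisection continuation in the hip stiffness from the warm start."""
    target_hf, target_hr = act.k_hf, act.k_hr
    if target_hf == 0.0 and target_hr == 0.0:
        return find_periodic_gait(
            params, act, q0_guess, v_target=v_target, solve_pulse=True,
            eff=eff, free_hip_cost=free_hip_cost, verify=verify,
        )

    def solve_at(frac, q, Ta, verify_now):
        a = replace(act, T_a=Ta, k_hf=frac * target_hf, k_hr=frac * target_hr)
        return find_periodic_gait_hs(
            params, a, q, v_target=v_target, eff=eff,
            free_hip_cost=free_hip_cost, verify=verify_now,
        )

    q, Ta = np.asarray(q0_guess, float), act.T_a
    frac = 0.0
    step = 1.0
    bisects = 0
    while frac < 1.0 - 1e-9:
        f_next = min(1.0, frac + step)
        g = solve_at(f_next, q, Ta, verify_now=(f_next >= 1.0) and verify)
        if g is None:
            bisects += 1
            if bisects > max_bisect:
                return None
            step /= 2
            continue
        frac = f_next
        q, Ta = g.q0.copy(), g.act.T_a
        if frac >= 1.0:
            return g
    return None


def sweep_hip_stiffness(
    v: float,
    which: str,
    grid,
    params: WalkerParams | None = None,
    k_a_grid=None,
    base_k_hf: float = 0.0,
    eff: EfficiencyParams | None = None,
) -> pd.DataFrame:
    """Best gait per hip-spring stiffness at a fixed speed.

    ``which`` is ``"flexion"`` (sweep ``k_hf``, retraction zero) or
    ``"retraction"`` (sweep ``k_hr`` at a given ``base_k_hf``), or
    ``"symmetric"`` (k_hf = k_hr swept together, hip work excluded from
    MCOT).  Each stiffness re-optimizes the ankle stiffness over
    ``k_a_grid`` (default: a small grid around the seed stiffness for
    the speed); hip-actuated gaits are solved by heel-strike-section
    shooting with continuation from the previous grid point.  Returns
    one row per grid point with the full energy breakdown and
    heel-strike impact quantities; infeasible points are recorded and
    the sweep continues.
    """
    if which not in ("flexion", "retraction", "symmetric"):
        raise ValueError(f"unknown sweep {which!r}")
    params = params or WalkerParams()
    eff = eff or EfficiencyParams()
    from .fixtures import seed_guess_full

    grid = list(grid)
    if not grid:
        return pd.DataFrame()
    if k_a_grid is None:
        _, ka_seed, _ = seed_guess_full(v)
        k_a_grid = tuple(np.round([ka_seed - 0.05, ka_seed, ka_seed + 0.05], 3))
    k_a_grid = tuple(float(k) for k in k_a_grid)

    # base ankle-only optimum provides the warm starts
    base = optimize_gait(
        OptimizationScenario(mode="ankle_only", v=v, k_a_grid=k_a_grid, eff=eff),
        params,
    )
    rows = []
    warm = {}  # k_a -> (q0, T_a) at the latest solved sweep point
    if base.best is not None:
        for k_a in k_a_grid:
            warm[k_a] = (base.best.q0.copy(), base.best.act.T_a)
    free = which == "symmetric"
    for k in grid:
        k = float(k)
        k_hf = k if which in ("flexion", "symmetric") else base_k_hf
        k_hr = k if which in ("retraction", "symmetric") else 0.0
        best = None
        for k_a in k_a_grid:
            if k_a not in warm:
                continue
            q, Ta = warm[k_a]
            act = ActuationParams(k_a=k_a, T_a=Ta, k_hf=k_hf, k_hr=k_hr)
            g = _solve_hip_gait(params, act, q, v, eff=eff, free_hip_cost=free)
            if g is None or abs(g.speed - v) > SPEED_TOL:
                continue
            if g.residual5 > PERIODICITY_TOL or not g.stable:
                continue
            warm[k_a] = (g.q0.copy(), g.act.T_a)
            if best is None or g.mcot < best.mcot:
                best = g
        rec = {"which": which, "k_sweep": k, "v": v, "feasible": best is not None}
        if best is not None:
            rec.update(_gait_record(v, best.act.k_a, best.act, best))
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
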