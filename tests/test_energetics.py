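import math
from types import SimpleNamespace

import numpy as np
import pytest

from flatwalker.energetics import (
    EnergyBreakdown,
    energy_audit,
    joint_work,
    mcot,
    stride_energetics,
)
from flatwalker.model import Phase
from flatwalker.params import ActuationParams, EfficiencyParams, WalkerParams


class TestMcot:
    def test_zero_work(self):
        assert mcot(0.0, 0.0, 1.0) == 0.0

    def test_default_efficiencies(self):
        # 4 * 0.1 + (-1/1.2) * (-0.1) = 0.4833...
        assert mcot(0.1, -0.1, 1.0) == pytest.approx(0.4 + 0.1 / 1.2)

    def test_negative_work_share(self):
        """With W- = -W+, the share of metabolic cost spent on negative
        work is |eta-| / (eta+ + |eta-|) ~ 17%."""
        eff = EfficiencyParams()
        w = 0.37
        total = mcot(w, -w, 1.0, eff)
        share = (-eff.eta_minus * w) / total
        assert share == pytest.approx(1 / 1.2 / (4 + 1 / 1.2), abs=1e-12)
        assert share == pytest.approx(0.172, abs=0.001)

    def test_invalid_step_length(self):
        with pytest.raises(ValueError):
            mcot(0.1, -0.1, 0.0)

    def test_monotonicity(self):
        base = mcot(0.2, -0.1, 1.0)
        assert mcot(0.3, -0.1, 1.0) > base
        assert mcot(0.2, -0.2, 1.0) > base
        assert mcot(0.2, -0.1, 1.2) < base


def linear_segment(phase, n1=0.0, slope=(0.0, 0.0, 0.0, 0.0), t1=1.0, pulse=False):
    """Fake phase segment with linear angle trajectories (zero rates in
    the torque-relevant joints unless given)."""
    base = np.array([math.pi, math.pi / 2, -math.pi / 2, 0.0])
    sl = np.asarray(slope)

    def sol(t):
        t = np.atleast_1d(t)
        phi = base[:, None] + sl[:, None] * t
        pd = np.broadcast_to(sl[:, None], (4, len(t)))
        return np.vstack([phi, pd])

    seg = SimpleNamespace(
        phase=phase, t0=0.0, t1=t1, anchor=np.zeros(2),
        pulse_active=pulse, hip_crossed=False,
        sample=lambda n: (np.linspace(0.0, t1, n), sol(np.linspace(0.0, t1, n))),
        sol=sol,
    )
    return seg


class TestJointWork:
    def test_constant_pulse_torque_closed_form(self):
        """Pure pulse torque 0.2 over a monotone ankle extension of 0.5
        does +0.1 of work and no negative work."""
        p = WalkerParams(c_a=0.0)
        act = ActuationParams(k_a=0.0, T_a=0.2)
        # stance ankle angle rate = slope1 - slope2 = -0.5 (extension)
        seg = linear_segment(Phase.FOOT, slope=(-0.5, 0.0, 0.0, -0.5), pulse=True)
        stride = SimpleNamespace(segments=[seg], impacts=[])
        w = joint_work(stride, p, act)
        assert w["w_plus_ankle"] == pytest.approx(0.1, abs=1e-12)
        assert w["w_minus_ankle"] == pytest.approx(0.0, abs=1e-12)
        assert w["w_plus_hip"] == w["w_minus_hip"] == 0.0

    def test_spring_work_cancels_over_closed_path(self):
        """A pure ankle spring over a closed angle excursion does equal
        and opposite positive/negative work."""
        p = WalkerParams(c_a=0.0)
        act = ActuationParams(k_a=2.0)
        base = np.array([math.pi, math.pi / 2, -math.pi / 2, 0.0])
        T = 2 * math.pi

        def sol(t):
            t = np.atleast_1d(t)
            phi = np.tile(base[:, None], (1, len(t)))
            pd = np.zeros((4, len(t)))
            phi[0] += 0.3 * np.sin(t)
            pd[0] = 0.3 * np.cos(t)
            return np.vstack([phi, pd])

        seg = SimpleNamespace(
            phase=Phase.FOOT, t0=0.0, t1=T, anchor=np.zeros(2),
            pulse_active=False, hip_crossed=False,
            sample=lambda n: (np.linspace(0.0, T, n), sol(np.linspace(0.0, T, n))),
            sol=sol,
        )
        stride = SimpleNamespace(segments=[seg], impacts=[])
        w = joint_work(stride, p, act, n=6000)
        assert w["w_plus_ankle"] == pytest.approx(-w["w_minus_ankle"], abs=1e-7)
        assert w["w_plus_ankle"] > 0.01

    def test_quadrature_matches_fine_grid(self, fixture_stride, params, periodic_gait):
        """Sign-split trapezoid work converges: the audit-grade sampling
        agrees with a doubled grid to 1e-6 (the default sweep sampling
        sits within ~2e-5 of the converged value)."""
        w1 = joint_work(fixture_stride, params, periodic_gait.act, n=8000)
        w2 = joint_work(fixture_stride, params, periodic_gait.act, n=16000)
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-6)
        w0 = joint_work(fixture_stride, params, periodic_gait.act, n=1200)
        for k in w0:
            assert w0[k] == pytest.approx(w2[k], abs=5e-5)


class TestAudit:
    def test_ballistic_interval(self, params):
        """Zero actuation, dampers off: dKE = gravity work."""
        from scipy.integrate import solve_ivp

        from flatwalker.dynamics import _eom_arrays, chain_coefficients
        from flatwalker.energetics import _kinetic, _potential

        p = WalkerParams(c_a=0.0)
        co = chain_coefficients(p)
        act = ActuationParams()
        y0 = np.array([math.pi + 0.2, math.pi / 2 + 0.3, -math.pi / 2 - 0.2, -0.1,
                       -0.3, -0.4, 0.5, 0.2])

        def rhs(t, y):
            qdd, _, _ = _eom_arrays(y[:4], y[4:], Phase.HEEL, False, False, p, act, co)
            return np.concatenate([y[4:], qdd[2:]])

        sol = solve_ivp(rhs, (0, 0.7), y0, rtol=1e-10, atol=1e-10)
        yT = sol.y[:, -1]
        anchor = np.zeros(2)
        dke = _kinetic(yT[:4], yT[4:], Phase.HEEL, co, p) - _kinetic(
            y0[:4], y0[4:], Phase.HEEL, co, p)
        wg = _potential(y0[:4], anchor, Phase.HEEL, co, p) - _potential(
            yT[:4], anchor, Phase.HEEL, co, p)
        assert dke == pytest.approx(wg, abs=1e-6)

    def test_stride_audit_closes(self, fixture_stride, params, periodic_gait):
        audit = energy_audit(fixture_stride, params, periodic_gait.act, n=4000)
        assert abs(audit["residual"]) < 1e-5

    def test_periodic_cycle_ke_closure(self, fixture_stride, params, periodic_gait):
        audit = energy_audit(fixture_stride, params, periodic_gait.act, n=4000)
        assert abs(audit["dKE"]) < 1e-5
        # work balance: positive work compensates all losses
        total = (audit["w_ankle"] + audit["w_hip"] + audit["w_damper"]
                 + audit["w_impulsive"] + audit["w_gravity"])
        assert total == pytest.approx(audit["dKE"], abs=1e-5)

    def test_audit_detects_corrupted_impulse(self, fixture_stride, params, periodic_gait):
        import copy

        bad = copy.copy(fixture_stride)
        bad.impacts = [copy.copy(im) for im in fixture_stride.impacts]
        im = max(bad.impacts, key=lambda im: abs(im.work))
        im.work = im.work * 1.01 + 1e-3  # corrupt by ~1%
        audit = energy_audit(bad, params, periodic_gait.act, n=4000)
        assert abs(audit["residual"]) > 1e-4


class TestStrideEnergetics:
    def test_breakdown_signs_and_mcot(self, fixture_stride, params, periodic_gait):
        e = stride_energetics(fixture_stride, params, periodic_gait.act, n=4000)
        assert e.w_plus_ankle >= 0 and e.w_plus_hip >= 0
        assert e.w_minus_ankle <= 0 and e.w_minus_hip <= 0
        assert e.w_damper <= 0
        assert e.w_impulsive <= 0
        assert e.mcot > 0
        eff = EfficiencyParams()
        assert e.mcot == pytest.approx(
            mcot(e.w_plus, e.w_minus, e.step_length, eff), abs=1e-12
        )

    def test_ankle_power_signature(self, fixture_stride, params, periodic_gait):
        """The stance ankle does negative work before reversal and a
        positive push-off burst afterwards."""
        from flatwalker.energetics import segment_powers, _signsplit_trapz

        pre_rev = post_rev = 0.0
        post_rev_minus = 0.0
        for seg in fixture_stride.segments:
            pw = segment_powers(seg, params, periodic_gait.act, 2000)
            plus, minus = _signsplit_trapz(pw["t"], pw["ankle_stance"])
            if seg.pulse_active:
                post_rev += plus
                post_rev_minus += minus
            else:
                pre_rev += minus
        assert pre_rev < 0  # net negative work while dorsiflexing
        assert post_rev > 0  # push-off burst
        assert post_rev > -post_rev_minus

    def test_free_hip_cost_excludes_hip_work(self, fixture_stride, params, periodic_gait):
        e1 = stride_energetics(fixture_stride, params, periodic_gait.act)
        e2 = stride_energetics(fixture_stride, params, periodic_gait.act,
                               free_hip_cost=True)
        eff = EfficiencyParams()
        expected = (eff.eta_plus * e1.w_plus_ankle + eff.eta_minus * e1.w_minus_ankle)
        assert e2.metabolic_work == pytest.approx(expected, abs=1e-12)
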