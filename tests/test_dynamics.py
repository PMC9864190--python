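import math

import numpy as np
import pytest

from flatwalker.dynamics import (
    ankle_damper_torque,
    ankle_torque,
    bias_forces,
    chain_coefficients,
    equations_of_motion,
    ground_reaction,
    hip_torque,
    joint_torques,
    mass_matrix,
)
from flatwalker.model import Phase, State, standing_state
from flatwalker.params import ActuationParams, WalkerParams


def random_state(rng, phase):
    phi = np.array([math.pi, math.pi / 2, -math.pi / 2, 0.0]) + rng.normal(0, 0.4, 4)
    return State(phi=phi, phidot=rng.normal(0, 0.6, 4), phase=phase)


class TestTorqueLaws:
    def test_rest_pose_zero(self):
        act = ActuationParams(k_a=1.0, T_a=0.0)
        assert ankle_torque(0.0, 0.0, act) == 0.0
        assert hip_torque(standing_state(), act) == 0.0

    def test_pulse_plus_spring(self):
        # dorsiflexion -0.1 with stiffness 1 cancels a pulse of 0.1
        act = ActuationParams(k_a=1.0, T_a=0.1)
        assert ankle_torque(-0.1, 0.0, act, pulse_active=True) == pytest.approx(0.0)
        assert ankle_torque(-0.1, 0.0, act, pulse_active=False) == pytest.approx(-0.1)

    def test_linear_damper(self):
        p = WalkerParams()
        assert ankle_damper_torque(0.5, p) == pytest.approx(-0.005)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            ActuationParams(k_a=-1.0)

    def test_hip_spring_is_restoring_and_switches(self):
        # flexion spring before the crossing (hip angle < 0), retraction
        # after; both restore the hip angle toward zero
        act = ActuationParams(k_hf=2.0, k_hr=1.0)
        s = standing_state()
        s.phi[2] = -math.pi / 2 - 0.3  # hip angle -0.3 (swing leg behind)
        assert hip_torque(s, act) == pytest.approx(+0.6)  # k_hf*|psi|, forward
        s.phi[2] = -math.pi / 2 + 0.3  # hip angle +0.3 (swing leg ahead)
        assert hip_torque(s, act) == pytest.approx(-0.3)  # k_hr*|psi|, braking

    def test_flexion_only_zero_after_crossing(self):
        act = ActuationParams(k_hf=0.0, k_hr=1.0)
        s = standing_state()
        s.phi[2] = -math.pi / 2 - 0.2  # before the crossing: no torque
        assert hip_torque(s, act) == 0.0
        s.phi[2] = -math.pi / 2 + 0.2  # after: retraction acts
        assert hip_torque(s, act) != 0.0

    def test_hip_torque_odd_and_linear_per_regime(self):
        sym = ActuationParams(k_hf=1.3, k_hr=1.3)
        asym = ActuationParams(k_hf=1.3, k_hr=0.4)
        for d in (0.1, 0.25, 0.5):
            sp = standing_state()
            sp.phi[2] += d
            sm = standing_state()
            sm.phi[2] -= d
            assert hip_torque(sp, sym) == pytest.approx(-hip_torque(sm, sym))
            assert hip_torque(sp, asym) == pytest.approx(-0.4 * d)
            assert hip_torque(sm, asym) == pytest.approx(1.3 * d)


class TestEquationsOfMotion:
    def test_matches_symbolic_lagrangian(self, params):
        """Closed-form M, h agree with an independent sympy derivation."""
        from flatwalker.symbolic import lambdified_chain_dynamics

        Mf, hf = lambdified_chain_dynamics()
        co = chain_coefficients(params)
        rng = np.random.default_rng(0)
        for _ in range(100):
            phi = rng.uniform(-3, 3, 4)
            pd = rng.uniform(-2, 2, 4)
            vb = rng.uniform(-1, 1, 2)
            assert np.allclose(mass_matrix(phi, co), Mf(phi, pd, params, vb), atol=1e-10)
            assert np.allclose(bias_forces(phi, pd, co), hf(phi, pd, params, vb), atol=1e-10)

    def test_compiled_path_matches_numpy_path(self, params):
        from flatwalker._fast import pack_params, rhs_fast, lam_fast
        from flatwalker.dynamics import _eom_arrays
        from flatwalker.simulate import _PHASE_CODE

        act = ActuationParams(k_a=3.0, T_a=0.2, k_hf=0.4, k_hr=0.7)
        co = chain_coefficients(params)
        P = pack_params(params, act, co)
        rng = np.random.default_rng(5)
        for phase in Phase:
            for pulse in (False, True):
                s = random_state(rng, phase)
                qdd, lam, _ = _eom_arrays(
                    s.phi, s.phidot, phase, pulse, True, params, act, co)
                y = np.concatenate([s.phi, s.phidot])
                yd = rhs_fast(y, _PHASE_CODE[phase], pulse, True, P)
                lm = lam_fast(y, _PHASE_CODE[phase], pulse, True, P)
                assert np.allclose(yd[4:], qdd[2:], atol=1e-12)
                assert np.allclose(lm[: len(lam)], lam, atol=1e-12)

    def test_constraints_satisfied(self, params):
        """FOOT phase: flat-foot angle locked and heel point static."""
        act = ActuationParams(k_a=2.0)
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = random_state(rng, Phase.FOOT)
            s.phi[0] = math.pi
            s.phidot[0] = 0.0
            qdd, lam, _ = equations_of_motion(s, params, act)
            assert qdd[2] == pytest.approx(0.0, abs=1e-10)  # phiddot1
            # heel acceleration = base + foot-rotation terms = 0
            heel_acc = qdd[:2] + params.l_f * (
                qdd[2] * np.array([-math.sin(s.phi[0]), math.cos(s.phi[0])])
                - s.phidot[0] ** 2 * np.array([math.cos(s.phi[0]), math.sin(s.phi[0])])
            )
            assert np.allclose(heel_acc, 0.0, atol=1e-10)

    def test_work_energy_rate(self, params):
        """d(KE)/dt equals gravity + joint + damper power along the field."""
        from flatwalker.dynamics import base_velocity, generalized_forces

        co = chain_coefficients(params)
        act = ActuationParams(k_a=1.5, T_a=0.1, k_hf=0.3, k_hr=0.2)
        rng = np.random.default_rng(8)
        for phase in (Phase.HEEL, Phase.TOE):
            for pulse in (False, True):
                s = random_state(rng, phase)
                s.pulse_active = pulse
                qdd, lam, torques = equations_of_motion(s, params, act, co)
                qd = np.concatenate([base_velocity(phase, s.phi, s.phidot, params), s.phidot])
                M = mass_matrix(s.phi, co)
                # dKE/dt = qd' M qdd + 1/2 qd' Mdot qd; use the EOM identity
                # M qdd + h = Q + J'lam  with  qd' (h - grav) = 1/2 qd' Mdot qd
                # so dKE/dt = qd' (Q + J'lam) - qd' grav_part; contact does
                # no work (J qd = 0), leaving actuator + gravity power.
                from flatwalker.dynamics import kinetic_energy
                from flatwalker.energetics import _potential

                eps = 1e-6

                def ke_pe(sgn):
                    st = s.copy()
                    st.phi = s.phi + sgn * eps * s.phidot
                    st.phidot = s.phidot + sgn * eps * qdd[2:]
                    return (
                        kinetic_energy(st, params),
                        _potential(st.phi, np.zeros(2), phase, co, params),
                    )

                (ke_p, pe_p), (ke_m, pe_m) = ke_pe(+1), ke_pe(-1)
                dke = (ke_p - ke_m) / (2 * eps)
                Q = generalized_forces(torques)
                p_act = float(Q @ qd)
                p_grav = -(pe_p - pe_m) / (2 * eps)
                assert dke == pytest.approx(p_act + p_grav, abs=5e-5)

    def test_inverted_pendulum_limit(self):
        """TOE phase with vanishing feet/swing masses reduces to the
        closed-form point-mass pendulum about the toe."""
        eps = 1e-6  # small but well-conditioned point-mass limit
        m_l = eps
        m_f = eps
        p = WalkerParams(
            m_h=1.0 - 2 * m_l - 2 * m_f, m_l=m_l, m_f=m_f,
            l_f=1e-8, d_f=0.5e-8, j_l=1e-9, j_f=1e-11, c_a=0.0,
        )
        act = ActuationParams()
        s = State(
            phi=[math.pi, math.pi / 2 - 0.3, -math.pi / 2, 0.0],
            phidot=[0.0, 0.25, 0.0, 0.0],
            phase=Phase.TOE,
        )
        qdd, _, _ = equations_of_motion(s, p, act)
        # hip at distance l from the pinned toe: phiddot = -(g/l) cos(phi)
        expected = -(p.g / p.l) * math.cos(s.phi[1])
        assert qdd[3] == pytest.approx(expected, abs=1e-5)


class TestGroundReaction:
    def test_standing_weight_support(self, params):
        """Total vertical contact force carries the weight (the dangling
        swing foot contributes a sub-percent transient)."""
        act = ActuationParams()
        s = standing_state(Phase.FOOT)
        qdd, lam, _ = equations_of_motion(s, params, act)
        gr = ground_reaction(s, lam, params)
        assert gr.force_trailing[1] == pytest.approx(params.m_tot * params.g, abs=0.01)
        assert gr.force_trailing[0] == pytest.approx(0.0, abs=1e-10)

    def test_newtons_second_law(self, params):
        """Sum of contact forces = m a_com + weight, via finite-difference
        CoM acceleration along a short integration."""
        from scipy.integrate import solve_ivp

        from flatwalker.dynamics import _eom_arrays
        from flatwalker.model import forward_kinematics

        co = chain_coefficients(params)
        act = ActuationParams(k_a=1.0, T_a=0.05)
        rng = np.random.default_rng(21)
        for phase in (Phase.HEEL, Phase.TOE, Phase.FOOT):
            s = random_state(rng, phase)
            if phase is Phase.FOOT:
                s.phi[0], s.phidot[0] = math.pi, 0.0

            def rhs(t, y):
                qdd, _, _ = _eom_arrays(y[:4], y[4:], phase, False, False, params, act, co)
                return np.concatenate([y[4:], qdd[2:]])

            h = 1e-5
            sol = solve_ivp(rhs, (0, h), np.concatenate([s.phi, s.phidot]),
                            rtol=1e-12, atol=1e-12, dense_output=True)
            solb = solve_ivp(rhs, (0, -h), np.concatenate([s.phi, s.phidot]),
                             rtol=1e-12, atol=1e-12, dense_output=True)

            def vcom(solution, t):
                y = solution.sol(t)
                st = State.from_q(y, phase=phase)
                return forward_kinematics(st, params).v_com

            a_com = (vcom(sol, h) - vcom(solb, -h)) / (2 * h)
            _, lam, _ = _eom_arrays(s.phi, s.phidot, phase, False, False, params, act, co)
            gr = ground_reaction(s, lam, params)
            total = gr.force_trailing.copy()
            if gr.force_leading is not None:
                total += gr.force_leading
            expected = params.m_tot * (a_com + np.array([0.0, params.g]))
            assert np.allclose(total, expected, atol=1e-4)

    def test_cop_from_angular_momentum_balance(self, params):
        """FOOT phase: the rate of angular momentum about the CoP equals
        the gravity moment (the contact force passes through the CoP)."""
        from scipy.integrate import solve_ivp

        from flatwalker.dynamics import _eom_arrays
        from flatwalker.model import forward_kinematics

        co = chain_coefficients(params)
        act = ActuationParams(k_a=1.0)
        rng = np.random.default_rng(31)
        for _ in range(5):
            s = random_state(rng, Phase.FOOT)
            s.phi[0], s.phidot[0] = math.pi, 0.0
            _, lam, _ = _eom_arrays(s.phi, s.phidot, Phase.FOOT, False, False, params, act, co)
            gr = ground_reaction(s, lam, params, anchor=(0.0, 0.0))
            cop = np.array([gr.cop_x, 0.0])

            def angmom(y):
                st = State.from_q(y, phase=Phase.FOOT)
                k = forward_kinematics(st, params)
                L = 0.0
                pts = [
                    (params.m_f, k.com_foot_st, None),
                    (params.m_l, k.com_leg_st, None),
                    (params.m_h, k.hip, None),
                    (params.m_l, k.com_leg_sw, None),
                    (params.m_f, k.com_foot_sw, None),
                ]
                vels = [
                    k.v_toe + (params.l_f - params.d_f) * st.phidot[0]
                    * np.array([-math.sin(st.phi[0]), math.cos(st.phi[0])]),
                    k.v_heel + params.d_l * st.phidot[1]
                    * np.array([-math.sin(st.phi[1]), math.cos(st.phi[1])]),
                    k.v_hip,
                    k.v_hip + (params.l - params.d_l) * st.phidot[2]
                    * np.array([-math.sin(st.phi[2]), math.cos(st.phi[2])]),
                    k.v_ankle_swing + (params.l_f - params.d_f) * st.phidot[3]
                    * np.array([-math.sin(st.phi[3]), math.cos(st.phi[3])]),
                ]
                js = [params.j_f, params.j_l, 0.0, params.j_l, params.j_f]
                oms = [st.phidot[0], st.phidot[1], 0.0, st.phidot[2], st.phidot[3]]
                for (m, pos, _), v, j, om in zip(pts, vels, js, oms):
                    r = pos - cop
                    L += m * (r[0] * v[1] - r[1] * v[0]) + j * om
                # gravity moment about cop
                tau_g = sum(
                    -m * params.g * (pos - cop)[0] for (m, pos, _) in pts
                )
                return L, tau_g

            def rhs(t, y):
                qdd, _, _ = _eom_arrays(y[:4], y[4:], Phase.FOOT, False, False, params, act, co)
                return np.concatenate([y[4:], qdd[2:]])

            y0 = np.concatenate([s.phi, s.phidot])
            h = 1e-6
            sol = solve_ivp(rhs, (0, h), y0, rtol=1e-12, atol=1e-12)
            solb = solve_ivp(rhs, (0, -h), y0, rtol=1e-12, atol=1e-12)
            _, tau0 = angmom(y0)
            L1, _ = angmom(sol.y[:, -1])
            Lm, _ = angmom(solb.y[:, -1])
            dLdt = (L1 - Lm) / (2 * h)
            assert dLdt == pytest.approx(tau0, abs=5e-5)
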