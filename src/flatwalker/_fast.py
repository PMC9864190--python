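"""Compiled (numba) fast path for the phase dynamics.

Numerically identical to the numpy implementation in
:mod:`flatwalker.dynamics` (same closed-form mass matrix, bias vector,
torque laws and KKT solve), specialized for the integrator's inner loop.
The test suite cross-checks the two paths; the simulator falls back to
the numpy path when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


#: phase codes (keep in sync with model.Phase)
HEEL, FOOT, TOE, DOUBLE, FOOT_DOUBLE = 0, 1, 2, 3, 4

_PHASE_ROWS = {HEEL: 2, FOOT: 3, TOE: 2, DOUBLE: 4, FOOT_DOUBLE: 5}


def pack_params(p, act, co) -> np.ndarray:
    """Flatten WalkerParams + ActuationParams + ChainCoefficients."""
    P = np.empty(33)
    P[0] = p.m_tot
    P[1] = p.g
    P[2] = p.l
    P[3] = p.l_f
    P[4] = p.c_a
    P[5] = act.k_a
    P[6] = act.T_a
    P[7] = act.k_hf
    P[8] = act.k_hr
    P[9:13] = co.b
    P[13:29] = co.c.ravel()
    P[29:33] = co.d
    return P


@njit(cache=True)
def _dyn_core(y, phase, pulse, crossed, P):
    """(ydot(8), lam(5)) for one evaluation of the phase dynamics."""
    m_tot = P[0]
    g = P[1]
    l = P[2]
    lf = P[3]
    c_a = P[4]
    k_a = P[5]
    T_a = P[6]
    k_hf = P[7]
    k_hr = P[8]
    b = P[9:13]
    c = P[13:29].reshape(4, 4)
    d = P[29:33]

    phi = y[:4]
    pd = y[4:]
    s = np.sin(phi)
    cph = np.cos(phi)

    # mass matrix
    M = np.zeros((6, 6))
    M[0, 0] = m_tot
    M[1, 1] = m_tot
    for k in range(4):
        M[0, 2 + k] = -b[k] * s[k]
        M[1, 2 + k] = b[k] * cph[k]
        M[2 + k, 0] = M[0, 2 + k]
        M[2 + k, 1] = M[1, 2 + k]
        for j in range(4):
            if j == k:
                M[2 + k, 2 + k] = d[k]
            else:
                M[2 + k, 2 + j] = c[k, j] * math.cos(phi[k] - phi[j])

    # bias forces
    h = np.zeros(6)
    for k in range(4):
        w2 = pd[k] * pd[k]
        h[0] -= b[k] * w2 * cph[k]
        h[1] -= b[k] * w2 * s[k]
        acc = 0.0
        for j in range(4):
            if j != k:
                acc += c[k, j] * math.sin(phi[k] - phi[j]) * pd[j] * pd[j]
        h[2 + k] = acc + g * b[k] * cph[k]
    h[1] += m_tot * g

    # joint torques -> generalized forces
    th_st = phi[0] - phi[1] - math.pi / 2
    th_sw = phi[3] - phi[2] - math.pi / 2
    psi = math.pi - phi[1] + phi[2]
    psi = (psi + math.pi) % (2 * math.pi) - math.pi
    tau1 = k_a * th_st
    if pulse:
        tau1 += T_a
    tau3 = k_a * th_sw
    kh = k_hr if psi > 0 else k_hf
    u = -kh * psi
    t1 = tau1
    if phase == HEEL:  # stance-toe airborne: damper on
        t1 += -c_a * (pd[1] - pd[0])
    t3 = tau3 + (-c_a * (pd[2] - pd[3]))
    Q = np.zeros(6)
    Q[2] = -t1
    Q[3] = t1 - u
    Q[4] = u + t3
    Q[5] = -t3

    # base velocity
    vbx = 0.0
    vby = 0.0
    if phase == HEEL or phase == FOOT or phase == FOOT_DOUBLE:
        vbx = lf * pd[0] * s[0]
        vby = -lf * pd[0] * cph[0]

    # constraint rows
    if phase == HEEL:
        m = 2
    elif phase == FOOT:
        m = 3
    elif phase == TOE:
        m = 2
    elif phase == DOUBLE:
        m = 4
    else:
        m = 5
    J = np.zeros((m, 6))
    Jd = np.zeros((m, 6))
    row = 0
    if phase == HEEL or phase == FOOT or phase == FOOT_DOUBLE:
        # heel pin
        J[row, 0] = 1.0
        J[row + 1, 1] = 1.0
        J[row, 2] = -lf * s[0]
        J[row + 1, 2] = lf * cph[0]
        Jd[row, 2] = -lf * cph[0] * pd[0]
        Jd[row + 1, 2] = -lf * s[0] * pd[0]
        row += 2
        if phase == FOOT or phase == FOOT_DOUBLE:
            J[row, 2] = 1.0
            row += 1
    else:
        # toe pin
        J[row, 0] = 1.0
        J[row + 1, 1] = 1.0
        row += 2
    if phase == DOUBLE or phase == FOOT_DOUBLE:
        # leading (swing) heel pin
        J[row, 0] = 1.0
        J[row + 1, 1] = 1.0
        J[row, 2] = -lf * s[0]
        J[row + 1, 2] = lf * cph[0]
        Jd[row, 2] = -lf * cph[0] * pd[0]
        Jd[row + 1, 2] = -lf * s[0] * pd[0]
        J[row, 3] = -l * s[1]
        J[row + 1, 3] = l * cph[1]
        Jd[row, 3] = -l * cph[1] * pd[1]
        Jd[row + 1, 3] = -l * s[1] * pd[1]
        J[row, 4] = -l * s[2]
        J[row + 1, 4] = l * cph[2]
        Jd[row, 4] = -l * cph[2] * pd[2]
        Jd[row + 1, 4] = -l * s[2] * pd[2]
        row += 2

    qd = np.empty(6)
    qd[0] = vbx
    qd[1] = vby
    qd[2:] = pd

    n = 6 + m
    KKT = np.zeros((n, n))
    rhs = np.empty(n)
    for i in range(6):
        for j in range(6):
            KKT[i, j] = M[i, j]
        rhs[i] = Q[i] - h[i]
    for i in range(m):
        for j in range(6):
            KKT[j, 6 + i] = -J[i, j]
            KKT[6 + i, j] = J[i, j]
        acc = 0.0
        for j in range(6):
            acc += Jd[i, j] * qd[j]
        rhs[6 + i] = -acc
    sol = np.linalg.solve(KKT, rhs)

    ydot = np.empty(8)
    ydot[:4] = pd
    ydot[4:] = sol[2:6]
    lam = np.zeros(5)
    lam[:m] = sol[6 : 6 + m]
    return ydot, lam


@njit(cache=True)
def rhs_fast(y, phase, pulse, crossed, P):
    ydot, _ = _dyn_core(y, phase, pulse, crossed, P)
    return ydot


@njit(cache=True)
def lam_fast(y, phase, pulse, crossed, P):
    _, lam = _dyn_core(y, phase, pulse, crossed, P)
    return lam
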