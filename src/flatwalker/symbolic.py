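"""Independent symbolic (Lagrangian) derivation of the chain dynamics.

Derives the floating-base mass matrix and bias vector of the walker with
sympy, straight from the kinetic/potential energy of the four-segment
chain, and lambdifies them.  This path shares no algebra with the
closed-form expressions in :mod:`flatwalker.dynamics`; the test suite
cross-checks the two on random states.
"""

from __future__ import annotations

import functools

import numpy as np
import sympy as sp

from .params import WalkerParams

__all__ = ["derive_chain_dynamics", "lambdified_chain_dynamics"]


@functools.lru_cache(maxsize=1)
def derive_chain_dynamics():
    """Symbolic (M, h, Q) with M*qddot + h = Q_applied.

    Returns sympy expressions in the coordinates [x, y, phi1..phi4] and
    the parameter symbols, via the Euler-Lagrange equations.
    """
    t = sp.symbols("t")
    x, y = sp.Function("x")(t), sp.Function("y")(t)
    phis = [sp.Function(f"phi{i}")(t) for i in range(1, 5)]
    m_h, m_l, m_f, l, d_l, l_f, d_f, j_l, j_f, g = sp.symbols(
        "m_h m_l m_f l d_l l_f d_f j_l j_f g", positive=True
    )
    m_tot = m_h + 2 * m_l + 2 * m_f

    def ev(a):
        return sp.Matrix([sp.cos(a), sp.sin(a)])

    toe = sp.Matrix([x, y])
    heel = toe + l_f * ev(phis[0])
    hip = heel + l * ev(phis[1])
    a2 = hip + l * ev(phis[2])
    c1 = toe + (l_f - d_f) * ev(phis[0])
    c2 = heel + d_l * ev(phis[1])
    c3 = hip + (l - d_l) * ev(phis[2])
    c4 = a2 + (l_f - d_f) * ev(phis[3])

    pts = [(m_f, c1), (m_l, c2), (m_h, hip), (m_l, c3), (m_f, c4)]
    T = sp.Rational(0)
    V = sp.Rational(0)
    for m, pt in pts:
        v = pt.diff(t)
        T += m * (v.T @ v)[0] / 2
        V += m * g * pt[1]
    for j, a in [(j_f, phis[0]), (j_l, phis[1]), (j_l, phis[2]), (j_f, phis[3])]:
        T += j * a.diff(t) ** 2 / 2

    coords = [x, y] + phis
    qd = [c.diff(t) for c in coords]
    qdd = [c.diff(t, 2) for c in coords]
    L = T - V
    eom = [sp.expand(L.diff(v).diff(t) - L.diff(c)) for c, v in zip(coords, qd)]

    M = sp.zeros(6, 6)
    h = sp.zeros(6, 1)
    for i, e in enumerate(eom):
        rest = e
        for j, a in enumerate(qdd):
            M[i, j] = sp.trigsimp(e.coeff(a))
            rest = rest - e.coeff(a) * a
        h[i] = sp.trigsimp(sp.expand(rest))

    params = (m_h, m_l, m_f, l, d_l, l_f, d_f, j_l, j_f, g)
    return M, h, coords, qd, params, m_tot


@functools.lru_cache(maxsize=1)
def lambdified_chain_dynamics():
    """Numeric (M, h) callables from the symbolic derivation.

    Both take ``(phi (4,), phidot (4,), params: WalkerParams)``; the base
    velocity does not enter M or h for this chain parameterization (M
    depends on angles only; base-velocity terms cancel in h).
    """
    M, h, coords, qd, psyms, _ = derive_chain_dynamics()
    phi_syms = sp.symbols("p1 p2 p3 p4")
    phid_syms = sp.symbols("w1 w2 w3 w4")
    base_d = sp.symbols("vx vy")
    sub = {}
    for c, s in zip(coords[2:], phi_syms):
        sub[c] = s
    for v, s in zip(qd[2:], phid_syms):
        sub[v] = s
    sub[qd[0]] = base_d[0]
    sub[qd[1]] = base_d[1]
    sub[coords[0]] = 0
    sub[coords[1]] = 0
    Mn = M.subs(sub)
    hn = h.subs(sub)
    args = phi_syms + phid_syms + base_d + psyms
    fM = sp.lambdify(args, Mn, "numpy", cse=True)
    fh = sp.lambdify(args, hn, "numpy", cse=True)

    def pack(p: WalkerParams):
        return (p.m_h, p.m_l, p.m_f, p.l, p.d_l, p.l_f, p.d_f, p.j_l, p.j_f, p.g)

    def M_func(phi, phidot, p: WalkerParams, v_base=(0.0, 0.0)):
        return np.asarray(fM(*phi, *phidot, *v_base, *pack(p)), dtype=float)

    def h_func(phi, phidot, p: WalkerParams, v_base=(0.0, 0.0)):
        return np.asarray(fh(*phi, *phidot, *v_base, *pack(p)), dtype=float).reshape(6)

    return M_func, h_func
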