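"""Independent brute-force oracles used only by the tests.

The toggle-switch oracle reduces the 2-gene system to one dimension:
at a steady state A = fA(B) and B = fB(A) with

    fA(B) = gA * HS(B; x0_BA, n_BA, lam_BA) / kA

(monotone in B), so roots of phi(A) = fA(fB(A)) - A enumerate all steady
states.  phi is scanned on a fine grid and each sign change is bisected;
stability comes from the 2x2 Jacobian evaluated independently of the
package's analytic one.
"""

import numpy as np


def _hs(x, x0, n, lam):
    return lam + (1.0 - lam) / (1.0 + (x / x0) ** n)


def _dhs(x, x0, n, lam):
    r = x / x0
    return -(1.0 - lam) * n * r ** (n - 1) / (x0 * (1.0 + r ** n) ** 2)


def toggle_switch_states(gA, kA, gB, kB, lamBA, nBA, x0BA, lamAB, nAB, x0AB,
                         grid=4000, tol=1e-12):
    """All steady states of a plain 2-gene toggle switch.

    Edge B->A has parameters (lamBA, nBA, x0BA) acting on gene A; edge
    A->B analogously.  Returns a list of ((A, B), stable) pairs sorted by A.
    """
    fA = lambda B: gA * _hs(B, x0BA, nBA, lamBA) / kA
    fB = lambda A: gB * _hs(A, x0AB, nAB, lamAB) / kB
    phi = lambda A: fA(fB(A)) - A

    a_hi = gA / kA
    a_lo = a_hi * min(lamBA, 1.0)
    lo, hi = 0.5 * a_lo, 2.0 * a_hi
    xs = np.geomspace(max(lo, 1e-12), hi, grid)
    vals = phi(xs)
    roots = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append(xs[i])
        elif vals[i] * vals[i + 1] < 0:
            a, b = xs[i], xs[i + 1]
            for _ in range(200):
                m = 0.5 * (a + b)
                if phi(a) * phi(m) <= 0:
                    b = m
                else:
                    a = m
                if b - a < tol * max(1.0, m):
                    break
            roots.append(0.5 * (a + b))

    out = []
    for A in roots:
        B = fB(A)
        J = np.array([
            [-kA, gA * _dhs(B, x0BA, nBA, lamBA)],
            [gB * _dhs(A, x0AB, nAB, lamAB), -kB],
        ])
        stable = bool(np.max(np.linalg.eigvals(J).real) < 0)
        out.append(((A, B), stable))
    out.sort(key=lambda r: r[0][0])
    return out


def toggle_switch_states_from_params(params):
    """Adapter: run the oracle from a package KineticParameters for the TS
    topology (edges in the order A->B, B->A)."""
    assert params.edge_pairs == (("A", "B"), ("B", "A"))
    gA, gB = params.g
    kA, kB = params.k
    lamAB, lamBA = params.lam
    nAB, nBA = params.n
    x0AB, x0BA = params.x0
    return toggle_switch_states(gA, kA, gB, kB, lamBA, nBA, x0BA,
                                lamAB, nAB, x0AB)
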