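"""Compiled inner loops for trajectory relaxation.

The integrator is an explicit adaptive Cash-Karp Runge-Kutta 4(5) with a
per-step error controller; the contract upstream is the residual bound,
not the scheme.  Convergence is declared when the relative residual
max_i |dx_i/dt| / max(x_i, floor) drops below the tolerance; trajectories
that exhaust the time horizon are flagged (candidate oscillations).
"""

from __future__ import annotations

import numpy as np
from numba import njit

FLAG_CONVERGED = 1
FLAG_TIMEOUT = 0
FLAG_NONFINITE = -1

# Cash-Karp tableau
_A2 = 0.2
_A3, _B31, _B32 = 0.3, 3.0 / 40.0, 9.0 / 40.0
_A4, _B41, _B42, _B43 = 0.6, 0.3, -0.9, 1.2
_A5, _B51, _B52, _B53, _B54 = 1.0, -11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0
_A6 = 0.875
_B61, _B62, _B63 = 1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0
_B64, _B65 = 44275.0 / 110592.0, 253.0 / 4096.0
_C1, _C3, _C4, _C6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
_D1 = 37.0 / 378.0 - 2825.0 / 27648.0
_D3 = 250.0 / 621.0 - 18575.0 / 48384.0
_D4 = 125.0 / 594.0 - 13525.0 / 55296.0
_D5 = -277.0 / 14336.0
_D6 = 512.0 / 1771.0 - 0.25


@njit(cache=True)
def _rhs(x, g, k, esrc, etgt, lam, nh, thr, out):
    n = g.shape[0]
    for i in range(n):
        out[i] = g[i]
    for e in range(esrc.shape[0]):
        r = x[esrc[e]] / thr[e]
        p = 1.0
        for _ in range(nh[e]):
            p *= r
        out[etgt[e]] *= lam[e] + (1.0 - lam[e]) / (1.0 + p)
    for i in range(n):
        out[i] -= k[i] * x[i]


@njit(cache=True)
def _integrate_one(x, g, k, esrc, etgt, lam, nh, thr,
                   t_max, conv_tol, floor, rtol, atol, max_steps):
    """Relax one trajectory in place; returns a FLAG_* code."""
    n = x.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n)
    xt = np.empty(n)
    t = 0.0
    h = 0.05
    for _ in range(max_steps):
        _rhs(x, g, k, esrc, etgt, lam, nh, thr, k1)
        # convergence on the true residual at the current point
        res = 0.0
        for i in range(n):
            denom = x[i] if x[i] > floor else floor
            r = abs(k1[i]) / denom
            if r > res:
                res = r
        if res < conv_tol:
            return FLAG_CONVERGED
        if t >= t_max:
            return FLAG_TIMEOUT
        if t + h > t_max:
            h = t_max - t
        # one adaptive step
        while True:
            for i in range(n):
                xt[i] = x[i] + h * _A2 * k1[i]
                if xt[i] < 0.0:
                    xt[i] = 0.0
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k2)
            for i in range(n):
                xt[i] = x[i] + h * (_B31 * k1[i] + _B32 * k2[i])
                if xt[i] < 0.0:
                    xt[i] = 0.0
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k3)
            for i in range(n):
                xt[i] = x[i] + h * (_B41 * k1[i] + _B42 * k2[i] + _B43 * k3[i])
                if xt[i] < 0.0:
                    xt[i] = 0.0
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k4)
            for i in range(n):
                xt[i] = x[i] + h * (_B51 * k1[i] + _B52 * k2[i]
                                    + _B53 * k3[i] + _B54 * k4[i])
                if xt[i] < 0.0:
                    xt[i] = 0.0
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k5)
            for i in range(n):
                xt[i] = x[i] + h * (_B61 * k1[i] + _B62 * k2[i] + _B63 * k3[i]
                                    + _B64 * k4[i] + _B65 * k5[i])
                if xt[i] < 0.0:
                    xt[i] = 0.0
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k6)
            err = 0.0
            for i in range(n):
                x_new = x[i] + h * (_C1 * k1[i] + _C3 * k3[i]
                                    + _C4 * k4[i] + _C6 * k6[i])
                e_i = h * (_D1 * k1[i] + _D3 * k3[i] + _D4 * k4[i]
                           + _D5 * k5[i] + _D6 * k6[i])
                sc = atol + rtol * (abs(x[i]) if abs(x[i]) > abs(x_new)
                                    else abs(x_new))
                r = abs(e_i) / sc
                if r > err:
                    err = r
                xt[i] = x_new
            if not np.isfinite(err):
                h *= 0.1
                if h < 1e-14:
                    return FLAG_NONFINITE
                continue
            if err <= 1.0:
                break
            fac = 0.9 * err ** -0.25
            if fac < 0.1:
                fac = 0.1
            h *= fac
            if h < 1e-14:
                return FLAG_NONFINITE
        t += h
        for i in range(n):
            x[i] = xt[i] if xt[i] > 0.0 else 0.0
        fac = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
        if fac > 5.0:
            fac = 5.0
        h *= fac
        if h > 10.0:
            h = 10.0
    return FLAG_TIMEOUT


@njit(cache=True)
def integrate_batch(ics, g, k, esrc, etgt, lam, nh, thr,
                    t_max, conv_tol, floor, rtol, atol, max_steps):
    """Relax every row of ``ics``; returns (final states, flags)."""
    m, n = ics.shape
    finals = np.empty((m, n))
    flags = np.empty(m, dtype=np.int64)
    x = np.empty(n)
    for j in range(m):
        for i in range(n):
            x[i] = ics[j, i]
        flags[j] = _integrate_one(x, g, k, esrc, etgt, lam, nh, thr,
                                  t_max, conv_tol, floor, rtol, atol,
                                  max_steps)
        for i in range(n):
            finals[j, i] = x[i]
    return finals, flags


@njit(cache=True)
def rk4_record(x0, g, k, esrc, etgt, lam, nh, thr, dt, n_record, record_every):
    """Fixed-step RK4 trajectory recorder (for limit-cycle analysis).

    Returns an (n_record, n_genes) array sampled every ``record_every``
    steps of size ``dt``.
    """
    n = x0.shape[0]
    x = x0.copy()
    out = np.empty((n_record, n))
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    xt = np.empty(n)
    for rec in range(n_record):
        for _ in range(record_every):
            _rhs(x, g, k, esrc, etgt, lam, nh, thr, k1)
            for i in range(n):
                xt[i] = x[i] + 0.5 * dt * k1[i]
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k2)
            for i in range(n):
                xt[i] = x[i] + 0.5 * dt * k2[i]
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k3)
            for i in range(n):
                xt[i] = x[i] + dt * k3[i]
            _rhs(xt, g, k, esrc, etgt, lam, nh, thr, k4)
            for i in range(n):
                x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                if x[i] < 0.0:
                    x[i] = 0.0
        for i in range(n):
            out[rec, i] = x[i]
    return out
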