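"""Numba-compiled LARS-lasso homotopy with a reconstruction-tolerance stop.

Solves  min ||beta||_1  s.t.  ||y - beta A||_2 <= eps  for atoms given as
rows of A (here A is a weight-scaled training matrix): the lasso solution
path is traced from beta = 0, and because the residual norm decreases
monotonically along it while the l1 norm increases, the constrained
optimum is the exact path point where the residual norm reaches eps —
located in closed form inside the segment where the crossing happens.

Correlations are maintained through a precomputed Gram matrix of the
unscaled atoms, so a batch of right-hand sides against one training
matrix costs one Gram build plus O(n * k) work per path step.  The active
Cholesky factor grows by rank-one updates and is rebuilt on the (rare)
sign-change drops.  A tiny ridge on the Gram diagonal guards against the
near-collinear atoms that locality scaling produces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: relative correlation level treated as "path exhausted"
_LAMBDA_TOL = 1e-10
#: ridge added to the active Gram diagonal (relative to its scale)
_RIDGE = 1e-10


@njit(cache=True)
def _forward_sub(L, b, k):
    x = np.empty(k)
    for i in range(k):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _back_sub(L, b, k):
    # solves L.T x = b
    x = np.empty(k)
    for i in range(k - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, k):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _homotopy(X, G0, y, invw, eps, max_steps):
    """Path solve for one right-hand side.

    X: (n, m) unscaled atoms; G0 = X X^T; invw: (n,) inverse penalty
    weights (0 disables an atom); eps: tolerance; returns
    (alpha, resid_norm, feasible_flag) with alpha on the original scale.
    """
    n, m = X.shape
    beta = np.zeros(n)
    active = np.empty(n, dtype=np.int64)
    signs = np.empty(n)
    in_active = np.zeros(n, dtype=np.bool_)
    k = 0
    kmax = min(n, m)
    L = np.zeros((kmax + 1, kmax + 1))

    # scaled Gram columns of the active atoms, appended as atoms enter, so
    # the per-step correlation update is one contiguous (k, n) matvec
    Gact = np.empty((kmax + 1, n))

    r = y.copy()
    rn2 = 0.0
    for t in range(m):
        rn2 += r[t] * r[t]
    if np.sqrt(rn2) <= eps:
        return beta, np.sqrt(rn2), True

    # correlations c_i = (x_i / w_i) . r
    c = invw * np.dot(X, r)
    lam = 0.0
    for i in range(n):
        if abs(c[i]) > lam:
            lam = abs(c[i])
    lam0 = lam
    if lam0 <= 0.0:
        return beta, np.sqrt(rn2), False
    ridge = _RIDGE * np.max(np.diag(G0)) + 1e-300

    # seed with the most correlated atom
    j0 = int(np.argmax(np.abs(c)))
    active[0] = j0
    signs[0] = 1.0 if c[j0] > 0 else -1.0
    in_active[j0] = True
    L[0, 0] = np.sqrt(invw[j0] * invw[j0] * G0[j0, j0] + ridge)
    for i in range(n):
        Gact[0, i] = invw[j0] * invw[i] * G0[j0, i]
    k = 1

    for step in range(max_steps):
        # direction: G_SS d = signs
        z = _forward_sub(L, signs[:k].copy(), k)
        d = _back_sub(L, z, k)

        # eta_i = sum_j d_j * Gtilde[i, aj] via the contiguous active buffer
        eta = np.dot(d, Gact[:k])

        # u = sum_j d_j * atom_j (m-vector) for residual tracking
        u = np.zeros(m)
        for j in range(k):
            aj = active[j]
            coef = d[j] * invw[aj]
            for t in range(m):
                u[t] += coef * X[aj, t]

        # candidate step to next atom entering
        gamma = lam  # full LS-on-active limit
        nxt = -1
        nxt_sign = 1.0
        for i in range(n):
            if in_active[i] or invw[i] == 0.0:
                continue
            den1 = 1.0 - eta[i]
            if den1 > 1e-14:
                g = (lam - c[i]) / den1
                if 1e-14 < g < gamma:
                    gamma = g
                    nxt = i
                    nxt_sign = 1.0
            den2 = 1.0 + eta[i]
            if den2 > 1e-14:
                g = (lam + c[i]) / den2
                if 1e-14 < g < gamma:
                    gamma = g
                    nxt = i
                    nxt_sign = -1.0

        # candidate step to a coefficient crossing zero (drop)
        drop = -1
        for j in range(k):
            if d[j] != 0.0:
                g = -beta[active[j]] / d[j]
                if 1e-14 < g < gamma:
                    gamma = g
                    drop = j
                    nxt = -1

        # does the residual reach eps within this segment?
        ru = 0.0
        uu = 0.0
        for t in range(m):
            ru += r[t] * u[t]
            uu += u[t] * u[t]
        # ||r - g u||^2 = rn2 - 2 g ru + g^2 uu = eps^2
        aq, bq, cq = uu, -2.0 * ru, rn2 - eps * eps
        if aq > 0.0:
            disc = bq * bq - 4.0 * aq * cq
            if disc >= 0.0:
                g_eps = (-bq - np.sqrt(disc)) / (2.0 * aq)
                if 0.0 <= g_eps <= gamma + 1e-15:
                    g_eps = min(g_eps, gamma)
                    for j in range(k):
                        beta[active[j]] += g_eps * d[j]
                    alpha = beta * invw
                    return alpha, eps, True

        # commit the full segment
        for j in range(k):
            beta[active[j]] += gamma * d[j]
        for t in range(m):
            r[t] -= gamma * u[t]
        rn2 = rn2 - 2.0 * gamma * ru + gamma * gamma * uu
        if rn2 < 0.0:
            rn2 = 0.0
        c -= gamma * eta
        lam -= gamma
        if np.sqrt(rn2) <= eps:
            alpha = beta * invw
            return alpha, np.sqrt(rn2), True

        if drop >= 0:
            # remove atom and rebuild the Cholesky factor
            jd = active[drop]
            in_active[jd] = False
            beta[jd] = 0.0
            for j in range(drop, k - 1):
                active[j] = active[j + 1]
                signs[j] = signs[j + 1]
                for i in range(n):
                    Gact[j, i] = Gact[j + 1, i]
            k -= 1
            M = np.empty((k, k))
            for a in range(k):
                for b in range(k):
                    ia, ib = active[a], active[b]
                    M[a, b] = invw[ia] * invw[ib] * G0[ia, ib]
                M[a, a] += ridge
            Lsub = np.linalg.cholesky(M)
            for a in range(k):
                for b in range(k):
                    L[a, b] = Lsub[a, b]
        elif nxt >= 0:
            if k >= kmax:
                alpha = beta * invw
                return alpha, np.sqrt(rn2), False
            # rank-one Cholesky extension
            g = np.empty(k)
            for j in range(k):
                g[j] = invw[nxt] * invw[active[j]] * G0[nxt, active[j]]
            l = _forward_sub(L, g, k)
            diag2 = invw[nxt] * invw[nxt] * G0[nxt, nxt] + ridge
            for j in range(k):
                diag2 -= l[j] * l[j]
            if diag2 <= 0.0:
                diag2 = ridge
            for j in range(k):
                L[k, j] = l[j]
            L[k, k] = np.sqrt(diag2)
            active[k] = nxt
            signs[k] = nxt_sign
            in_active[nxt] = True
            for i in range(n):
                Gact[k, i] = invw[nxt] * invw[i] * G0[nxt, i]
            k += 1
        else:
            # gamma == lam: least-squares limit on the active set
            if lam <= _LAMBDA_TOL * lam0:
                break
        # recompute lam defensively (numerical drift)
        lam = 0.0
        for i in range(n):
            if abs(c[i]) > lam:
                lam = abs(c[i])
        if lam <= _LAMBDA_TOL * lam0:
            break

    alpha = beta * invw
    return alpha, np.sqrt(rn2), np.sqrt(rn2) <= eps


@njit(cache=True)
def _class_resid(X, labels, y, alpha):
    m = X.shape[1]
    r0 = y.copy()
    r1 = y.copy()
    for i in range(X.shape[0]):
        a = alpha[i]
        if a != 0.0:
            if labels[i] == 1:
                for t in range(m):
                    r1[t] -= a * X[i, t]
            else:
                for t in range(m):
                    r0[t] -= a * X[i, t]
    v0 = 0.0
    v1 = 0.0
    for t in range(m):
        v0 += r0[t] * r0[t]
        v1 += r1[t] * r1[t]
    return np.sqrt(v0), np.sqrt(v1)


@njit(cache=True)
def batch_solve(X, G0, labels, Y, invW, eps, max_steps):
    """Homotopy solve + per-class residuals for every row of Y.

    Returns (v_nonbinding, v_binding, feasible) arrays of length len(Y).
    """
    nq = Y.shape[0]
    v0 = np.empty(nq)
    v1 = np.empty(nq)
    ok = np.empty(nq, dtype=np.bool_)
    for q in range(nq):
        alpha, _, feas = _homotopy(X, G0, Y[q], invW[q], eps, max_steps)
        ok[q] = feas
        v0[q], v1[q] = _class_resid(X, labels, Y[q], alpha)
    return v0, v1, ok


def solve_constrained_l1(X, y, weights, eps, max_steps=2000, G0=None):
    """Python-facing single solve: returns (alpha, resid_norm, feasible).

    ``weights`` are the l1 penalty coefficients (may contain +inf to
    disable atoms); they are normalized by their minimum first, which
    leaves the argmin unchanged and keeps the path well-conditioned.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    finite = np.isfinite(w)
    if not finite.any():
        raise ValueError("all atoms disabled by infinite weights")
    wmin = w[finite].min()
    if wmin <= 0:
        raise ValueError("weights must be strictly positive")
    with np.errstate(over="ignore"):
        invw = np.where(finite, wmin / w, 0.0)
    if G0 is None:
        G0 = X @ X.T
    return _homotopy(X, G0, y, invw, eps, int(max_steps))
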