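"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own computational paths: naive
loops, dense grid search and all-pairs counting.
"""

from __future__ import annotations

import numpy as np


def naive_block_means(window: np.ndarray, blocks) -> np.ndarray:
    """Two-loop mean over declared (start, end) 1-based row ranges."""
    out = []
    for start, end in blocks:
        for j in range(window.shape[1]):
            acc = 0.0
            cnt = 0
            for i in range(start, end + 1):
                acc += window[i - 1, j]
                cnt += 1
            out.append(acc / cnt)
    return np.array(out)


def grid_search_weighted_l1(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    eps: float,
    box: float = 2.0,
    coarse_step: float = 0.05,
    levels: int = 5,
) -> np.ndarray:
    """Dense coarse-to-fine grid minimizer of sum w_i|a_i| s.t. ||y - aX|| <= eps.

    Starts on a dense grid over [-box, box]^n at ``coarse_step`` and
    refines around the best feasible point; the problem is convex, so
    local refinement around the coarse minimum is sound.  Final
    resolution is coarse_step / 10**levels.
    """
    n = X.shape[0]
    centers = np.zeros(n)
    half = box
    step = coarse_step
    best_pt = None
    for _ in range(levels + 1):
        axes = [np.arange(c - half, c + half + step / 2, step) for c in centers]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in mesh], axis=1)
        resid = np.linalg.norm(y[None, :] - pts @ X, axis=1)
        feasible = resid <= eps + 1e-9
        if not feasible.any():
            # keep the most nearly feasible point and shrink around it
            idx = int(np.argmin(resid))
        else:
            obj = np.abs(pts) @ weights
            obj[~feasible] = np.inf
            idx = int(np.argmin(obj))
        centers = pts[idx]
        best_pt = centers
        half = 2.5 * step
        step = step / 10.0
    return best_pt


def enumerate_weighted_l1(X, y, weights, eps):
    """Exact minimizer of sum w_i|a_i| s.t. ||y - aX|| <= eps by exhaustive
    enumeration of sign patterns (3^n faces of the l1 ball geometry).

    On each face with support F and signs s, the objective is linear, so
    the face optimum lies on the constraint boundary; the KKT system
    c + 2 mu (G a - b) = 0 with G = X_F X_F^T, b = X_F y is solved for the
    multiplier mu by scalar root finding.  Independent of any path solver.
    """
    from itertools import product

    from scipy.optimize import brentq

    n, _ = X.shape
    best_obj, best_a = np.inf, None
    if np.linalg.norm(y) <= eps:
        return np.zeros(n)
    for signs in product((-1, 0, 1), repeat=n):
        s = np.array(signs, dtype=float)
        F = np.nonzero(s)[0]
        if F.size == 0:
            continue
        XF = X[F]
        G = XF @ XF.T
        b = XF @ y
        c = weights[F] * s[F]
        try:
            Ginv_b = np.linalg.solve(G, b)
            Ginv_c = np.linalg.solve(G, c)
        except np.linalg.LinAlgError:
            continue
        ls_resid2 = float(y @ y - b @ Ginv_b)
        if ls_resid2 > eps**2 + 1e-12:
            continue  # face cannot reach the boundary

        def resid2(mu):
            a = Ginv_b - Ginv_c / (2.0 * mu)
            r = y - a @ XF
            return float(r @ r)

        lo, hi = 1e-12, 1e12
        if resid2(lo) < eps**2 or resid2(hi) > eps**2:
            continue
        mu = brentq(lambda m: resid2(m) - eps**2, lo, hi, xtol=1e-15, rtol=1e-14)
        aF = Ginv_b - Ginv_c / (2.0 * mu)
        if np.any(np.sign(np.where(np.abs(aF) < 1e-10, 0.0, aF)) * s[F] < 0):
            continue  # sign pattern not self-consistent
        obj = float(weights[F] @ np.abs(aF))
        if obj < best_obj:
            best_obj = obj
            best_a = np.zeros(n)
            best_a[F] = aF
    return best_a


def auc_pair_count(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs AUC: wins + half credit for score ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_loop(y_true, y_pred):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def lars_reference_solve(X, y, weights, eps, max_iter=500):
    """Constrained weighted-l1 solve via sklearn's lasso path (independent
    of the package's homotopy): interpolate the knot where the residual
    norm crosses eps.  Returns None if the path never reaches eps."""
    import warnings

    from sklearn.linear_model import lars_path

    wn = np.asarray(weights, float)
    wn = wn / wn.min()
    D = np.asfortranarray((X / wn[:, None]).T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, coefs = lars_path(D, y, method="lasso", max_iter=max_iter)
    res = y[:, None] - D @ coefs
    norms = np.linalg.norm(res, axis=0)
    hit = np.nonzero(norms <= eps)[0]
    if not hit.size:
        return None
    k = int(hit[0])
    if k == 0:
        beta = coefs[:, 0]
    else:
        r0, r1 = res[:, k - 1], res[:, k]
        dr = r1 - r0
        aq, bq, cq = dr @ dr, 2 * r0 @ dr, r0 @ r0 - eps**2
        disc = max(bq * bq - 4 * aq * cq, 0.0)
        t = (-bq - np.sqrt(disc)) / (2 * aq)
        if not 0 <= t <= 1:
            t = (-bq + np.sqrt(disc)) / (2 * aq)
        beta = coefs[:, k - 1] + t * (coefs[:, k] - coefs[:, k - 1])
    return beta / wn
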