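"""Coordinate-descent solver for the L1-regularized squared-hinge objective.

Minimizes

    F(w) = ||w||_1 + C * sum_i max(0, 1 - y_i * w.x_i)**2

by cyclic coordinate descent where each one-dimensional subproblem

    h(t) = |t| + C * sum_i max(0, b_i - d_i * t)**2,
    d_i = y_i * x_ij,  b_i = m_i + d_i * w_j   (m_i the current margins)

is minimized *exactly*: h is convex piecewise quadratic with breakpoints
at t = b_i / d_i plus the kink at 0, so a sorted sweep over breakpoints
with running active-set sums locates the subdifferential's zero crossing
in closed form. Exact one-dimensional minimization makes the iteration a
descent method with exact zeros (below the penalty threshold the solution
is the all-zero vector bit for bit) and, because the nonsmooth term is
separable, coordinate-wise optimality implies global optimality.

Stopping: maximum coordinate-wise optimality violation below ``tol`` or
``max_sweeps`` full sweeps. A coordinate whose violation is already below
``tol`` is skipped within the sweep, which makes warm-started refits (the
cross-validation workhorse) cheap. Everything is deterministic: cyclic
order, no randomization.

Internally the design matrix is kept transposed, (p, n), so the inner
loops run over contiguous memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_cd", "fit_path", "objective_value", "cv_accuracy_path"]


@njit(cache=True, fastmath=False)
def _min1d(d, b, t, order, k, C):  # pragma: no cover - jitted
    """Exact minimizer of |t| + C * sum_{q<k} max(0, b_q - d_q t)^2.

    ``t`` and ``order`` are work arrays (breakpoints and their insertion-
    sorted index order; k is small in this package's problems).
    """
    if k == 0:
        return 0.0
    for q in range(k):
        t[q] = b[q] / d[q]
        order[q] = q
    for q in range(1, k):
        oq = order[q]
        tq = t[oq]
        r = q - 1
        while r >= 0 and t[order[r]] > tq:
            order[r + 1] = order[r]
            r -= 1
        order[r + 1] = oq

    twoC = 2.0 * C
    A = 0.0
    Bv = 0.0
    for q in range(k):  # active set for t -> -inf: terms with d > 0
        if d[q] > 0.0:
            A += d[q] * d[q]
            Bv += d[q] * b[q]

    prev = -np.inf
    zero_done = False
    ei = 0
    while True:
        tb = t[order[ei]] if ei < k else np.inf
        if not zero_done and 0.0 <= tb:
            t_e = 0.0
            is_kink = True
        else:
            t_e = tb
            is_kink = False

        if t_e > prev:  # interior stationary point of (prev, t_e)?
            s = -1.0 if t_e <= 0.0 else 1.0
            if A > 0.0:
                tstar = (twoC * Bv - s) / (twoC * A)
                if prev < tstar < t_e:
                    return tstar

        if is_kink:
            gl = -1.0 - twoC * Bv
            gr = 1.0 - twoC * Bv
            if gl <= 0.0 <= gr:
                return 0.0
            zero_done = True
            prev = 0.0
            continue

        if ei >= k:
            break

        q = order[ei]
        s = -1.0 if t_e < 0.0 else 1.0
        gl = s + twoC * (A * t_e - Bv)
        if d[q] > 0.0:  # term deactivates as t passes its breakpoint
            A -= d[q] * d[q]
            Bv -= d[q] * b[q]
        else:
            A += d[q] * d[q]
            Bv += d[q] * b[q]
        gr = s + twoC * (A * t_e - Bv)
        if gl <= 0.0 <= gr:
            return t_e
        prev = t_e
        ei += 1

    if A > 0.0:  # final interval (prev, inf), sign +1
        tstar = (twoC * Bv - 1.0) / (twoC * A)
        if tstar > prev:
            return tstar
    return prev


@njit(cache=True)
def _cd_T(XT, y, C, w, m, d_buf, b_buf, t_buf, order_buf,
          max_sweeps, tol):  # pragma: no cover - jitted
    """CD core on the transposed design XT (p, n) with margin state ``m``."""
    p, n = XT.shape
    twoC = 2.0 * C
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        maxviol = 0.0
        for j in range(p):
            wj = w[j]
            g = 0.0
            # fused pass: gradient of the smooth part + subproblem buffers
            for i in range(n):
                di = y[i] * XT[j, i]
                d_buf[i] = di
                b_buf[i] = m[i] + di * wj
                if m[i] > 0.0:
                    g -= di * m[i]
            g *= twoC
            if wj > 0.0:
                viol = abs(g + 1.0)
            elif wj < 0.0:
                viol = abs(g - 1.0)
            else:
                viol = abs(g) - 1.0
                if viol < 0.0:
                    viol = 0.0
            if viol > maxviol:
                maxviol = viol
            if viol <= tol:
                continue  # coordinate already optimal at this tolerance

            # compact away zero-feature entries (dense data: usually none)
            k = 0
            for i in range(n):
                if d_buf[i] != 0.0:
                    d_buf[k] = d_buf[i]
                    b_buf[k] = b_buf[i]
                    k += 1
            if k == 0:
                w[j] = 0.0
                continue
            t_new = _min1d(d_buf, b_buf, t_buf, order_buf, k, C)
            if t_new != wj:
                w[j] = t_new
                diff = t_new - wj
                for i in range(n):
                    m[i] -= y[i] * XT[j, i] * diff
        if maxviol < tol:
            break
    return sweeps


@njit(cache=True)
def _solve_T(XT, y, C, w, max_sweeps, tol):  # pragma: no cover - jitted
    p, n = XT.shape
    m = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(p):
            acc += XT[j, i] * w[j]
        m[i] = 1.0 - y[i] * acc
    d_buf = np.empty(n)
    b_buf = np.empty(n)
    t_buf = np.empty(n)
    order_buf = np.empty(n, np.int64)
    return _cd_T(XT, y, C, w, m, d_buf, b_buf, t_buf, order_buf,
                 max_sweeps, tol)


def solve_cd(X, y, C, w, max_sweeps, tol):
    """Cyclic CD on F(w); updates ``w`` in place, returns sweeps used.

    ``w`` is the warm start (commonly zeros). X is (n, p) float64, y is
    (n,) float64 in {-1, +1}.
    """
    XT = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    y = np.asarray(y, dtype=np.float64)
    return _solve_T(XT, y, float(C), w, int(max_sweeps), float(tol))


@njit(cache=True)
def _fit_path_T(XT, y, C_grid, max_sweeps, tol, scale_tol):  # pragma: no cover
    """Warm-started solutions along an ascending C grid; returns (nC, p).

    With ``scale_tol`` the stopping tolerance is multiplied by max(1, C):
    violations live on the gradient scale, which grows with C.
    """
    p, n = XT.shape
    W = np.zeros((len(C_grid), p))
    w = np.zeros(p)
    m = np.ones(n)
    d_buf = np.empty(n)
    b_buf = np.empty(n)
    t_buf = np.empty(n)
    order_buf = np.empty(n, np.int64)
    for ci in range(len(C_grid)):
        tol_c = tol * max(1.0, C_grid[ci]) if scale_tol else tol
        _cd_T(XT, y, C_grid[ci], w, m, d_buf, b_buf, t_buf, order_buf,
              max_sweeps, tol_c)
        W[ci] = w
    return W


def fit_path(X, y, C_grid, max_sweeps, tol, scale_tol=False):
    """Warm-started solution path over an ascending C grid, shape (nC, p)."""
    XT = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    return _fit_path_T(XT, np.asarray(y, dtype=np.float64),
                       np.asarray(C_grid, dtype=np.float64),
                       int(max_sweeps), float(tol), scale_tol)


@njit(cache=True)
def cv_accuracy_path(X, y, C_grid, test_pairs, max_sweeps, tol,
                     standardize, fit_intercept):  # pragma: no cover
    """Leave-two-out predictions over a C grid.

    ``X`` is the raw (n, p) feature matrix, ``y`` in {-1, +1};
    ``test_pairs`` is (n_iter, 2) row indices left out per iteration (one
    per class). Standardization, when requested, uses training-fold
    statistics only. Within each fold the C grid is fit as a warm-started
    ascending path *from the fold's own data only* — warm starts never
    involve a model that has seen the left-out samples, so capped sweeps
    cannot leak test labels. The stopping tolerance is scaled by
    max(1, C) since violations live on the gradient scale.

    Returns ``pred`` with shape (n_iter, 2, nC): the sign-rule class
    (+1/-1, ties -> -1) for each left-out sample.
    """
    n, p = X.shape
    nC = len(C_grid)
    n_iter = test_pairs.shape[0]
    p_aug = p + 1 if fit_intercept else p

    nt = n - 2
    XtT = np.empty((p_aug, nt))
    yt = np.empty(nt)
    pred = np.empty((n_iter, 2, nC))
    fmu = np.zeros(p)
    fsd = np.ones(p)

    for it in range(n_iter):
        i0 = test_pairs[it, 0]
        i1 = test_pairs[it, 1]
        r = 0
        for i in range(n):
            if i != i0 and i != i1:
                for j in range(p):
                    XtT[j, r] = X[i, j]
                yt[r] = y[i]
                r += 1
        if standardize:
            for j in range(p):
                acc = 0.0
                for i in range(nt):
                    acc += XtT[j, i]
                fmu[j] = acc / nt
                acc = 0.0
                for i in range(nt):
                    dv = XtT[j, i] - fmu[j]
                    acc += dv * dv
                s = np.sqrt(acc / nt)
                fsd[j] = s if s > 0.0 else 1.0
                for i in range(nt):
                    XtT[j, i] = (XtT[j, i] - fmu[j]) / fsd[j]
        if fit_intercept:
            for i in range(nt):
                XtT[p, i] = 1.0

        W = _fit_path_T(XtT, yt, C_grid, max_sweeps, tol, True)
        for ci in range(nC):
            for q in range(2):
                irow = test_pairs[it, q]
                acc = 0.0
                for j in range(p):
                    # fmu/fsd stay (0, 1) when standardization is off
                    acc += (X[irow, j] - fmu[j]) / fsd[j] * W[ci, j]
                if fit_intercept:
                    acc += W[ci, p]
                pred[it, q, ci] = 1.0 if acc > 0.0 else -1.0
    return pred


def objective_value(X: np.ndarray, y: np.ndarray, w: np.ndarray, C: float) -> float:
    """F(w) = ||w||_1 + C * sum max(0, 1 - y * Xw)^2 (plain numpy)."""
    margins = 1.0 - y * (X @ w)
    hinge = np.maximum(margins, 0.0)
    return float(np.abs(w).sum() + C * np.dot(hinge, hinge))
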