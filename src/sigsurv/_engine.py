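"""Numba kernels for penalized Cox partial-likelihood fitting.

All kernels operate on data sorted by ascending survival time.  Tied times
form groups described by ``first``/``last`` index arrays; the Breslow
approximation shares one risk-set sum per tie group.  Case weights ``w``
(0/1 in cross-validation) select the active subjects, which lets every
leave-one-out fold reuse the same sorted arrays.

Risk-set quantities are accumulated in a single descending pass:

    S0(t)  = sum_{j: t_j >= t} w_j exp(eta_j)
    S1(t)  = sum_{j: t_j >= t} w_j exp(eta_j) x_j

from which the partial log-likelihood, its gradient and its Hessian follow
via the cumulative-hazard identity: with G_i = sum_{events e: t_e <= t_i}
(w_e d_e)/S0_e and a_i = w_i exp(eta_i) G_i,

    grad = X' (w*delta - a),
    hess = X' diag(a) X - sum_events (w_e d_e) xbar_e xbar_e'.

The Hessian is assembled with BLAS matrix products so that fits remain fast
for the ~50-variable combined models.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ETA_CAP = 500.0


@njit(cache=False)
def _risk_pass(Xs, delta, w, first, last, eta, S0arr, Garr, wd):
    """Descending risk-set pass; fills S0arr, Garr (cumulative event/S0)
    and wd (= w*delta).  Returns the partial log-likelihood."""
    n = Xs.shape[0]
    acc0 = 0.0
    for i in range(n - 1, -1, -1):
        e = eta[i]
        if e > _ETA_CAP:
            e = _ETA_CAP
        r = w[i] * np.exp(e)
        acc0 += r
        wd[i] = w[i] * delta[i]
        if i == first[i]:
            for j in range(i, last[i] + 1):
                S0arr[j] = acc0
    loglik = 0.0
    g = 0.0
    for i in range(n):
        if i == first[i]:
            # add this tie group's event mass once, at group entry
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0 and S0arr[i] > 0.0:
                g += gw / S0arr[i]
        Garr[i] = g
        if wd[i] > 0.0:
            loglik += wd[i] * (eta[i] - np.log(S0arr[i]))
    return loglik


@njit(cache=False)
def cox_loglik(Xs, delta, w, first, last, beta):
    """Breslow partial log-likelihood at ``beta`` for the ``w``-weighted set."""
    n, p = Xs.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s
    S0arr = np.zeros(n)
    Garr = np.zeros(n)
    wd = np.zeros(n)
    return _risk_pass(Xs, delta, w, first, last, eta, S0arr, Garr, wd)


@njit(cache=False)
def _loglik_grad_hess(Xs, XsT, delta, w, first, last, beta, grad, hess):
    """Fill gradient and (negative-definite-free) Hessian of the partial
    log-likelihood; returns the log-likelihood."""
    n, p = Xs.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s
    S0arr = np.zeros(n)
    Garr = np.zeros(n)
    wd = np.zeros(n)
    loglik = _risk_pass(Xs, delta, w, first, last, eta, S0arr, Garr, wd)

    # a_i and the gradient
    a = np.zeros(n)
    resid = np.zeros(n)
    for i in range(n):
        e = eta[i]
        if e > _ETA_CAP:
            e = _ETA_CAP
        a[i] = w[i] * np.exp(e) * Garr[i]
        resid[i] = wd[i] - a[i]
    gv = np.dot(XsT, resid)
    for j in range(p):
        grad[j] = gv[j]

    # hess = X' diag(a) X - B'B with B rows sqrt(w_e d_e) xbar_e per event group
    tmp = XsT * a
    H1 = np.dot(tmp, Xs)

    # count event groups
    ng = 0
    for i in range(n):
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0:
                ng += 1
    Bt = np.zeros((p, ng))
    # second descending pass for S1 per group
    acc1 = np.zeros(p)
    gidx = ng - 1
    for i in range(n - 1, -1, -1):
        e = eta[i]
        if e > _ETA_CAP:
            e = _ETA_CAP
        r = w[i] * np.exp(e)
        for j in range(p):
            acc1[j] += r * Xs[i, j]
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0:
                s0 = S0arr[i]
                c = np.sqrt(gw) / s0
                for j in range(p):
                    Bt[j, gidx] = c * acc1[j]
                gidx -= 1
    H2 = np.dot(Bt, Bt.T)
    for j1 in range(p):
        for j2 in range(p):
            hess[j1, j2] = H1[j1, j2] - H2[j1, j2]
    return loglik


@njit(cache=False)
def newton_ridge(Xs, XsT, delta, w, first, last, lam, beta0, tol, maxit):
    """Newton maximization of l(beta) - lam/2 ||beta||^2 with step halving.

    Returns (beta, n_iter, converged, penalized_loglik)."""
    n, p = Xs.shape
    beta = beta0.copy()
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    l_cur = _loglik_grad_hess(Xs, XsT, delta, w, first, last, beta, grad, hess)
    f_cur = l_cur
    for j in range(p):
        f_cur -= 0.5 * lam * beta[j] * beta[j]
    it = 0
    converged = False
    while it < maxit:
        it += 1
        gmax = 0.0
        for j in range(p):
            hess[j, j] += lam + 1e-10
            grad[j] -= lam * beta[j]
            if abs(grad[j]) > gmax:
                gmax = abs(grad[j])
        if gmax < 1e-10:
            converged = True
            break
        step = np.linalg.solve(hess, grad)
        # cap absurd steps (monotone likelihood at lam=0)
        smax = 0.0
        for j in range(p):
            if abs(step[j]) > smax:
                smax = abs(step[j])
        if smax > 10.0:
            for j in range(p):
                step[j] *= 10.0 / smax
        newbeta = beta + step
        f_new = cox_loglik(Xs, delta, w, first, last, newbeta)
        for j in range(p):
            f_new -= 0.5 * lam * newbeta[j] * newbeta[j]
        nhalf = 0
        while f_new < f_cur - 1e-12 and nhalf < 30:
            nhalf += 1
            for j in range(p):
                step[j] *= 0.5
                newbeta[j] = beta[j] + step[j]
            f_new = cox_loglik(Xs, delta, w, first, last, newbeta)
            for j in range(p):
                f_new -= 0.5 * lam * newbeta[j] * newbeta[j]
        beta = newbeta
        f_cur = f_new
        smax = 0.0
        for j in range(p):
            if abs(step[j]) > smax:
                smax = abs(step[j])
        if smax < tol:
            converged = True
            break
        l_cur = _loglik_grad_hess(Xs, XsT, delta, w, first, last, beta, grad, hess)
    return beta, it, converged, f_cur


@njit(cache=False)
def _working_quants(Xs, delta, w, first, last, beta, eta, ww, z):
    """Diagonal quadratic approximation at ``beta``: working weights and
    response for coordinate descent (glmnet-style).  Returns loglik."""
    n, p = Xs.shape
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s
    S0arr = np.zeros(n)
    Garr = np.zeros(n)
    wd = np.zeros(n)
    loglik = _risk_pass(Xs, delta, w, first, last, eta, S0arr, Garr, wd)
    # G2_i = sum_{events <= t_i} w_e d_e / S0_e^2  (same grouping as Garr)
    g2 = 0.0
    G2arr = np.zeros(n)
    for i in range(n):
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0 and S0arr[i] > 0.0:
                g2 += gw / (S0arr[i] * S0arr[i])
        G2arr[i] = g2
    for i in range(n):
        e = eta[i]
        if e > _ETA_CAP:
            e = _ETA_CAP
        r = w[i] * np.exp(e)
        a = r * Garr[i]
        v = a - r * r * G2arr[i]
        if v < 1e-12:
            v = 1e-12
        ww[i] = v
        z[i] = eta[i] + (wd[i] - a) / v
    return loglik


@njit(cache=False)
def cox_lasso_cd(Xs, delta, w, first, last, lam, beta0, tol, maxit):
    """Penalized fit maximizing l(beta) - lam * sum|beta_j| via IRLS plus
    cyclic coordinate descent with soft thresholding.

    Returns (beta, n_iter, converged)."""
    n, p = Xs.shape
    beta = beta0.copy()
    eta = np.zeros(n)
    ww = np.zeros(n)
    z = np.zeros(n)
    converged = False
    it = 0
    while it < maxit:
        it += 1
        _working_quants(Xs, delta, w, first, last, beta, eta, ww, z)
        colssq = np.zeros(p)
        for i in range(n):
            for j in range(p):
                colssq[j] += ww[i] * Xs[i, j] * Xs[i, j]
        res = np.zeros(n)
        for i in range(n):
            res[i] = z[i] - eta[i]
        # inner coordinate descent on the weighted least-squares problem
        for _ in range(100):
            dmax = 0.0
            for j in range(p):
                if colssq[j] <= 0.0:
                    continue
                u = colssq[j] * beta[j]
                for i in range(n):
                    u += ww[i] * Xs[i, j] * res[i]
                if u > lam:
                    bnew = (u - lam) / colssq[j]
                elif u < -lam:
                    bnew = (u + lam) / colssq[j]
                else:
                    bnew = 0.0
                d = bnew - beta[j]
                if d != 0.0:
                    # res_i = z_i - eta_i ; eta gains d * x_ij
                    for i in range(n):
                        res[i] -= d * Xs[i, j]
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            if dmax < 0.1 * tol:
                break
        # recompute eta change magnitude for outer convergence
        dout = 0.0
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += Xs[i, j] * beta[j]
            d = s - eta[i]
            if abs(d) > dout:
                dout = abs(d)
        if dout < tol:
            converged = True
            break
    # flush numerical dust from boundary soft-threshold ties to exact zero
    for j in range(p):
        if abs(beta[j]) < 1e-12:
            beta[j] = 0.0
    return beta, it, converged


@njit(cache=False)
def null_score_max(Xs, XsT, delta, w, first, last):
    """max_j |d l / d beta_j| at beta = 0 -- the lasso lambda_max bound."""
    p = Xs.shape[1]
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    _loglik_grad_hess(Xs, XsT, delta, w, first, last, np.zeros(p), grad, hess)
    m = 0.0
    for j in range(p):
        if abs(grad[j]) > m:
            m = abs(grad[j])
    return m


@njit(cache=False)
def fit_path_ridge(Xs, XsT, delta, w, first, last, lam_grid, tol, maxit):
    """Warm-started ridge fits along a descending lambda grid."""
    nlam = lam_grid.size
    p = Xs.shape[1]
    betas = np.zeros((nlam, p))
    b = np.zeros(p)
    for k in range(nlam):
        b, _, _, _ = newton_ridge(
            Xs, XsT, delta, w, first, last, lam_grid[k], b, tol, maxit
        )
        betas[k] = b
    return betas


@njit(cache=False)
def fit_path_lasso(Xs, delta, w, first, last, lam_grid, tol, maxit):
    nlam = lam_grid.size
    p = Xs.shape[1]
    betas = np.zeros((nlam, p))
    b = np.zeros(p)
    for k in range(nlam):
        b, _, _ = cox_lasso_cd(Xs, delta, w, first, last, lam_grid[k], b, tol, maxit)
        betas[k] = b
    return betas


@njit(cache=False, inline="always")
def _chol_solve(A, b, x, p):
    """Solve A x = b for symmetric positive-definite A via an in-place
    Cholesky; A's lower triangle is overwritten.  Returns False on
    breakdown (caller should jitter the diagonal)."""
    for j in range(p):
        s = A[j, j]
        for k in range(j):
            s -= A[j, k] * A[j, k]
        if s <= 0.0:
            return False
        d = np.sqrt(s)
        A[j, j] = d
        for i in range(j + 1, p):
            s = A[i, j]
            for k in range(j):
                s -= A[i, k] * A[j, k]
            A[i, j] = s / d
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= A[i, k] * x[k]
        x[i] = s / A[i, i]
    for i in range(p - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, p):
            s -= A[k, i] * x[k]
        x[i] = s / A[i, i]
    return True


@njit(cache=False, inline="always")
def _risk_from_r(delta, w, first, last, eta, r, S0arr, Garr, wd):
    """Risk-set pass from precomputed r = w*exp(eta); fills the shared
    buffers and returns the partial log-likelihood."""
    n = r.size
    acc0 = 0.0
    for i in range(n - 1, -1, -1):
        acc0 += r[i]
        wd[i] = w[i] * delta[i]
        if i == first[i]:
            for j in range(i, last[i] + 1):
                S0arr[j] = acc0
    loglik = 0.0
    g = 0.0
    for i in range(n):
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0 and S0arr[i] > 0.0:
                g += gw / S0arr[i]
        Garr[i] = g
        if wd[i] > 0.0:
            loglik += wd[i] * (eta[i] - np.log(S0arr[i]))
    return loglik


@njit(cache=False, inline="always")
def _newton_ws(
    Xs, XsT, delta, w, first, last, lam, beta,
    eta, r, S0arr, Garr, wd, a, resid, grad, hess, chol, step, acc1,
    tol, maxit,
):
    """Workspace Newton for the ridge objective l(beta) - lam/2 ||beta||^2.

    All buffers are caller-owned; ``beta`` is updated in place.  Small-p
    explicit loops; convergence on the applied-step norm (the error after a
    step of size s is O(s^2)).  Returns the iteration count."""
    n, p = Xs.shape
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s if s < _ETA_CAP else _ETA_CAP
        r[i] = w[i] * np.exp(eta[i])
    l_cur = _risk_from_r(delta, w, first, last, eta, r, S0arr, Garr, wd)
    pen = 0.0
    for j in range(p):
        pen += beta[j] * beta[j]
    f_cur = l_cur - 0.5 * lam * pen
    it = 0
    while it < maxit:
        it += 1
        for i in range(n):
            a[i] = r[i] * Garr[i]
            resid[i] = wd[i] - a[i]
        gmax = 0.0
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += Xs[i, j] * resid[i]
            grad[j] = s - lam * beta[j]
            if abs(grad[j]) > gmax:
                gmax = abs(grad[j])
        if gmax < 1e-11:
            break
        # hess = X' diag(a) X - sum_groups (gw/S0^2) S1 S1'  (+ lam I)
        for j1 in range(p):
            for j2 in range(j1, p):
                s = 0.0
                for i in range(n):
                    s += a[i] * Xs[i, j1] * Xs[i, j2]
                hess[j1, j2] = s
        for j in range(p):
            acc1[j] = 0.0
        for i in range(n - 1, -1, -1):
            for j in range(p):
                acc1[j] += r[i] * Xs[i, j]
            if i == first[i]:
                gw = 0.0
                for jj in range(i, last[i] + 1):
                    gw += wd[jj]
                if gw > 0.0:
                    c = gw / (S0arr[i] * S0arr[i])
                    for j1 in range(p):
                        for j2 in range(j1, p):
                            hess[j1, j2] -= c * acc1[j1] * acc1[j2]
        for j1 in range(p):
            hess[j1, j1] += lam + 1e-10
            for j2 in range(j1, p):
                chol[j2, j1] = hess[j1, j2]
        ok = _chol_solve(chol, grad, step, p)
        if not ok:
            for j1 in range(p):
                for j2 in range(j1, p):
                    chol[j2, j1] = hess[j1, j2]
                chol[j1, j1] = hess[j1, j1] + 1e-6
            _chol_solve(chol, grad, step, p)
        smax = 0.0
        for j in range(p):
            if abs(step[j]) > smax:
                smax = abs(step[j])
        if smax > 10.0:
            for j in range(p):
                step[j] *= 10.0 / smax
            smax = 10.0
        scale = 1.0
        for _ in range(31):
            for j in range(p):
                beta[j] += scale * step[j]
            for i in range(n):
                s = 0.0
                for j in range(p):
                    s += Xs[i, j] * beta[j]
                eta[i] = s if s < _ETA_CAP else _ETA_CAP
                r[i] = w[i] * np.exp(eta[i])
            l_new = _risk_from_r(delta, w, first, last, eta, r, S0arr, Garr, wd)
            pen = 0.0
            for j in range(p):
                pen += beta[j] * beta[j]
            f_new = l_new - 0.5 * lam * pen
            if f_new >= f_cur - 1e-12:
                break
            for j in range(p):
                beta[j] -= scale * step[j]
            scale *= 0.5
        f_cur = f_new
        if smax * scale < tol:
            break
    return it


@njit(cache=False, inline="always")
def _chol_factor(A, p):
    """In-place Cholesky of the lower triangle of A; False on breakdown."""
    for j in range(p):
        s = A[j, j]
        for k in range(j):
            s -= A[j, k] * A[j, k]
        if s <= 0.0:
            return False
        d = np.sqrt(s)
        A[j, j] = d
        for i in range(j + 1, p):
            s = A[i, j]
            for k in range(j):
                s -= A[i, k] * A[j, k]
            A[i, j] = s / d
    return True


@njit(cache=False, inline="always")
def _chol_apply(L, b, x, p):
    """x = (L L')^{-1} b for a prefactored lower-triangular L."""
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(p - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=False, inline="always")
def _hess_at(Xs, delta, w, first, last, beta, lam, eta, r, S0arr, Garr, wd, a, acc1, hess):
    """Penalized negative Hessian (upper triangle) at ``beta``."""
    n, p = Xs.shape
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s if s < _ETA_CAP else _ETA_CAP
        r[i] = w[i] * np.exp(eta[i])
    _risk_from_r(delta, w, first, last, eta, r, S0arr, Garr, wd)
    for i in range(n):
        a[i] = r[i] * Garr[i]
    for j1 in range(p):
        for j2 in range(j1, p):
            s = 0.0
            for i in range(n):
                s += a[i] * Xs[i, j1] * Xs[i, j2]
            hess[j1, j2] = s
    for j in range(p):
        acc1[j] = 0.0
    for i in range(n - 1, -1, -1):
        for j in range(p):
            acc1[j] += r[i] * Xs[i, j]
        if i == first[i]:
            gw = 0.0
            for jj in range(i, last[i] + 1):
                gw += wd[jj]
            if gw > 0.0:
                c = gw / (S0arr[i] * S0arr[i])
                for j1 in range(p):
                    for j2 in range(j1, p):
                        hess[j1, j2] -= c * acc1[j1] * acc1[j2]
    for j in range(p):
        hess[j, j] += lam + 1e-10
    return 0


@njit(cache=False)
def cv_deviance_loo(
    Xs, XsT, delta, w_train, first, last, lam_grid, l1, tol, maxit
):
    """Leave-one-out cross-validated partial deviance along a lambda grid.

    For each active subject i and each lambda, refit on the training set
    minus i (warm-started from the full-training-set solution at the same
    lambda) and accumulate the Verweij-van Houwelingen contribution

        cvl_i = l_train(beta_{-i}) - l_{train - i}(beta_{-i}).

    Returns the deviance curve  -2 * sum_i cvl_i  per lambda."""
    n, p = Xs.shape
    nlam = lam_grid.size
    eta = np.zeros(n)
    r = np.zeros(n)
    S0arr = np.zeros(n)
    Garr = np.zeros(n)
    wd = np.zeros(n)
    a = np.zeros(n)
    resid = np.zeros(n)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    chol = np.zeros((p, p))
    step = np.zeros(p)
    acc1 = np.zeros(p)

    betas_full = np.zeros((nlam, p))
    chols = np.zeros((nlam, p, p))
    b = np.zeros(p)
    for k in range(nlam):
        if l1:
            b, _, _ = cox_lasso_cd(Xs, delta, w_train, first, last, lam_grid[k], b, tol, maxit)
        else:
            _newton_ws(
                Xs, XsT, delta, w_train, first, last, lam_grid[k], b,
                eta, r, S0arr, Garr, wd, a, resid, grad, hess, chol, step, acc1,
                tol, maxit,
            )
            # store the Cholesky of the penalized Hessian at the full-train
            # optimum: each leave-one-out refit reuses it as a fixed
            # Fisher-scoring metric (the Hessian changes only by O(1/n)).
            _hess_at(
                Xs, delta, w_train, first, last, b, lam_grid[k],
                eta, r, S0arr, Garr, wd, a, acc1, hess,
            )
            for j1 in range(p):
                for j2 in range(j1, p):
                    chols[k, j2, j1] = hess[j1, j2]
            if not _chol_factor(chols[k], p):
                for j1 in range(p):
                    for j2 in range(j1, p):
                        chols[k, j2, j1] = hess[j1, j2]
                    chols[k, j1, j1] += 1e-6
                _chol_factor(chols[k], p)
        betas_full[k] = b

    dev = np.zeros(nlam)
    w_fold = w_train.copy()
    bf = np.zeros(p)
    corr = np.zeros(p)
    for i in range(n):
        if w_train[i] <= 0.0:
            continue
        w_fold[i] = 0.0
        for j in range(p):
            corr[j] = 0.0
        for k in range(nlam):
            # warm start: full-train solution at this lambda plus the
            # leave-one-out correction carried over from the previous lambda
            for j in range(p):
                bf[j] = betas_full[k, j] + corr[j]
            if l1:
                bf, _, _ = cox_lasso_cd(
                    Xs, delta, w_fold, first, last, lam_grid[k], bf, tol, maxit
                )
                l_wo = cox_loglik(Xs, delta, w_fold, first, last, bf)
                l_all = cox_loglik(Xs, delta, w_train, first, last, bf)
            else:
                lam = lam_grid[k]
                # fixed-metric quasi-Newton from the full-train solution
                for ii in range(n):
                    s = 0.0
                    for j in range(p):
                        s += Xs[ii, j] * bf[j]
                    eta[ii] = s if s < _ETA_CAP else _ETA_CAP
                    r[ii] = w_fold[ii] * np.exp(eta[ii])
                converged = False
                for _ in range(30):
                    _risk_from_r(delta, w_fold, first, last, eta, r, S0arr, Garr, wd)
                    for ii in range(n):
                        resid[ii] = wd[ii] - r[ii] * Garr[ii]
                    for j in range(p):
                        s = 0.0
                        for ii in range(n):
                            s += Xs[ii, j] * resid[ii]
                        grad[j] = s - lam * bf[j]
                    _chol_apply(chols[k], grad, step, p)
                    smax = 0.0
                    for j in range(p):
                        bf[j] += step[j]
                        if abs(step[j]) > smax:
                            smax = abs(step[j])
                    for ii in range(n):
                        s = 0.0
                        for j in range(p):
                            s += Xs[ii, j] * bf[j]
                        eta[ii] = s if s < _ETA_CAP else _ETA_CAP
                        r[ii] = w_fold[ii] * np.exp(eta[ii])
                    if smax < tol:
                        converged = True
                        break
                if not converged:
                    _newton_ws(
                        Xs, XsT, delta, w_fold, first, last, lam, bf,
                        eta, r, S0arr, Garr, wd, a, resid, grad, hess, chol,
                        step, acc1, tol, maxit,
                    )
                # eta/r are current for bf: reuse them for both logliks
                l_wo = _risk_from_r(delta, w_fold, first, last, eta, r, S0arr, Garr, wd)
                for ii in range(n):
                    r[ii] = w_train[ii] * np.exp(eta[ii])
                l_all = _risk_from_r(delta, w_train, first, last, eta, r, S0arr, Garr, wd)
                for j in range(p):
                    corr[j] = bf[j] - betas_full[k, j]
            dev[k] += -2.0 * (l_all - l_wo)
        w_fold[i] = 1.0
    return dev


@njit(cache=False)
def breslow_cumhaz(Xs, delta, w, first, last, beta):
    """Breslow cumulative baseline hazard at the reference covariate pattern
    eta = 0 (columns already centered).  Returns (event_times_idx, H0 steps)
    as parallel arrays over event tie groups (ascending)."""
    n, p = Xs.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += Xs[i, j] * beta[j]
        eta[i] = s
    S0arr = np.zeros(n)
    Garr = np.zeros(n)
    wd = np.zeros(n)
    _risk_pass(Xs, delta, w, first, last, eta, S0arr, Garr, wd)
    ng = 0
    for i in range(n):
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0:
                ng += 1
    idx = np.zeros(ng, dtype=np.int64)
    h0 = np.zeros(ng)
    g = 0
    cum = 0.0
    for i in range(n):
        if i == first[i]:
            gw = 0.0
            for j in range(i, last[i] + 1):
                gw += wd[j]
            if gw > 0.0:
                cum += gw / S0arr[i]
                idx[g] = i
                h0[g] = cum
                g += 1
    return idx, h0


# ---------------------------------------------------------------------------
# penalized logistic regression (intercept unpenalized)


@njit(cache=False)
def logistic_loglik(X, y, w, beta, intercept):
    n, p = X.shape
    ll = 0.0
    for i in range(n):
        if w[i] <= 0.0:
            continue
        s = intercept
        for j in range(p):
            s += X[i, j] * beta[j]
        if s > 35.0:
            ll += w[i] * (y[i] * s - s)
        elif s < -35.0:
            ll += w[i] * (y[i] * s)
        else:
            ll += w[i] * (y[i] * s - np.log(1.0 + np.exp(s)))
    return ll


@njit(cache=False)
def logistic_ridge(X, y, w, lam, beta0, int0, tol, maxit):
    """Newton fit of penalized Bernoulli likelihood l - lam/2 ||beta||^2."""
    n, p = X.shape
    q = p + 1
    beta = beta0.copy()
    intercept = int0
    it = 0
    converged = False
    while it < maxit:
        it += 1
        grad = np.zeros(q)
        hess = np.zeros((q, q))
        for i in range(n):
            if w[i] <= 0.0:
                continue
            s = intercept
            for j in range(p):
                s += X[i, j] * beta[j]
            if s > 35.0:
                mu = 1.0
            elif s < -35.0:
                mu = 0.0
            else:
                mu = 1.0 / (1.0 + np.exp(-s))
            r = w[i] * (y[i] - mu)
            v = w[i] * mu * (1.0 - mu)
            if v < 1e-10:
                v = 1e-10
            grad[0] += r
            hess[0, 0] += v
            for j in range(p):
                grad[j + 1] += r * X[i, j]
                hess[0, j + 1] += v * X[i, j]
                hess[j + 1, 0] += v * X[i, j]
                for j2 in range(p):
                    hess[j + 1, j2 + 1] += v * X[i, j] * X[i, j2]
        for j in range(p):
            grad[j + 1] -= lam * beta[j]
            hess[j + 1, j + 1] += lam
        step = np.linalg.solve(hess, grad)
        smax = 0.0
        for j in range(q):
            if abs(step[j]) > smax:
                smax = abs(step[j])
        if smax > 10.0:
            for j in range(q):
                step[j] *= 10.0 / smax
            smax = 10.0
        intercept += step[0]
        for j in range(p):
            beta[j] += step[j + 1]
        if smax < tol:
            converged = True
            break
    return beta, intercept, it, converged


@njit(cache=False)
def logistic_lasso_cd(X, y, w, lam, beta0, int0, tol, maxit):
    """IRLS + coordinate descent for l - lam * sum|beta_j| (intercept free)."""
    n, p = X.shape
    beta = beta0.copy()
    intercept = int0
    eta = np.zeros(n)
    converged = False
    it = 0
    while it < maxit:
        it += 1
        ww = np.zeros(n)
        z = np.zeros(n)
        for i in range(n):
            s = intercept
            for j in range(p):
                s += X[i, j] * beta[j]
            eta[i] = s
            if s > 35.0:
                mu = 1.0
            elif s < -35.0:
                mu = 0.0
            else:
                mu = 1.0 / (1.0 + np.exp(-s))
            v = w[i] * mu * (1.0 - mu)
            if v < 1e-10:
                v = 1e-10
            ww[i] = v
            z[i] = s + w[i] * (y[i] - mu) / v
        res = np.zeros(n)
        for i in range(n):
            res[i] = z[i] - eta[i]
        sw = 0.0
        for i in range(n):
            sw += ww[i]
        colssq = np.zeros(p)
        for i in range(n):
            for j in range(p):
                colssq[j] += ww[i] * X[i, j] * X[i, j]
        for _ in range(100):
            dmax = 0.0
            # intercept (unpenalized)
            u = 0.0
            for i in range(n):
                u += ww[i] * res[i]
            d0 = u / sw
            if d0 != 0.0:
                intercept += d0
                for i in range(n):
                    res[i] -= d0
                if abs(d0) > dmax:
                    dmax = abs(d0)
            for j in range(p):
                if colssq[j] <= 0.0:
                    continue
                u = colssq[j] * beta[j]
                for i in range(n):
                    u += ww[i] * X[i, j] * res[i]
                if u > lam:
                    bnew = (u - lam) / colssq[j]
                elif u < -lam:
                    bnew = (u + lam) / colssq[j]
                else:
                    bnew = 0.0
                d = bnew - beta[j]
                if d != 0.0:
                    for i in range(n):
                        res[i] -= d * X[i, j]
                    beta[j] = bnew
                    if abs(d) > dmax:
                        dmax = abs(d)
            if dmax < 0.1 * tol:
                break
        dout = 0.0
        for i in range(n):
            s = intercept
            for j in range(p):
                s += X[i, j] * beta[j]
            d = s - eta[i]
            if abs(d) > dout:
                dout = abs(d)
        if dout < tol:
            converged = True
            break
    return beta, intercept, it, converged


@njit(cache=False)
def logistic_cv_deviance_loo(X, y, w_train, lam_grid, l1, tol, maxit):
    """LOO-CV predictive binomial deviance along a lambda grid."""
    n, p = X.shape
    nlam = lam_grid.size
    betas = np.zeros((nlam, p))
    ints = np.zeros(nlam)
    b = np.zeros(p)
    b0 = 0.0
    for k in range(nlam):
        if l1:
            b, b0, _, _ = logistic_lasso_cd(X, y, w_train, lam_grid[k], b, b0, tol, maxit)
        else:
            b, b0, _, _ = logistic_ridge(X, y, w_train, lam_grid[k], b, b0, tol, maxit)
        betas[k] = b
        ints[k] = b0
    dev = np.zeros(nlam)
    w_fold = w_train.copy()
    for i in range(n):
        if w_train[i] <= 0.0:
            continue
        w_fold[i] = 0.0
        bf = betas[0].copy()
        bf0 = ints[0]
        for k in range(nlam):
            if l1:
                bf, bf0, _, _ = logistic_lasso_cd(
                    X, y, w_fold, lam_grid[k], bf, bf0, tol, maxit
                )
            else:
                bf, bf0, _, _ = logistic_ridge(
                    X, y, w_fold, lam_grid[k], bf, bf0, tol, maxit
                )
            s = bf0
            for j in range(p):
                s += X[i, j] * bf[j]
            if s > 35.0:
                s = 35.0
            elif s < -35.0:
                s = -35.0
            mu = 1.0 / (1.0 + np.exp(-s))
            dev[k] += -2.0 * (y[i] * np.log(mu) + (1.0 - y[i]) * np.log(1.0 - mu))
        w_fold[i] = 1.0
    return dev
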