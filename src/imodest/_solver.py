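"""Coordinate-descent elastic-net kernels.

Objective (glmnet parameterization, mixing parameter ``alpha``):

    (1/(2n)) * sum_i (y_i - b0 - x_i.b)^2
        + lam * ( alpha * ||b||_1  +  (1 - alpha)/2 * ||b||_2^2 )

With ``alpha = 0.5`` the l1 and squared-l2 terms are weighted
``0.5 * lam`` and ``0.25 * lam`` respectively.  The intercept is handled
by centering: all kernels work on the centered Gram matrix
``C = Xc'Xc`` and moment vector ``c = Xc'yc`` of the current subset, so a
leave-one-out or leave-fold-out refit is a rank-one/few downdate of the
full-data moments — no data copying, no re-centering passes.

Coordinate update for feature j (rho = c_j - sum_{k!=j} C_jk b_k):

    b_j <- soft(rho/n, lam*alpha) / (C_jj/n + lam*(1-alpha))

The penalty applies on the scale the columns already have (cohort-wide
standardized); subsets are centered but not re-scaled, matching a fixed
penalty held across refits.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def cd_solve(C, c, n, lam, alpha, beta, tol, max_iter):
    """In-place coordinate descent on centered moments; returns #passes."""
    p = C.shape[0]
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    it = 0
    for it in range(max_iter):
        dmax = 0.0
        for j in range(p):
            r = c[j] + C[j, j] * beta[j]
            for k in range(p):
                r -= C[j, k] * beta[k]
            r /= n
            denom = C[j, j] / n + l2
            if denom <= 0.0:
                bj = 0.0
            elif r > l1:
                bj = (r - l1) / denom
            elif r < -l1:
                bj = (r + l1) / denom
            else:
                bj = 0.0
            d = bj - beta[j]
            if d < 0.0:
                d = -d
            if d > dmax:
                dmax = d
            beta[j] = bj
        if dmax < tol:
            break
    return it + 1


@njit(cache=True)
def _moments(X, y):
    n, p = X.shape
    G = np.zeros((p, p))
    b = np.zeros(p)
    Sx = np.zeros(p)
    Sy = 0.0
    for i in range(n):
        Sy += y[i]
        for j in range(p):
            xij = X[i, j]
            Sx[j] += xij
            b[j] += y[i] * xij
            for k in range(j, p):
                G[j, k] += xij * X[i, k]
    for j in range(p):
        for k in range(j):
            G[j, k] = G[k, j]
    return G, b, Sx, Sy


@njit(cache=True)
def fit_path(X, y, lams, alpha, tol, max_iter):
    """Full-data fit warm-started down a descending lambda path.

    Returns (beta at the final lambda, intercept).
    """
    n, p = X.shape
    G, b, Sx, Sy = _moments(X, y)
    C = np.empty((p, p))
    cvec = np.empty(p)
    for j in range(p):
        cvec[j] = b[j] - Sx[j] * (Sy / n)
        for k in range(p):
            C[j, k] = G[j, k] - Sx[j] * Sx[k] / n
    beta = np.zeros(p)
    for li in range(lams.shape[0]):
        cd_solve(C, cvec, n, lams[li], alpha, beta, tol, max_iter)
    b0 = Sy / n
    for j in range(p):
        b0 -= Sx[j] / n * beta[j]
    return beta, b0


@njit(cache=True)
def loo_predictions(X, y, lam, alpha, beta_init, tol, max_iter):
    """Exact leave-one-out predictions at a fixed lambda.

    Each held-out sample's model is refit to convergence on the n-1
    remaining samples (centered moments via rank-one downdate), warm
    started from ``beta_init`` (the full-data solution).
    """
    n, p = X.shape
    G, b, Sx, Sy = _moments(X, y)
    preds = np.empty(n)
    C = np.empty((p, p))
    cvec = np.empty(p)
    beta = np.empty(p)
    for i in range(n):
        n1 = n - 1
        Sy1 = Sy - y[i]
        for j in range(p):
            sxj = Sx[j] - X[i, j]
            cvec[j] = b[j] - y[i] * X[i, j] - sxj * (Sy1 / n1)
            for k in range(p):
                sxk = Sx[k] - X[i, k]
                C[j, k] = G[j, k] - X[i, j] * X[i, k] - sxj * sxk / n1
        for j in range(p):
            beta[j] = beta_init[j]
        cd_solve(C, cvec, n1, lam, alpha, beta, tol, max_iter)
        b0 = Sy1 / n1
        xb = 0.0
        for j in range(p):
            b0 -= (Sx[j] - X[i, j]) / n1 * beta[j]
            xb += X[i, j] * beta[j]
        preds[i] = b0 + xb
    return preds


@njit(cache=True)
def cv_path_sse(X, y, lams, alpha, fold_ids, n_folds, tol, max_iter):
    """K-fold cross-validated prediction SSE along a descending lambda
    path (warm starts within each fold).  Returns the total held-out SSE
    per lambda."""
    n, p = X.shape
    G, b, Sx, Sy = _moments(X, y)
    nl = lams.shape[0]
    sse = np.zeros(nl)
    C = np.empty((p, p))
    cvec = np.empty(p)
    beta = np.empty(p)
    Gout = np.empty((p, p))
    Sxo = np.empty(p)
    bo = np.empty(p)
    for f in range(n_folds):
        n_out = 0
        Syo = 0.0
        for j in range(p):
            Sxo[j] = 0.0
            bo[j] = 0.0
            for k in range(p):
                Gout[j, k] = 0.0
        for i in range(n):
            if fold_ids[i] == f:
                n_out += 1
                Syo += y[i]
                for j in range(p):
                    xij = X[i, j]
                    Sxo[j] += xij
                    bo[j] += y[i] * xij
                    for k in range(p):
                        Gout[j, k] += xij * X[i, k]
        n_in = n - n_out
        if n_in < 2 or n_out == 0:
            continue
        Syi = Sy - Syo
        for j in range(p):
            sxj = Sx[j] - Sxo[j]
            cvec[j] = (b[j] - bo[j]) - sxj * (Syi / n_in)
            for k in range(p):
                sxk = Sx[k] - Sxo[k]
                C[j, k] = G[j, k] - Gout[j, k] - sxj * sxk / n_in
        for j in range(p):
            beta[j] = 0.0
        for li in range(nl):
            cd_solve(C, cvec, n_in, lams[li], alpha, beta, tol, max_iter)
            b0 = Syi / n_in
            for j in range(p):
                b0 -= (Sx[j] - Sxo[j]) / n_in * beta[j]
            for i in range(n):
                if fold_ids[i] == f:
                    pred = b0
                    for j in range(p):
                        pred += X[i, j] * beta[j]
                    d = y[i] - pred
                    sse[li] += d * d
    return sse
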