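"""Logistic-regression fitting primitives shared across modules.

Two entry points: a general IRLS fit for small design matrices, and a
vectorized per-SNP fit (intercept + dosage only) used when thousands of
single-SNP models must be fitted at once.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit

MAX_ITER = 25
TOL = 1e-8
# |beta| beyond this on a standardized-ish scale signals (quasi-)separation
BETA_BOUND = 15.0


def irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER,
                  tol: float = TOL) -> tuple[np.ndarray, np.ndarray | None, bool]:
    """Fit y ~ X by iteratively reweighted least squares.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary response in {0, 1}.

    Returns
    -------
    (beta, cov, converged) where cov is the inverse observed information at
    the final iterate (None if singular) and converged is False on
    non-convergence or separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X.T * w) @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        eta = np.clip(X @ beta, -30.0, 30.0)
        ll = float(y @ eta + log_expit(-eta).sum())
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if np.max(np.abs(beta)) > BETA_BOUND:
        converged = False
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, converged


def batch_snp_logistic(G: np.ndarray, y: np.ndarray,
                       max_iter: int = MAX_ITER, tol: float = TOL):
    """Fit status ~ intercept + dosage independently for every column of G.

    Missing dosages (NaN) drop that sample for that SNP only.  Columns with
    zero dosage variance among non-missing samples are flagged untestable.

    Returns
    -------
    dict of 1-D arrays keyed by ``beta``, ``se``, ``pvalue``, ``n_used``,
    ``converged`` (bool; False for untestable or separated columns).
    """
    from scipy.stats import norm

    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    mask = np.isfinite(G)
    Gz = np.where(mask, G, 0.0)
    n_used = mask.sum(axis=0)

    # untestable: monomorphic dosage among non-missing samples
    s1 = (Gz * mask).sum(axis=0)
    s2 = (Gz * Gz * mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / np.maximum(n_used, 1) - (s1 / np.maximum(n_used, 1)) ** 2
    testable = (n_used >= 2) & (var > 1e-12)

    a = np.zeros(m)
    b = np.zeros(m)
    ll_old = np.full(m, -np.inf)
    done = ~testable
    for _ in range(max_iter):
        eta = np.clip(a[None, :] + Gz * b[None, :], -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None) * mask
        r = (y[:, None] - mu) * mask
        S0 = w.sum(axis=0)
        S1 = (w * Gz).sum(axis=0)
        S2 = (w * Gz * Gz).sum(axis=0)
        g0 = r.sum(axis=0)
        g1 = (r * Gz).sum(axis=0)
        det = S0 * S2 - S1 * S1
        bad = det <= 1e-300
        det = np.where(bad, 1.0, det)
        da = np.where(bad | done, 0.0, (S2 * g0 - S1 * g1) / det)
        db = np.where(bad | done, 0.0, (S0 * g1 - S1 * g0) / det)
        a = a + da
        b = b + db
        eta = np.clip(a[None, :] + Gz * b[None, :], -30.0, 30.0)
        ll = (mask * (y[:, None] * eta + log_expit(-eta))).sum(axis=0)
        done = done | (np.abs(ll - ll_old) < tol)
        ll_old = ll
        if done.all():
            break
    converged = done & testable & (np.abs(b) <= BETA_BOUND) & (np.abs(a) <= BETA_BOUND)

    # Wald SE for the dosage slope from the final information matrix
    eta = np.clip(a[None, :] + Gz * b[None, :], -30.0, 30.0)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None) * mask
    S0 = w.sum(axis=0)
    S1 = (w * Gz).sum(axis=0)
    S2 = (w * Gz * Gz).sum(axis=0)
    det = S0 * S2 - S1 * S1
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.where(det > 0, S0 / np.where(det > 0, det, 1.0), np.nan))
    se = np.where(converged, se, np.nan)
    with np.errstate(invalid="ignore"):
        z = np.abs(b) / se
    pval = np.clip(2.0 * norm.sf(z), 1e-300, 1.0)
    pval = np.where(converged, pval, np.nan)
    beta = np.where(converged, b, np.nan)
    return {"beta": beta, "se": se, "pvalue": pval,
            "n_used": n_used.astype(int), "converged": converged}
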