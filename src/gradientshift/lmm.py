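"""Random-intercept linear mixed model via profiled likelihood.

The model is  y = X beta + Z u + e,  with one random intercept per group
(u_g ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2 I)).  Writing lambda =
sigma_u^2 / sigma_e^2, the covariance is V = sigma_e^2 (I + lambda Z Z'),
and for a given lambda the GLS problem reduces to ordinary least squares on
group-wise partially demeaned data: within a group of size m every row has
theta * group-mean subtracted, theta = 1 - (1 + lambda m)^(-1/2).  Both beta
and sigma_e^2 then profile out in closed form, leaving a one-dimensional
search over log(lambda) (coarse grid scan + golden-section refinement).

This specialization exists because the cross-validated permutation analyses
need on the order of 10^5-10^6 refits; general-purpose mixed-model code is
orders of magnitude too slow for that.  The kernels are written as plain
loops and JIT-compiled with numba when available (a pure-NumPy fallback runs
the identical source).  Agreement with statsmodels' MixedLM is enforced in
the test suite.

Estimation is ML by default (required for AIC ladders); REML is available
for coefficient reporting.  AIC counts all estimated parameters including
the two variance components.  Wald t statistics use residual degrees of
freedom n - p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = ["LMMFit", "fit_lmm", "predict_lmm", "loocv", "permuted_loocv_accuracies",
           "HAVE_NUMBA"]

_LOG_LAM_LO = -12.0
_LOG_LAM_HI = 8.0


@njit(cache=True)
def _crit_at(X, y, starts, counts, lam, reml):
    """Profiled -2 log-likelihood at variance ratio ``lam``.

    Returns (criterion, beta, sigma2_e, rss, logdetV).
    """
    n, p = X.shape
    G = starts.shape[0]
    Xt = X.copy()
    yt = y.copy()
    logdet = 0.0
    for g in range(G):
        s = starts[g]
        m = counts[g]
        f = 1.0 + lam * m
        logdet += np.log(f)
        theta = 1.0 - 1.0 / np.sqrt(f)
        if theta != 0.0:
            for j in range(p):
                mu = 0.0
                for i in range(s, s + m):
                    mu += Xt[i, j]
                mu /= m
                for i in range(s, s + m):
                    Xt[i, j] -= theta * mu
            mu = 0.0
            for i in range(s, s + m):
                mu += yt[i]
            mu /= m
            for i in range(s, s + m):
                yt[i] -= theta * mu
    A = Xt.T @ Xt
    b = Xt.T @ yt
    beta = np.linalg.solve(A, b)
    rss = 0.0
    for i in range(n):
        pred = 0.0
        for j in range(p):
            pred += Xt[i, j] * beta[j]
        d = yt[i] - pred
        rss += d * d
    if reml:
        dof = n - p
        sig2 = rss / dof
        sign, logdetA = np.linalg.slogdet(A)
        # profiled REML deviance: the p*log(sigma2) from log|X'V^-1 X| cancels
        # against n*log(sigma2) from log|V|, leaving (n-p)*log(2*pi*sigma2)
        crit = dof * np.log(2.0 * np.pi * sig2) + dof + logdet + logdetA
    else:
        sig2 = rss / n
        crit = n * np.log(2.0 * np.pi * sig2) + n + logdet
    return crit, beta, sig2, rss, logdet


@njit(cache=True)
def _fit_kernel(X, y, starts, counts, reml):
    """Grid scan + golden-section search over log(lambda).

    Returns (lam, crit) at the optimum.
    """
    n_grid = 21
    best_t = _LOG_LAM_LO
    best_c = 1e300
    step = (_LOG_LAM_HI - _LOG_LAM_LO) / (n_grid - 1)
    for k in range(n_grid):
        t = _LOG_LAM_LO + k * step
        c, _, _, _, _ = _crit_at(X, y, starts, counts, np.exp(t), reml)
        if c < best_c:
            best_c = c
            best_t = t
    # also consider the lambda = 0 boundary (plain OLS)
    c0, _, _, _, _ = _crit_at(X, y, starts, counts, 0.0, reml)
    lo = best_t - step
    hi = best_t + step
    invphi = 0.6180339887498949
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, _, _, _, _ = _crit_at(X, y, starts, counts, np.exp(x1), reml)
    f2, _, _, _, _ = _crit_at(X, y, starts, counts, np.exp(x2), reml)
    for _ in range(40):
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1, _, _, _, _ = _crit_at(X, y, starts, counts, np.exp(x1), reml)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2, _, _, _, _ = _crit_at(X, y, starts, counts, np.exp(x2), reml)
    t_opt = 0.5 * (a + b)
    lam = np.exp(t_opt)
    c_opt, _, _, _, _ = _crit_at(X, y, starts, counts, lam, reml)
    if c0 <= c_opt:
        return 0.0, c0
    return lam, c_opt


@njit(cache=True)
def _blups_from(X, y, starts, counts, beta, lam):
    """Empirical-Bayes random intercepts per group: lam*sum(resid)/(1+lam*m)."""
    G = starts.shape[0]
    p = X.shape[1]
    u = np.zeros(G)
    for g in range(G):
        s = starts[g]
        m = counts[g]
        ssum = 0.0
        for i in range(s, s + m):
            pred = 0.0
            for j in range(p):
                pred += X[i, j] * beta[j]
            ssum += y[i] - pred
        u[g] = lam * ssum / (1.0 + lam * m)
    return u


@njit(cache=True)
def _loocv_kernel(X, y, starts, counts, group_code):
    """Leave-one-row-out predictions with full ML refits.

    ``group_code`` maps each row to its group index (rows sorted by group).
    Prediction for the held-out row: fixed effects + the refit BLUP of its
    (still-seen) group.
    """
    n, p = X.shape
    G = starts.shape[0]
    preds = np.empty(n)
    Xs = np.empty((n - 1, p))
    ys = np.empty(n - 1)
    starts2 = np.empty(G, dtype=np.int64)
    counts2 = np.empty(G, dtype=np.int64)
    for i in range(n):
        k = 0
        for r in range(n):
            if r == i:
                continue
            for j in range(p):
                Xs[k, j] = X[r, j]
            ys[k] = y[r]
            k += 1
        gi = group_code[i]
        for g in range(G):
            counts2[g] = counts[g]
        counts2[gi] -= 1
        pos = 0
        for g in range(G):
            starts2[g] = pos
            pos += counts2[g]
        lam, _ = _fit_kernel(Xs, ys, starts2, counts2, False)
        _, beta, _, _, _ = _crit_at(Xs, ys, starts2, counts2, lam, False)
        u = _blups_from(Xs, ys, starts2, counts2, beta, lam)
        pred = u[gi]
        for j in range(p):
            pred += X[i, j] * beta[j]
        preds[i] = pred
    return preds


@njit(cache=True)
def _pearson(a, b):
    n = a.shape[0]
    ma = 0.0
    mb = 0.0
    for i in range(n):
        ma += a[i]
        mb += b[i]
    ma /= n
    mb /= n
    sab = 0.0
    saa = 0.0
    sbb = 0.0
    for i in range(n):
        da = a[i] - ma
        db = b[i] - mb
        sab += da * db
        saa += da * da
        sbb += db * db
    return sab / np.sqrt(saa * sbb)


@njit(cache=True)
def _perm_loocv_kernel(X, y, starts, counts, group_code, perm_idx):
    """LOOCV accuracy for each permuted outcome vector.

    ``perm_idx`` is (n_perm, n): each row permutes y across all rows.
    Returns the n_perm null accuracies (Pearson r of permuted-observed vs
    predicted from a full LOOCV rerun).
    """
    n_perm = perm_idx.shape[0]
    n = y.shape[0]
    acc = np.empty(n_perm)
    yp = np.empty(n)
    for q in range(n_perm):
        for i in range(n):
            yp[i] = y[perm_idx[q, i]]
        preds = _loocv_kernel(X, yp, starts, counts, group_code)
        acc[q] = _pearson(yp, preds)
    return acc


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    lam: float
    sigma2_e: float
    sigma2_u: float
    loglik: float
    aic: float
    method: str            # "ml" | "reml" | "ols"
    n_obs: int
    n_params: int          # count including variance components
    group_labels: list
    blups: dict
    df_resid: int

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def _sort_by_group(X, y, groups):
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.ascontiguousarray(np.asarray(y, dtype=np.float64))
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    ys = y[order]
    codes_s = codes[order]
    counts = np.bincount(codes_s, minlength=labels.size).astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int64)
    return Xs, ys, codes_s.astype(np.int64), starts, counts, labels, order


def _check_full_rank(X):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy scan
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                bad.append(j)
        raise np.linalg.LinAlgError(
            f"singular design: column(s) {bad} are collinear with the others")


def fit_lmm(X, y, groups, reml: bool = False) -> LMMFit:
    """Fit the random-intercept model (or OLS when only one group exists)."""
    Xs, ys, codes, starts, counts, labels, _ = _sort_by_group(X, y, groups)
    n, p = Xs.shape
    if n <= p:
        raise ValueError(f"n_obs = {n} too small for {p} fixed-effect columns")
    _check_full_rank(Xs)
    single_group = labels.size < 2

    if single_group:
        lam = 0.0
        crit_reml = reml
    else:
        lam, _ = _fit_kernel(Xs, ys, starts, counts, reml)
        crit_reml = reml
    crit, beta, sig2, rss, logdetV = _crit_at(Xs, ys, starts, counts, lam, crit_reml)

    # -0.5 * profiled criterion: the ML (or restricted) log-likelihood
    loglik = -0.5 * crit
    sigma2_u = lam * sig2

    # Wald covariance of beta: sig2 * (Xt'Xt)^-1 at the optimum
    Xt = _transform(Xs, starts, counts, lam)
    A = Xt.T @ Xt
    cov_beta = sig2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))

    if single_group:
        method = "ols"
        n_params = p + 1
        blup_arr = np.zeros(labels.size)
    else:
        method = "reml" if reml else "ml"
        n_params = p + 2
        blup_arr = _blups_from(Xs, ys, starts, counts, beta, lam)

    # AIC is only well defined across models under ML
    aic = 2.0 * n_params - 2.0 * loglik if not reml else float("nan")
    return LMMFit(
        beta=beta, se=se, cov_beta=cov_beta, lam=float(lam),
        sigma2_e=float(sig2), sigma2_u=float(sigma2_u), loglik=float(loglik),
        aic=float(aic), method=method, n_obs=n, n_params=n_params,
        group_labels=list(labels), blups=dict(zip(labels.tolist(), blup_arr)),
        df_resid=n - p,
    )


def _transform(X, starts, counts, lam):
    """Group-wise partial demeaning used by the GLS reduction."""
    Xt = X.copy()
    for g in range(starts.shape[0]):
        s, m = starts[g], counts[g]
        theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * m)
        if theta != 0.0:
            Xt[s:s + m] -= theta * X[s:s + m].mean(axis=0, keepdims=True)
    return Xt


def predict_lmm(fit: LMMFit, X_new, groups_new, use_blup: bool = True) -> np.ndarray:
    """Fixed-effect predictions, plus the group BLUP for seen groups."""
    X_new = np.asarray(X_new, dtype=np.float64)
    pred = X_new @ fit.beta
    if use_blup:
        for i, g in enumerate(np.asarray(groups_new)):
            pred[i] += fit.blups.get(g, 0.0)
    return pred


def loocv(X, y, groups) -> np.ndarray:
    """Leave-one-row-out ML predictions (full refit per fold).

    Predictions are returned in the original row order.
    """
    Xs, ys, codes, starts, counts, labels, order = _sort_by_group(X, y, groups)
    preds_sorted = _loocv_kernel(Xs, ys, starts, counts, codes)
    preds = np.empty_like(preds_sorted)
    preds[order] = preds_sorted
    return preds


def permuted_loocv_accuracies(X, y, groups, perm_idx) -> np.ndarray:
    """Null LOOCV accuracies: one full LOOCV rerun per permuted outcome.

    ``perm_idx`` is (n_perm, n) of row permutations in the ORIGINAL order.
    """
    Xs, ys, codes, starts, counts, labels, order = _sort_by_group(X, y, groups)
    # re-express permutations in sorted-row space: sorted row k holds original
    # row order[k]; permuted y_sorted[k] = y_original[perm[order[k]]] which is
    # sorted position inv_order[perm[order[k]]]
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(order.size)
    perm_idx = np.asarray(perm_idx, dtype=np.int64)
    perm_sorted = inv_order[perm_idx[:, order]]
    return _perm_loocv_kernel(Xs, ys, starts, counts, codes,
                              np.ascontiguousarray(perm_sorted))
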