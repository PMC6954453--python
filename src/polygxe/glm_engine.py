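"""Marginal and interaction generalized-linear-model scans over SNPs.

Two scans are provided:

* marginal:      g[E(Y)] = b0 + bG*G + bX'X            (screening / GRS-M weights)
* interaction:   g[E(Y)] = b0 + bG*G + bE*E + bGE*G*E + bX'X

For gaussian traits every SNP's fit is exact ordinary least squares,
computed for all SNPs at once by residualizing the SNP-specific columns on
the shared block (Frisch-Waugh); P-values use the t reference with the
residual degrees of freedom.  For binomial traits a batched
iteratively-reweighted-least-squares Newton solver fits all SNPs
simultaneously (tolerance 1e-8, max 50 iterations); P-values use the normal
(Wald) reference.  Non-converged, separated, or degenerate fits are flagged
``converged=False`` and excluded downstream, never silently imputed.

Subjects missing a SNP's genotype are dropped from that SNP's fit only
(complete-case per SNP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "MarginalScan",
    "InteractionScan",
    "fit_marginal_scan",
    "screen_snps",
    "fit_interaction_scan",
    "wald_test",
    "fit_glm",
]

_IRLS_TOL = 1e-8
_IRLS_MAXIT = 50
_ETA_CAP = 30.0
_BETA_CAP = 30.0  # |log-odds| beyond this signals separation


@dataclass
class MarginalScan:
    """Per-SNP marginal coefficient, SE, two-sided Wald P, convergence flag."""

    beta_g: np.ndarray
    se_g: np.ndarray
    p_g: np.ndarray
    converged: np.ndarray


@dataclass
class InteractionScan:
    """Per-SNP interaction coefficient, its variance, Wald P, convergence flag."""

    beta_ge: np.ndarray
    var_ge: np.ndarray
    p_ge: np.ndarray
    converged: np.ndarray


def wald_test(beta: float, se: float):
    """Wald z = beta/se and its two-sided normal P-value."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    return z, 2.0 * stats.norm.sf(abs(z))


def fit_glm(X: np.ndarray, y: np.ndarray, family: str):
    """Fit one GLM (identity-gaussian or logit-binomial) by least squares/IRLS.

    Returns ``(coef, cov, converged, df_resid)``.  Used for single-model fits
    such as the GRS interaction test; the scans below use batched versions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if family == "gaussian":
        A = X.T @ X
        if np.linalg.cond(A) > 1e10:
            return np.full(p, np.nan), np.full((p, p), np.nan), False, n - p
        coef = np.linalg.solve(A, X.T @ y)
        resid = y - X @ coef
        sigma2 = resid @ resid / (n - p)
        return coef, sigma2 * np.linalg.inv(A), True, n - p
    if family != "binomial":
        raise ValueError("family must be 'gaussian' or 'binomial'")
    coef = np.zeros(p)
    A0 = X.T @ X
    if np.linalg.cond(A0) > 1e10:
        return np.full(p, np.nan), np.full((p, p), np.nan), False, n - p
    converged = False
    A = A0
    for _ in range(_IRLS_MAXIT):
        eta = np.clip(X @ coef, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        A = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(A, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan), np.full((p, p), np.nan), False, n - p
        coef = coef + delta
        if np.max(np.abs(delta)) < _IRLS_TOL:
            converged = True
            break
    if not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > _BETA_CAP:
        converged = False
    cov = np.linalg.inv(A)
    return coef, cov, converged, n - p


def _residualizer(S: np.ndarray):
    Q, _ = np.linalg.qr(S)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    return resid


def _gaussian_marginal(y, S, G):
    """Exact OLS of y ~ S + g for every column g of G, via Frisch-Waugh."""
    n, q = S.shape
    resid = _residualizer(S)
    yt = resid(y)
    Gt = resid(G)
    den = np.einsum("nl,nl->l", Gt, Gt)
    df = n - q - 1
    ok = den > 1e-10 * n
    den_safe = np.where(ok, den, 1.0)
    beta = (Gt * yt[:, None]).sum(axis=0) / den_safe
    rss = yt @ yt - beta**2 * den_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / den_safe)
    ok &= se > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return _masked(beta, se, p, ok)


def _gaussian_interaction(y, S, G, E):
    """Exact OLS of y ~ S + g + g*E for every column g; S must contain E."""
    n, q = S.shape
    resid = _residualizer(S)
    yt = resid(y)
    T1 = resid(G)
    T2 = resid(G * E[:, None])
    a11 = np.einsum("nl,nl->l", T1, T1)
    a22 = np.einsum("nl,nl->l", T2, T2)
    a12 = np.einsum("nl,nl->l", T1, T2)
    b1 = T1.T @ yt
    b2 = T2.T @ yt
    det = a11 * a22 - a12**2
    scale = np.maximum(a11 * a22, 1e-30)
    ok = (a11 > 1e-10 * n) & (a22 > 1e-10 * n) & (det > 1e-10 * scale)
    det_safe = np.where(ok, det, 1.0)
    coef_g = (a22 * b1 - a12 * b2) / det_safe
    coef_ge = (a11 * b2 - a12 * b1) / det_safe
    df = n - q - 2
    rss = yt @ yt - (coef_g * b1 + coef_ge * b2)
    sigma2 = np.maximum(rss, 0.0) / df
    var_ge = sigma2 * a11 / det_safe
    ok &= var_ge > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef_ge / np.sqrt(var_ge)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    beta, se, p = _masked(coef_ge, np.sqrt(var_ge), p, ok)
    return beta, se**2, p, ok


def _masked(beta, se, p, ok):
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    p = np.where(ok, p, np.nan)
    return beta, se, p


def _batched_irls(y, S, T):
    """Batched logistic Newton solver for designs [S | T_l], l = 1..L.

    S is the shared (n, q) block; T is (n, L, r) of SNP-specific columns.
    Returns (coef_T_last, var_T_last, converged) for the *last* T column
    (the coefficient of interest is always placed last).
    """
    n, q = S.shape
    _, L, r = T.shape
    m = q + r
    # flag degenerate designs up front: zero-variance SNP-specific columns
    # or SNP columns collinear with the shared block / each other
    X0 = np.concatenate(
        [np.broadcast_to(S[:, None, :], (n, L, q)), T], axis=2
    )  # (n, L, m) -- views only for S
    A0 = np.einsum("nli,nlj->lij", X0, X0)
    ok = np.linalg.cond(A0) < 1e10
    bS = np.zeros((L, q))
    bT = np.zeros((L, r))
    active = ok.copy()
    A = np.tile(np.eye(m), (L, 1, 1))
    A[ok] = A0[ok]
    for _ in range(_IRLS_MAXIT):
        if not active.any():
            break
        eta = np.clip(S @ bS.T + np.einsum("nlr,lr->nl", T, bT), -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        w[:, ~active] = 0.0  # frozen SNPs contribute nothing
        Anew = np.einsum("nli,nl,nlj->lij", X0, w, X0)
        A[active] = Anew[active]
        resid = y[:, None] - mu
        gS = np.einsum("ni,nl->li", S, resid)
        gT = np.einsum("nlr,nl->lr", T, resid)
        grad = np.concatenate([gS, gT], axis=1)
        idx = np.nonzero(active)[0]
        try:
            delta = np.linalg.solve(A[idx], grad[idx][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(
                A[idx] + 1e-8 * np.eye(m), grad[idx][:, :, None]
            )[:, :, 0]
        bS[idx] += delta[:, :q]
        bT[idx] += delta[:, q:]
        done = np.max(np.abs(delta), axis=1) < _IRLS_TOL
        active[idx[done]] = False
    converged = ok & ~active
    finite = np.all(np.isfinite(bT), axis=1) & (np.max(np.abs(bT), axis=1) < _BETA_CAP)
    converged &= finite
    var_last = np.full(L, np.nan)
    if converged.any():
        cov = np.linalg.inv(A[converged])
        var_last[converged] = cov[:, m - 1, m - 1]
    converged &= np.nan_to_num(var_last) > 0
    return bT[:, -1], var_last, converged


def _complete_case_cols(dosages):
    """Indices of SNPs with at least one missing call."""
    return np.nonzero(np.isnan(dosages).any(axis=0))[0]


def fit_marginal_scan(g, s) -> MarginalScan:
    """Per-SNP marginal association scan: trait ~ intercept + SNP + covariates."""
    if not s.prepared:
        raise ValueError("SampleTable must be prepared before scanning")
    y, X = s.y, s.x
    n = y.shape[0]
    S = np.column_stack([np.ones(n), X])
    if n <= S.shape[1] + 2:
        raise ValueError("too few subjects for the marginal scan")
    D = g.dosages
    L = D.shape[1]
    has_nan = _complete_case_cols(D)
    Dc = D.copy()
    if has_nan.size:
        Dc[np.isnan(Dc)] = 0.0  # placeholder; these SNPs are refit below
    if s.y_family == "gaussian":
        beta, se, p = _gaussian_marginal(y, S, Dc)
        conv = ~np.isnan(beta)
    else:
        beta, var, conv = _batched_irls(y, S, Dc[:, :, None])
        se = np.sqrt(var)
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(beta / se))
        beta, se, p = _masked(beta, se, p, conv)
    for j in has_nan:
        keep = ~np.isnan(D[:, j])
        Xj = np.column_stack([S[keep], D[keep, j]])
        beta[j], se[j], p[j], conv[j] = _single_fit(
            Xj, y[keep], s.y_family, n_extra=1
        )
    return MarginalScan(beta, se, p, conv)


def fit_interaction_scan(g, s, subset=None) -> InteractionScan:
    """Per-SNP interaction scan: trait ~ intercept + SNP + E + SNP*E + covariates."""
    if not s.prepared:
        raise ValueError("SampleTable must be prepared before scanning")
    y, e, X = s.y, s.e, s.x
    n = y.shape[0]
    S = np.column_stack([np.ones(n), e, X])
    D = g.dosages if subset is None else g.dosages[:, np.asarray(subset)]
    has_nan = _complete_case_cols(D)
    Dc = D.copy()
    if has_nan.size:
        Dc[np.isnan(Dc)] = 0.0
    if s.y_family == "gaussian":
        beta, var, p, conv = _gaussian_interaction(y, S, Dc, e)
    else:
        T = np.stack([Dc, Dc * e[:, None]], axis=2)
        beta, var, conv = _batched_irls(y, S, T)
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(beta / np.sqrt(var)))
        beta, _, p = _masked(beta, np.sqrt(var), p, conv)
        var = np.where(conv, var, np.nan)
    for j in has_nan:
        keep = ~np.isnan(D[:, j])
        gj = D[keep, j]
        Xj = np.column_stack([S[keep], gj, gj * e[keep]])
        beta[j], sej, p[j], conv[j] = _single_fit(Xj, y[keep], s.y_family, n_extra=2)
        var[j] = sej**2
    return InteractionScan(beta, var, p, conv)


def _single_fit(Xj, y, family, n_extra):
    """Complete-case fit of one SNP's model; coefficient of interest is last."""
    coef, cov, converged, df = fit_glm(Xj, y, family)
    if not converged:
        return np.nan, np.nan, np.nan, False
    b = coef[-1]
    v = cov[-1, -1]
    if not v > 0:
        return np.nan, np.nan, np.nan, False
    se = np.sqrt(v)
    if family == "gaussian":
        p = 2.0 * stats.t.sf(abs(b / se), df)
    else:
        p = 2.0 * stats.norm.sf(abs(b / se))
    return b, se, p, True


def screen_snps(m: MarginalScan, alpha: float = 0.05) -> np.ndarray:
    """Indices of converged SNPs with marginal P strictly below ``alpha``."""
    with np.errstate(invalid="ignore"):
        keep = m.converged & (np.nan_to_num(m.p_g, nan=1.0) < alpha)
    return np.nonzero(keep)[0]
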