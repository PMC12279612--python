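"""Mixed-effects estimation internals.

Three estimators that the surrounding stack does not provide:

* :func:`fit_logit_gh` -- maximum likelihood for a logistic model with a
  single normal random intercept, integrating the likelihood per cluster
  by Gauss-Hermite quadrature.
* :func:`fit_multinomial_laplace` -- multinomial logit with crossed normal
  random intercepts for patients and physicians (shared across outcome
  categories), estimated by Laplace-approximate marginal likelihood with
  an inner Newton solve for the joint mode.
* :func:`fit_cox_frailty` -- Cox proportional hazards with crossed
  log-normal frailties for patients and physicians, via penalized Breslow
  partial likelihood (Ripatti-Palmgren style Laplace profile for the
  variance components).

These are written for the moderate problem sizes of the analysis pipeline
(dense linear algebra over fixed effects plus latent intercepts).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, expit
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["fit_logit_gh", "fit_multinomial_laplace", "fit_cox_frailty", "MixedFitResult"]


class MixedFitResult:
    """Lightweight result container shared by the mixed estimators."""

    def __init__(self, params, bse, loglik, nparams, vc, converged, method, extra=None):
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.loglik = float(loglik)
        self.nparams = int(nparams)
        self.vc = dict(vc)
        self.converged = bool(converged)
        self.method = method
        self.extra = extra or {}

    @property
    def aic(self) -> float:
        return 2 * self.nparams - 2 * self.loglik


# ---------------------------------------------------------------------------
# Random-intercept logistic via Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def fit_logit_gh(X, y, groups, n_quad: int = 21, start=None):
    """ML fit of ``logit P(y=1) = x'beta + u_g``, ``u_g ~ N(0, tau^2)``.

    ``groups`` are integer cluster codes.  Returns a
    :class:`MixedFitResult` whose params are ``(beta..., tau)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="mergesort")
    X, y, groups = X[order], y[order], groups[order]
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    s = 2.0 * y - 1.0

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    p = X.shape[1]
    cluster_of = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, len(y)]))

    def negll(params, want_grad=False):
        beta, tau = params[:p], abs(params[p])
        eta = X @ beta
        shift = np.sqrt(2.0) * tau * nodes  # (Q,)
        z = s[None, :] * (eta[None, :] + shift[:, None])
        row_ll = -np.logaddexp(0.0, -z)  # (Q, n): log sigma(s*(eta + a_q))
        cl = np.add.reduceat(row_ll, starts, axis=1) + log_w[:, None]  # (Q, C)
        tot = logsumexp(cl, axis=0)  # (C,)
        if not want_grad:
            return -float(tot.sum())
        # posterior node weights per cluster and the usual weighted score
        post = np.exp(cl - tot[None, :])  # (Q, C)
        resid = y[None, :] - expit(eta[None, :] + shift[:, None])  # (Q, n)
        wrow = post[:, cluster_of]  # (Q, n)
        wr = resid * wrow
        g_beta = X.T @ wr.sum(axis=0)
        g_tau = float((wr.sum(axis=1) * np.sqrt(2.0) * nodes).sum())
        g_tau *= np.sign(params[p]) if params[p] != 0 else 1.0
        return -float(tot.sum()), -np.r_[g_beta, g_tau]

    if start is None:
        # plain logistic start via a few Newton steps
        beta0 = np.zeros(p)
        for _ in range(25):
            mu = expit(X @ beta0)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            grad = X.T @ (y - mu)
            hess = (X * w[:, None]).T @ X
            step = np.linalg.solve(hess, grad)
            beta0 = beta0 + step
            if np.abs(step).max() < 1e-10:
                break
        start = np.r_[beta0, 0.5]

    res = minimize(lambda q: negll(q, want_grad=True), start, jac=True,
                   method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    if not res.success and res.fun > negll(start):
        res = minimize(negll, start, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
    params = res.x.copy()
    params[p] = abs(params[p])

    hess = approx_hess1(params, negll)
    try:
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p + 1, np.nan)
    return MixedFitResult(
        params=params,
        bse=bse,
        loglik=-res.fun,
        nparams=p + 1,
        vc={"tau2_physician": float(params[p] ** 2)},
        converged=bool(res.success or res.fun < np.inf),
        method="logit-GH",
    )


# ---------------------------------------------------------------------------
# Multinomial logit with crossed random intercepts (Laplace)
# ---------------------------------------------------------------------------

def _mnl_eta(X, B, u, w, pat, phys):
    return X @ B.T + (u[pat] + w[phys])[:, None]


def _mnl_ll_parts(X, ycode, B, u, w, pat, phys):
    """Log-likelihood, per-row probs and the scalar/vector weight sums."""
    eta = _mnl_eta(X, B, u, w, pat, phys)  # (n, m)
    m = eta.shape[1]
    a = np.maximum(eta.max(axis=1), 0.0)
    den = np.exp(-a) + np.exp(eta - a[:, None]).sum(axis=1)
    logden = a + np.log(den)
    probs = np.exp(eta - logden[:, None])  # (n, m)
    picked = np.where(ycode > 0, np.take_along_axis(
        eta, np.clip(ycode - 1, 0, m - 1)[:, None], axis=1).ravel(), 0.0)
    ll = float(picked.sum() - logden.sum())
    return ll, probs


def _mnl_newton(X, ycode, pat, phys, P, J, m, sig2, tau2, z0=None, max_iter=60):
    """Inner Newton solve for the penalized joint mode over (B, u, w)."""
    n, p = X.shape
    dim = m * p + P + J
    z = np.zeros(dim) if z0 is None else z0.copy()

    onehot = np.zeros((n, m))
    rows = np.flatnonzero(ycode > 0)
    onehot[rows, ycode[rows] - 1] = 1.0

    def unpack(z):
        B = z[: m * p].reshape(m, p)
        u = z[m * p: m * p + P]
        w = z[m * p + P:]
        return B, u, w

    def pen_ll(z):
        B, u, w = unpack(z)
        ll, _ = _mnl_ll_parts(X, ycode, B, u, w, pat, phys)
        return ll - 0.5 * (u @ u) / sig2 - 0.5 * (w @ w) / tau2

    f = pen_ll(z)
    for _ in range(max_iter):
        B, u, w = unpack(z)
        _, probs = _mnl_ll_parts(X, ycode, B, u, w, pat, phys)
        G = onehot - probs  # (n, m) gradient wrt eta
        # row-level weight aggregates: r_i[c] = sum_c' W_i[c,c'], t_i = sum r_i
        r = probs - probs * probs.sum(axis=1, keepdims=True)  # diag - p p' row sums
        # note: (diag(p) - p p')_cc' summed over c' = p_c - p_c * sum(p) = r above
        t = r.sum(axis=1)

        grad = np.empty(dim)
        for c in range(m):
            grad[c * p:(c + 1) * p] = X.T @ G[:, c]
        gu = np.bincount(pat, weights=G.sum(axis=1), minlength=P) - u / sig2
        gw = np.bincount(phys, weights=G.sum(axis=1), minlength=J) - w / tau2
        grad[m * p: m * p + P] = gu
        grad[m * p + P:] = gw

        H = np.zeros((dim, dim))
        for c in range(m):
            for c2 in range(c, m):
                if c == c2:
                    wcc = probs[:, c] * (1 - probs[:, c])
                else:
                    wcc = -probs[:, c] * probs[:, c2]
                block = (X * wcc[:, None]).T @ X
                H[c * p:(c + 1) * p, c2 * p:(c2 + 1) * p] = block
                if c2 != c:
                    H[c2 * p:(c2 + 1) * p, c * p:(c + 1) * p] = block.T
            xc = X * r[:, c][:, None]
            bu = np.vstack([np.bincount(pat, weights=xc[:, a], minlength=P)
                            for a in range(p)]).T  # (P, p)
            bw = np.vstack([np.bincount(phys, weights=xc[:, a], minlength=J)
                            for a in range(p)]).T
            H[m * p: m * p + P, c * p:(c + 1) * p] = bu
            H[c * p:(c + 1) * p, m * p: m * p + P] = bu.T
            H[m * p + P:, c * p:(c + 1) * p] = bw
            H[c * p:(c + 1) * p, m * p + P:] = bw.T
        huu = np.bincount(pat, weights=t, minlength=P)
        hww = np.bincount(phys, weights=t, minlength=J)
        H[m * p: m * p + P, m * p: m * p + P] = np.diag(huu + 1.0 / sig2)
        H[m * p + P:, m * p + P:] = np.diag(hww + 1.0 / tau2)
        # patient x physician co-occurrence
        cross = np.zeros((P, J))
        np.add.at(cross, (pat, phys), t)
        H[m * p: m * p + P, m * p + P:] = cross
        H[m * p + P:, m * p: m * p + P] = cross.T

        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(dim), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # line search on the penalized objective
        alpha, improved = 1.0, False
        for _ in range(30):
            z_new = z + alpha * step
            f_new = pen_ll(z_new)
            if f_new >= f - 1e-12:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        z, f_prev, f = z_new, f, f_new
        if np.abs(grad).max() < 1e-7 or abs(f - f_prev) < 1e-10 * (1 + abs(f)):
            # recompute grad next loop; stop when tiny
            if np.abs(grad).max() < 1e-5:
                break
    return z, f, H


def fit_multinomial_laplace(X, ycode, pat, phys, n_cat):
    """Laplace-approximate ML for a mixed multinomial logit.

    ``ycode`` uses 0 for the reference category and ``1..n_cat-1``
    otherwise; ``pat``/``phys`` are integer codes for the crossed random
    intercepts, which are shared across outcome categories.  Params are
    stacked per category: ``(beta_cat1..., beta_cat2..., sigma, tau)``.
    """
    X = np.asarray(X, dtype=float)
    ycode = np.asarray(ycode, dtype=int)
    pat = np.asarray(pat, dtype=int)
    phys = np.asarray(phys, dtype=int)
    m = n_cat - 1
    n, p = X.shape
    P, J = pat.max() + 1, phys.max() + 1

    state = {"z": None}

    def neg_marginal(log_vc):
        sig2, tau2 = np.exp(log_vc)
        z, f, H = _mnl_newton(X, ycode, pat, phys, P, J, m, sig2, tau2, z0=state["z"])
        state["z"] = z
        latent = H[m * p:, m * p:]
        sign, logdet = np.linalg.slogdet(latent)
        if sign <= 0:
            return np.inf
        lm = f - 0.5 * (P * np.log(sig2) + J * np.log(tau2)) - 0.5 * logdet
        return -lm

    res = minimize(neg_marginal, np.log([0.25, 0.25]), method="Nelder-Mead",
                   options={"maxiter": 60, "xatol": 1e-3, "fatol": 1e-6})
    sig2, tau2 = np.exp(np.clip(res.x, -12, 6))
    z, f, H = _mnl_newton(X, ycode, pat, phys, P, J, m, sig2, tau2, z0=state["z"])
    loglik = -neg_marginal(np.log([sig2, tau2]))

    nb = m * p
    try:
        cov_full = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
        bse = np.sqrt(np.clip(np.diag(cov_full)[:nb], 0, None))
        converged = True
    except np.linalg.LinAlgError:
        bse = np.full(nb, np.nan)
        converged = False
    return MixedFitResult(
        params=z[:nb],
        bse=bse,
        loglik=loglik,
        nparams=nb + 2,
        vc={"sigma2_patient": float(sig2), "tau2_physician": float(tau2)},
        converged=converged and res.fun < np.inf,
        method="multinomial-Laplace",
        extra={"u_patient": z[nb: nb + P], "u_physician": z[nb + P:]},
    )


# ---------------------------------------------------------------------------
# Cox frailty via penalized partial likelihood
# ---------------------------------------------------------------------------

def _breslow_parts(eta, time, event):
    """Breslow partial log-likelihood, gradient and Hessian wrt eta.

    Rows must be sorted by ascending time.  Returns (ll, grad, hess) with
    hess the *negative* second derivative (positive semi-definite).
    """
    n = len(eta)
    e = np.exp(eta - eta.max())
    # S(t_i) = sum of e over risk set {j: t_j >= t_i}; reverse cumulative sum
    rev = np.cumsum(e[::-1])[::-1]
    # map each row to the first index of its tied-time block
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if time[i] == time[i - 1] else i
    S = rev[first]  # risk-set sums per row (block-aligned)
    d_events = event.astype(float)
    # A_i = sum over event rows k with t_k <= t_i of 1/S_k; C_i similarly 1/S_k^2
    inc_a = d_events / S
    inc_c = d_events / S ** 2
    # events at the same time share a risk set; cumulative by block end
    cum_a = np.cumsum(inc_a)
    cum_c = np.cumsum(inc_c)
    last = np.zeros(n, dtype=int)
    last[-1] = n - 1
    for i in range(n - 2, -1, -1):
        last[i] = last[i + 1] if time[i] == time[i + 1] else i
    A = cum_a[last]
    C = cum_c[last]
    scale = eta.max()
    ll = float((eta * d_events).sum() - (d_events * (np.log(S) + scale)).sum())
    grad = d_events - e * A
    # hess = diag(e*A) - outer(e, e) * C[min(t_i, t_j)] ; C is nondecreasing
    hess = np.diag(e * A) - np.outer(e, e) * np.minimum.outer(C, C)
    return ll, grad, hess


def fit_cox_frailty(X, time, event, pat, phys, max_outer: int = 40):
    """Cox PH with crossed log-normal frailties by penalized Breslow PL.

    Params are the fixed-effect log hazard ratios.  Variance components
    are profiled out with a Laplace approximation of the integrated
    partial likelihood.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    pat = np.asarray(pat, dtype=int)
    phys = np.asarray(phys, dtype=int)
    order = np.argsort(time, kind="mergesort")
    X, time, event, pat, phys = X[order], time[order], event[order], pat[order], phys[order]

    n, p = X.shape
    P, J = pat.max() + 1, phys.max() + 1
    dim = p + P + J
    Zp = np.zeros((n, P)); Zp[np.arange(n), pat] = 1.0
    Zj = np.zeros((n, J)); Zj[np.arange(n), phys] = 1.0
    M = np.hstack([X, Zp, Zj])

    def pen_ll(z, sig2, tau2):
        ll, _, _ = _breslow_parts(M @ z, time, event)
        u, w = z[p: p + P], z[p + P:]
        return ll - 0.5 * (u @ u) / sig2 - 0.5 * (w @ w) / tau2

    def newton(sig2, tau2, z0=None):
        z = np.zeros(dim) if z0 is None else z0.copy()
        f = pen_ll(z, sig2, tau2)
        H_full = None
        for _ in range(50):
            eta = M @ z
            _, g_eta, h_eta = _breslow_parts(eta, time, event)
            grad = M.T @ g_eta
            grad[p: p + P] -= z[p: p + P] / sig2
            grad[p + P:] -= z[p + P:] / tau2
            H_full = M.T @ h_eta @ M
            idx = np.arange(p, p + P)
            H_full[idx, idx] += 1.0 / sig2
            idx = np.arange(p + P, dim)
            H_full[idx, idx] += 1.0 / tau2
            try:
                step = np.linalg.solve(H_full + 1e-9 * np.eye(dim), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H_full, grad, rcond=None)[0]
            alpha, improved = 1.0, False
            for _ in range(30):
                z_new = z + alpha * step
                f_new = pen_ll(z_new, sig2, tau2)
                if f_new >= f - 1e-12:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
            z, f = z_new, f_new
            if np.abs(grad).max() < 1e-6:
                break
        return z, f, H_full

    state = {"z": None}

    def neg_marginal(log_vc):
        sig2, tau2 = np.exp(log_vc)
        z, f, H = newton(sig2, tau2, state["z"])
        state["z"] = z
        latent = H[p:, p:]
        sign, logdet = np.linalg.slogdet(latent)
        if sign <= 0:
            return np.inf
        return -(f - 0.5 * (P * np.log(sig2) + J * np.log(tau2)) - 0.5 * logdet)

    res = minimize(neg_marginal, np.log([0.25, 0.25]), method="Nelder-Mead",
                   options={"maxiter": max_outer, "xatol": 1e-3, "fatol": 1e-6})
    sig2, tau2 = np.exp(np.clip(res.x, -12, 6))
    z, f, H = newton(sig2, tau2, state["z"])
    loglik = -neg_marginal(np.log([sig2, tau2]))

    try:
        cov_full = np.linalg.inv(H + 1e-9 * np.eye(dim))
        bse = np.sqrt(np.clip(np.diag(cov_full)[:p], 0, None))
        converged = np.isfinite(loglik)
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        converged = False
    return MixedFitResult(
        params=z[:p],
        bse=bse,
        loglik=loglik,
        nparams=p + 2,
        vc={"sigma2_patient": float(sig2), "tau2_physician": float(tau2)},
        converged=bool(converged),
        method="cox-frailty-PPL",
        extra={"u_patient": z[p: p + P], "u_physician": z[p + P:]},
    )
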