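"""Gamma log-link GLMM with crossed random intercepts (Laplace approximation).

The response is gamma distributed with shape ``nu`` and mean
``mu = exp(X beta + sum_k Z_k b_k)``; each grouping factor contributes
independent N(0, sigma_k^2) intercepts.  The marginal likelihood is
approximated by Laplace integration over the random effects:

    ll = l(y | b_hat) - 1/2 b_hat' D^-1 b_hat - 1/2 sum_k m_k log sigma_k^2
         - 1/2 log|Z'WZ + D^-1|

where ``b_hat`` maximises the penalised joint log-density (found by Newton
with step halving; ``W = diag(nu * y * exp(-eta))`` is the negative Hessian of
the gamma log-likelihood in eta).  The outer optimiser works over
``(log sigma_k^2 ..., log nu)`` with beta profiled out by the penalised
iteratively reweighted least squares step (joint Newton over beta and b);
beta is then polished by direct maximisation of the Laplace objective and its
covariance taken from the observed information in beta at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp
from scipy.special import gammaln

from .errors import NonPositiveResponseError


def _gamma_loglik(y: np.ndarray, eta: np.ndarray, nu: float) -> float:
    # log f = nu log nu - nu eta + (nu-1) log y - nu y e^-eta - lgamma(nu)
    return float(np.sum(
        nu * math.log(nu) - nu * eta + (nu - 1.0) * np.log(y)
        - nu * y * np.exp(-eta) - gammaln(nu)
    ))


@dataclass
class GLMMResult:
    """A fitted gamma log-link mixed model."""

    coef: np.ndarray
    coef_names: list[str]
    vcov: np.ndarray
    shape: float                     # gamma shape nu
    re_var: dict
    loglik: float                    # Laplace-approximate marginal ll
    aic: float
    k_params: int
    converged: bool
    n: int
    p: int
    factor_names: list[str] = field(default_factory=list)
    method: str = "Laplace"
    sigma2: float | None = None      # None: no additive residual variance

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Contrast d.f.; the gamma fit uses the asymptotic normal reference."""
        return float("inf")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted means (response scale); strictly positive by construction."""
        return np.exp(np.asarray(X) @ self.coef)


def _make_z(codes, sizes, n):
    offsets = np.cumsum([0, *sizes])
    q = offsets[-1]
    if q == 0:
        return sp.csr_matrix((0, n)), q, offsets
    rows = np.concatenate([c + off for c, off in zip(codes, offsets[:-1])])
    cols = np.tile(np.arange(n), len(sizes))
    Z = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(q, n))
    return Z, q, offsets


def _inner_mode(X, y, Z, d_inv_rep, nu, beta, b, solve_beta: bool,
                max_iter: int = 80, tol: float = 1e-9):
    """Newton for the penalised joint density over (beta, b) or b alone."""
    n, p = X.shape
    q = Z.shape[0]
    if q == 0 and not solve_beta:
        eta = np.clip(X @ beta, -500.0, 500.0)
        return beta, b, _gamma_loglik(y, eta, nu)
    Zd = Z.toarray() if q else np.zeros((0, n))

    def eta_of(beta, b):
        e = X @ beta
        if q:
            e = e + Zd.T @ b
        return np.clip(e, -500.0, 500.0)

    def objective(beta, b):
        pen = 0.5 * float(b @ (d_inv_rep * b)) if q else 0.0
        return _gamma_loglik(y, eta_of(beta, b), nu) - pen

    f = objective(beta, b)
    for it in range(max_iter):
        eta = eta_of(beta, b)
        mu_ratio = y * np.exp(-eta)            # y / mu
        u = nu * (mu_ratio - 1.0)              # d ll / d eta
        w = nu * mu_ratio                      # -d2 ll / d eta2  (> 0)
        if solve_beta:
            g = np.concatenate([X.T @ u, (Zd @ u) - d_inv_rep * b]) if q else X.T @ u
            XtWX = X.T @ (w[:, None] * X)
            if q:
                XtWZ = X.T @ (w[:, None] * Zd.T)
                ZtWZ = (Zd * w) @ Zd.T + np.diag(d_inv_rep)
                H = np.block([[XtWX, XtWZ], [XtWZ.T, ZtWZ]])
            else:
                H = XtWX
        else:
            g = (Zd @ u) - d_inv_rep * b
            H = (Zd * w) @ Zd.T + np.diag(d_inv_rep)
        if np.max(np.abs(g)) < tol * (1.0 + abs(f)):
            break
        try:
            with warnings.catch_warnings():
                # near-boundary variance parameters make H poorly scaled;
                # the step-halving line search below guards the step itself
                warnings.simplefilter("ignore", sla.LinAlgWarning)
                step = sla.solve(H, g, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            if solve_beta:
                nb = beta + t * step[:p]
                nbb = b + t * step[p:] if q else b
            else:
                nb, nbb = beta, b + t * step
            nf = objective(nb, nbb)
            if nf >= f - 1e-12:
                break
            t *= 0.5
        beta, b, f = nb, nbb, nf
    return beta, b, f


def _laplace_loglik(X, y, Z, sizes, offsets, sig2, nu, beta, b, solve_beta):
    q = Z.shape[0]
    d_inv_rep = np.repeat(1.0 / np.maximum(sig2, 1e-12), sizes) if q else np.empty(0)
    beta, b, _ = _inner_mode(X, y, Z, d_inv_rep, nu, beta, b, solve_beta=solve_beta)
    eta = np.clip(X @ beta + (Z.T @ b if q else 0.0), -500.0, 500.0)
    ll = _gamma_loglik(y, eta, nu)
    if q:
        ll -= 0.5 * float(b @ (d_inv_rep * b))
        ll -= 0.5 * float(np.dot(sizes, np.log(np.maximum(sig2, 1e-12))))
        w = nu * y * np.exp(-eta)
        Zd = Z.toarray()
        H = (Zd * w) @ Zd.T + np.diag(d_inv_rep)
        sign, logdet = np.linalg.slogdet(H)
        ll -= 0.5 * logdet
    return ll, beta, b


def fit_glmm_gamma_core(
    X: np.ndarray,
    y: np.ndarray,
    codes: Sequence[np.ndarray],
    sizes: Sequence[int],
    coef_names: Sequence[str] | None = None,
    factor_names: Sequence[str] | None = None,
) -> GLMMResult:
    """Laplace fit of the gamma log-link mixed model."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise NonPositiveResponseError("gamma family requires y > 0")
    n, p = X.shape
    Z, q, offsets = _make_z(codes, sizes, n)
    k = len(sizes)

    # starting values from OLS on log y
    logy = np.log(y)
    beta0 = np.linalg.lstsq(X, logy, rcond=None)[0]
    resid = logy - X @ beta0
    v = float(np.var(resid)) or 0.5
    nu0 = max(0.2, min(50.0, 1.5 / v))
    state = {"beta": beta0.copy(), "b": np.zeros(q)}

    def negll(params):
        sig2 = np.exp(np.clip(params[:k], -20, 20))
        nu = float(np.exp(np.clip(params[k], -6, 8)))
        ll, beta, b = _laplace_loglik(
            X, y, Z, sizes, offsets, sig2, nu,
            state["beta"], state["b"], solve_beta=True,
        )
        state["beta"], state["b"] = beta, b
        return -ll

    x0 = np.concatenate([np.full(k, math.log(max(0.05, v / 2))), [math.log(nu0)]])
    res = opt.minimize(negll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 600 * (k + 1), "maxfev": 600 * (k + 1)})
    sig2 = np.exp(np.clip(res.x[:k], -20, 20))
    nu = float(np.exp(np.clip(res.x[k], -6, 8)))
    converged = bool(res.success)
    if not converged:
        warnings.warn("gamma GLMM outer optimiser did not report convergence",
                      stacklevel=2)

    # polish beta at fixed (sig2, nu) by direct Laplace maximisation over beta
    def neg_beta(beta):
        ll, _, b = _laplace_loglik(X, y, Z, sizes, offsets, sig2, nu,
                                   beta, state["b"], solve_beta=False)
        state["b"] = b
        return -ll

    pres = opt.minimize(neg_beta, state["beta"], method="BFGS",
                        options={"gtol": 1e-7, "maxiter": 200})
    beta = pres.x
    ll_final, _, _ = _laplace_loglik(X, y, Z, sizes, offsets, sig2, nu,
                                     beta, state["b"], solve_beta=False)

    # coefficient covariance from the joint observed information at the mode
    # (the beta block of the inverse of the full (beta, b) Hessian, i.e.
    # conditional on the estimated variance parameters)
    b_hat = state["b"]
    eta = np.clip(X @ beta + (Z.T @ b_hat if q else 0.0), -500.0, 500.0)
    w = nu * y * np.exp(-eta)
    XtWX = X.T @ (w[:, None] * X)
    if q:
        Zd = Z.toarray()
        d_inv_rep = np.repeat(1.0 / np.maximum(sig2, 1e-12), sizes)
        XtWZ = X.T @ (w[:, None] * Zd.T)
        ZtWZ = (Zd * w) @ Zd.T + np.diag(d_inv_rep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sla.LinAlgWarning)
            info = XtWX - XtWZ @ sla.solve(ZtWZ, XtWZ.T, assume_a="pos")
    else:
        info = XtWX
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)

    k_params = p + k + 1
    fnames = list(factor_names) if factor_names is not None else [f"f{i}" for i in range(k)]
    return GLMMResult(
        coef=beta,
        coef_names=list(coef_names) if coef_names is not None else [f"x{i}" for i in range(p)],
        vcov=vcov,
        shape=nu,
        re_var={name: float(s) for name, s in zip(fnames, sig2)},
        loglik=float(ll_final),
        aic=float(2 * k_params - 2 * ll_final),
        k_params=k_params,
        converged=converged,
        n=n, p=p,
        factor_names=fnames,
    )
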