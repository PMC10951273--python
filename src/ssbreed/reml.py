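"""Restricted maximum likelihood for linear mixed models.

Two solvers share one ascent scheme (average-information updates with an
EM-REML fallback and step halving, so the restricted log-likelihood never
decreases across accepted iterations):

* :func:`reml_factor` — crossed i.i.d. random factors (y = Xb + sum Z_k u_k + e
  with u_k ~ N(0, s2_k I)).  Works in the q-dimensional random-effect space via
  the Woodbury identity, so replicated trials with a few hundred hybrids fit in
  well under a second per iteration.
* :func:`reml_dense` — random terms with an arbitrary covariance kernel
  (y = Xb + u + e, u ~ N(0, sum s2_k K_k)).  Operates on the n x n marginal
  covariance; intended for the modest n of EMM-level analyses.

Both floor variances at (effectively) zero and report the asymptotic
variance-covariance of the estimates from the inverse average-information
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = ["RemlResult", "reml_factor", "reml_dense"]

_TOL = 1e-8
_MAXIT = 200


@dataclass
class RemlResult:
    """Variance components and fixed effects from a REML fit."""

    varcomps: dict[str, float]
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int
    ai_inv: np.ndarray | None = None
    names: list[str] = field(default_factory=list)
    # hooks for Satterthwaite df: d/ds2_k of X'V^-1X at the optimum
    grad_mats: dict[str, np.ndarray] = field(default_factory=dict)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Approximate denominator df for the contrast c'beta."""
        c = np.asarray(c, dtype=float)
        phi = float(c @ self.cov_beta @ c)
        if self.ai_inv is None or not self.grad_mats:
            return float("inf")
        bc = self.cov_beta @ c
        g = np.array([float(bc @ self.grad_mats[k] @ bc) for k in self.names])
        var_phi = float(g @ self.ai_inv @ g)
        if var_phi <= 0:
            return float("inf")
        return 2.0 * phi * phi / var_phi


def _ascend(compute, theta0, floor, tol=_TOL, maxit=_MAXIT):
    """Shared AI/EM ascent. ``compute(theta)`` returns
    (loglik, score, AI, q_eff) with q_eff the per-component EM divisors."""
    theta = np.maximum(np.asarray(theta0, dtype=float), floor)
    ll, score, ai, q_eff = compute(theta)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        directions = []
        try:
            directions.append(np.linalg.solve(ai, score))
        except np.linalg.LinAlgError:
            pass
        directions.append(2.0 * theta**2 * score / q_eff)  # EM-REML step
        norm = np.linalg.norm(score)
        if norm > 0:
            directions.append(score / norm * np.max(np.abs(theta)) * 0.1)
        accepted = False
        for d in directions:
            step = 1.0
            for _ in range(16):
                cand = np.maximum(theta + step * d, floor)
                ll2, s2, ai2, q2 = compute(cand)
                if np.isfinite(ll2) and ll2 >= ll - 1e-12 * (1 + abs(ll)):
                    moved = not np.allclose(cand, theta)
                    theta, score, ai, q_eff = cand, s2, ai2, q2
                    if ll2 - ll < tol * (1.0 + abs(ll)) and moved:
                        converged = True
                    ll = ll2
                    accepted = moved
                    break
                step *= 0.5
            if accepted or converged:
                break
        history.append(ll)
        if converged or not accepted:
            converged = True
            break
    return theta, ll, history, converged, it, ai


def _snap(theta, floor):
    out = theta.copy()
    out[out <= 2.0 * floor] = 0.0
    return out


def reml_factor(y, X, factors: dict[str, np.ndarray], tol=_TOL, maxit=_MAXIT) -> RemlResult:
    """REML for crossed i.i.d. random factors plus a residual.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (full column rank)
    factors : mapping name -> (n, q_k) design matrix of an i.i.d. random factor
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    names = list(factors) + ["residual"]
    Zs = [np.asarray(factors[k], dtype=float) for k in factors]
    if n <= p:
        raise ValueError("not enough observations to estimate variance components")
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response has zero variance")
    floor = max(1e-8 * vy, 1e-12)

    U = np.hstack(Zs) if Zs else np.zeros((n, 0))
    q = U.shape[1]
    qs = [Z.shape[1] for Z in Zs]
    blocks = np.cumsum([0] + qs)
    C = U.T @ U
    UtX, Uty = U.T @ X, U.T @ y
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def compute(theta):
        sig, se = theta[:-1], theta[-1]
        Dvec = np.repeat(sig, qs) if q else np.zeros(0)
        M = C + np.diag(se / Dvec) if q else np.zeros((0, 0))
        try:
            cM = cho_factor(M) if q else None
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        MiUtX = cho_solve(cM, UtX) if q else np.zeros((0, p))
        MiUty = cho_solve(cM, Uty) if q else np.zeros(0)
        XtVinvX = (XtX - UtX.T @ MiUtX) / se
        XtVinvy = (Xty - UtX.T @ MiUty) / se
        ytVinvy = (yty - Uty @ MiUty) / se
        try:
            cB = cho_factor(XtVinvX)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        beta = cho_solve(cB, XtVinvy)
        ytPy = ytVinvy - float(XtVinvy @ beta)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cM[0])))) if q else 0.0
        logdetV = (n - q) * np.log(se) + float(np.sum(np.array(qs) * np.log(sig))) + logdetM
        sgn, logdetB = np.linalg.slogdet(XtVinvX)
        if sgn <= 0:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        ll = -0.5 * (logdetV + logdetB + ytPy)

        Vinv_y = (y - U @ MiUty) / se
        Vinv_X = (X - U @ MiUtX) / se
        Py = Vinv_y - Vinv_X @ beta

        def apply_P(h):
            Uth = U.T @ h
            Vh = (h - U @ cho_solve(cM, Uth)) / se if q else h / se
            return Vh - Vinv_X @ cho_solve(cB, X.T @ Vh)

        hs = []
        trPG = []
        for k, Z in enumerate(Zs):
            blk = slice(blocks[k], blocks[k + 1])
            B_k = C[:, blk]
            MiB = cho_solve(cM, B_k)
            trVinvG = (float(np.trace(C[blk, blk])) - float(np.sum(MiB * B_k))) / se
            F_k = (UtX[blk].T - UtX.T @ MiB) / se  # p x q_k
            trPG.append(trVinvG - float(np.sum(cho_solve(cB, F_k) * F_k)))
            hs.append(Z @ (Z.T @ Py))
        # residual
        trVinv = (n - float(np.trace(cho_solve(cM, C)))) / se if q else n / se
        XtV2X = Vinv_X.T @ Vinv_X
        trPG.append(trVinv - float(np.trace(cho_solve(cB, XtV2X))))
        hs.append(Py)

        score = np.array([0.5 * (float(Py @ h) - t) for h, t in zip(hs, trPG)])
        Ph = [apply_P(h) for h in hs]
        K = len(hs)
        AI = np.empty((K, K))
        for a in range(K):
            for b in range(a, K):
                AI[a, b] = AI[b, a] = 0.5 * float(hs[a] @ Ph[b])
        q_eff = np.array([*qs, n], dtype=float)
        return ll, score, AI, q_eff

    theta0 = np.full(len(names), vy / len(names))
    theta, ll, history, conv, it, ai = _ascend(compute, theta0, floor, tol, maxit)

    # final pass for fixed effects and Satterthwaite hooks
    sig, se = theta[:-1], theta[-1]
    Dvec = np.repeat(sig, qs) if q else np.zeros(0)
    M = C + np.diag(se / Dvec) if q else np.zeros((0, 0))
    cM = cho_factor(M) if q else None
    MiUtX = cho_solve(cM, UtX) if q else np.zeros((0, p))
    MiUty = cho_solve(cM, Uty) if q else np.zeros(0)
    XtVinvX = (XtX - UtX.T @ MiUtX) / se
    XtVinvy = (Xty - UtX.T @ MiUty) / se
    cov_beta = np.linalg.inv(XtVinvX)
    beta = cov_beta @ XtVinvy
    Vinv_X = (X - U @ MiUtX) / se
    grad_mats = {}
    for k in range(len(Zs)):
        blk = slice(blocks[k], blocks[k + 1])
        B_k = C[:, blk]
        F_k = (UtX[blk].T - UtX.T @ cho_solve(cM, B_k)) / se
        grad_mats[names[k]] = F_k @ F_k.T
    grad_mats["residual"] = Vinv_X.T @ Vinv_X

    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_inv = None
    theta_out = _snap(theta, floor)
    return RemlResult(dict(zip(names, theta_out)), beta, cov_beta, ll, history,
                      conv, it, ai_inv, names, grad_mats)


def reml_dense(y, X, kernels: dict[str, np.ndarray], tol=_TOL, maxit=_MAXIT) -> RemlResult:
    """REML with explicit n x n covariance kernels plus an i.i.d. residual.

    ``kernels`` maps component name -> PSD matrix K_k; the marginal covariance
    is V = sum s2_k K_k + s2_e I.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    names = list(kernels) + ["residual"]
    Gs = [np.asarray(kernels[k], dtype=float) for k in kernels] + [np.eye(n)]
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response has zero variance")
    floor = max(1e-8 * vy, 1e-12)
    # scale starting values by mean diagonal so kernels on different scales start sanely
    diag_means = np.array([max(np.mean(np.diag(G)), 1e-12) for G in Gs])

    def compute(theta):
        V = np.zeros((n, n))
        for t, G in zip(theta, Gs):
            V += t * G
        try:
            cV = cho_factor(V)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        Vinv = cho_solve(cV, np.eye(n))
        Vinv_X = Vinv @ X
        XtVinvX = X.T @ Vinv_X
        try:
            cB = cho_factor(XtVinvX)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        Vinv_y = Vinv @ y
        beta = cho_solve(cB, X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ beta
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cV[0]))))
        sgn, logdetB = np.linalg.slogdet(XtVinvX)
        if sgn <= 0:
            return -np.inf, np.zeros(len(theta)), np.eye(len(theta)), np.ones(len(theta))
        ll = -0.5 * (logdetV + logdetB + float(y @ Py))
        P = Vinv - Vinv_X @ cho_solve(cB, Vinv_X.T)
        hs = [G @ Py for G in Gs]
        score = np.array([0.5 * (float(Py @ h) - float(np.sum(P * G)))
                          for h, G in zip(hs, Gs)])
        K = len(Gs)
        Ph = [P @ h for h in hs]
        AI = np.empty((K, K))
        for a in range(K):
            for b in range(a, K):
                AI[a, b] = AI[b, a] = 0.5 * float(hs[a] @ Ph[b])
        q_eff = np.full(K, float(n))
        return ll, score, AI, q_eff

    theta0 = vy / len(Gs) / diag_means
    theta, ll, history, conv, it, ai = _ascend(compute, theta0, floor, tol, maxit)

    V = np.zeros((n, n))
    for t, G in zip(theta, Gs):
        V += t * G
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    cov_beta = np.linalg.inv(XtVinvX)
    beta = cov_beta @ (X.T @ (Vinv @ y))
    grad_mats = {nm: X.T @ Vinv @ G @ Vinv @ X for nm, G in zip(names, Gs)}
    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_inv = None
    theta_out = _snap(theta, floor)
    return RemlResult(dict(zip(names, theta_out)), beta, cov_beta, ll, history,
                      conv, it, ai_inv, names, grad_mats)
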