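"""Multistate free-energy estimators: MBAR and (two-state) BAR.

The MBAR equations are solved by minimising the convex objective

    kappa(f) = sum_n ln sum_k N_k exp(f_k - u_{kn}) - sum_k N_k f_k

(whose stationary point is the self-consistent MBAR solution), followed by
self-consistent polish iterations to tight tolerance.  The asymptotic
covariance of the dimensionless free energies uses the SVD form of the
weight-matrix estimator.  BAR is implemented independently (a bracketed root
solve of the Bennett implicit equation) so the two can cross-check each other
on two-state problems.

Inputs are reduced potentials: u_kn[k, n] = beta * U_k(x_n), with samples n
pooled over all states and N_k samples drawn from state k.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

__all__ = ["mbar_solve", "mbar_free_energy", "bar_free_energy"]


def _validate(u_kn: np.ndarray, n_k: np.ndarray):
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=int)
    if u_kn.ndim != 2:
        raise ValueError("u_kn must be a (n_states, n_samples) matrix")
    K, N = u_kn.shape
    if n_k.shape != (K,) or n_k.sum() != N or np.any(n_k < 0):
        raise ValueError("n_k must hold per-state sample counts summing to n_samples")
    if K < 2:
        raise ValueError("need at least two states")
    return u_kn, n_k


def mbar_solve(
    u_kn: np.ndarray,
    n_k: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the MBAR equations.

    Returns ``(f_k, theta)``: dimensionless free energies (f_0 = 0) and their
    asymptotic covariance matrix.  ``tol`` is the self-consistency tolerance
    on max |delta f|.
    """
    u_kn, n_k = _validate(u_kn, n_k)
    K, N = u_kn.shape
    active = n_k > 0
    log_n = np.where(active, np.log(np.where(n_k > 0, n_k, 1)), -np.inf)

    # numerical conditioning: remove the per-sample minimum
    shift = u_kn.min(axis=0)
    u = u_kn - shift[None, :]

    def objective(f):
        # kappa(f)/N plus gradient
        a = f[:, None] + log_n[:, None] - u  # (K, N)
        lse = logsumexp(a, axis=0)
        g = np.exp(a - lse[None, :]).sum(axis=1) - n_k
        return lse.sum() - float(n_k @ f), g

    f0 = np.zeros(K)
    res = minimize(objective, f0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter})
    f = res.x
    # self-consistent polish: f_k <- -ln sum_n exp(-u_kn - ln D_n)
    for _ in range(max_iter):
        log_denom = logsumexp(f[:, None] + log_n[:, None] - u, axis=0)  # (N,)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError("MBAR self-consistent iteration did not converge")

    # asymptotic covariance via the SVD form of Theta
    log_denom = logsumexp(f[:, None] + log_n[:, None] - u, axis=0)
    logw = f[:, None] - u - log_denom[None, :]  # (K, N)
    W = np.exp(logw).T  # (N, K)
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    inner = np.eye(K) - (S[:, None] * (V.T @ (n_k[:, None] * V)) * S[None, :])
    theta = V @ np.diag(S) @ np.linalg.pinv(inner, rcond=1e-10) @ np.diag(S) @ V.T
    return f, theta


def mbar_free_energy(
    u_kn: np.ndarray, n_k: np.ndarray, kT: float = 1.0, tol: float = 1e-10
) -> tuple[float, float]:
    """Free-energy difference f(last state) - f(first state).

    Returns ``(dG, dG_err)`` in units of ``kT`` (pass the thermal energy in
    kcal/mol to get kcal/mol); the error is the asymptotic standard error.
    """
    f, theta = mbar_solve(u_kn, n_k, tol=tol)
    var = theta[0, 0] + theta[-1, -1] - 2 * theta[0, -1]
    if not np.isfinite(var) or var > 25.0 or _min_adjacent_overlap(u_kn, n_k, f) < 1e-6:
        warnings.warn(
            "poor phase-space overlap between adjacent windows; the free-energy "
            "uncertainty estimate is unreliable (divergent)",
            UserWarning,
            stacklevel=2,
        )
    return kT * float(f[-1] - f[0]), kT * float(np.sqrt(max(var, 0.0)))


def _min_adjacent_overlap(u_kn, n_k, f) -> float:
    """Smallest adjacent-window entry of the MBAR overlap matrix
    O = W^T diag(N) W (rows sum to 1); ~0 means disconnected windows."""
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    shift = u_kn.min(axis=0)
    log_n = np.where(n_k > 0, np.log(np.where(n_k > 0, n_k, 1)), -np.inf)
    log_denom = logsumexp(f[:, None] + log_n[:, None] - (u_kn - shift), axis=0)
    logw = f[:, None] - (u_kn - shift) - log_denom[None, :]  # (K, N)
    W = np.exp(logw)
    O = n_k[:, None] * (W @ W.T)  # O_kl = N_k sum_n W_nk W_nl
    off = np.diagonal(O, offset=1)
    return float(off.min()) if len(off) else 1.0


def _fermi(x):
    # overflow-safe logistic 1/(1+e^x)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_free_energy(
    w_forward: np.ndarray, w_reverse: np.ndarray, kT: float = 1.0
) -> float:
    """Bennett acceptance ratio estimate of f_1 - f_0.

    ``w_forward``: reduced work u_1(x) - u_0(x) on samples from state 0;
    ``w_reverse``: reduced work u_0(x) - u_1(x) on samples from state 1.
    Solved by bracketed root finding on the Bennett implicit equation,
    independently of the MBAR path.
    """
    w_f = np.asarray(w_forward, dtype=float)
    w_r = np.asarray(w_reverse, dtype=float)
    if len(w_f) == 0 or len(w_r) == 0:
        raise ValueError("need samples from both end states")
    m = np.log(len(w_f) / len(w_r))

    def g(df):
        return _fermi(m + w_f - df).sum() - _fermi(-m + w_r + df).sum()

    lo = min(-w_r.max(), w_f.min()) - 50.0
    hi = max(w_f.max(), -w_r.min()) + 50.0
    return kT * brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
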