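"""Gaussian-process machinery for short allele-frequency time series.

Covariance model
----------------
The latent trajectory f(t) gets a squared-exponential (SE) kernel

    K_SE(t, t') = sf2 * exp(-(t - t')^2 / (2 l^2)),

observation noise is white with variance sn2, and each observation carries a
known extra variance (the beta-binomial posterior variance, "FBB"), so the
full covariance of the centered observations is

    C = K_SE(t, t) + sn2 * I + diag(fbb).

The log marginal likelihood (LML)

    log p(y) = -1/2 y' C^{-1} y - 1/2 log|C| - J/2 log(2*pi)

is evaluated through a Cholesky factorization, never an explicit inverse.
Hyperparameters are optimized in log space (positivity for free) with
analytic gradients, starting from the best point of a scale-free grid.

Numerical policy: if a Cholesky fails, jitter of 1e-8 * mean(diag) is added
to the diagonal and escalated tenfold up to 1e-2 * mean(diag) before the fit
is flagged as failed (a per-SNP failure, never an exception that kills a
genome-wide run).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .types import GPFit

__all__ = [
    "GPNumericalError",
    "se_covariance",
    "assemble_covariance",
    "log_marginal_likelihood",
    "gp_predict",
    "fit_se_model",
    "fit_noise_model",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: smallest admissible variance parameter; keeps log-space optimization finite
VAR_FLOOR = 1e-12

_JITTER_START = 1e-8
_JITTER_MAX = 1e-2


class GPNumericalError(RuntimeError):
    """Covariance not positive definite even after maximal jitter."""


def se_covariance(t, t_prime, length_scale: float, signal_variance: float):
    """Squared-exponential kernel matrix between two sets of time points."""
    if length_scale <= 0:
        raise ValueError(f"length scale must be positive, got {length_scale}")
    if signal_variance < 0:
        raise ValueError("signal variance must be non-negative")
    t = np.asarray(t, dtype=float).ravel()
    tp = np.asarray(t_prime, dtype=float).ravel()
    d = t[:, None] - tp[None, :]
    return signal_variance * np.exp(-(d * d) / (2.0 * length_scale**2))


def assemble_covariance(t, kernel, noise_variance: float, fbb):
    """Full observation covariance K_SE + sn2*I + diag(fbb).

    ``kernel`` is an ``(length_scale, signal_variance)`` pair, or ``None``
    for the time-independent model (no SE term).
    """
    t = np.asarray(t, dtype=float).ravel()
    fbb = np.asarray(fbb, dtype=float).ravel()
    if fbb.size != t.size:
        raise ValueError(
            f"fbb length {fbb.size} does not match {t.size} time points"
        )
    if np.any(fbb < 0):
        raise ValueError("fbb variances must be non-negative")
    if kernel is None:
        C = np.zeros((t.size, t.size))
    else:
        length_scale, signal_variance = kernel
        C = se_covariance(t, t, length_scale, signal_variance)
    idx = np.diag_indices_from(C)
    C[idx] += noise_variance + fbb
    return C


def _chol_with_jitter(C: np.ndarray):
    """Cholesky factor of C, escalating diagonal jitter on failure."""
    try:
        return np.linalg.cholesky(C), 0.0
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(C)))
    if scale <= 0:
        scale = 1.0
    jitter = _JITTER_START
    while jitter <= _JITTER_MAX:
        try:
            L = np.linalg.cholesky(C + jitter * scale * np.eye(C.shape[0]))
            return L, jitter * scale
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise GPNumericalError("covariance not positive definite after maximal jitter")


def log_marginal_likelihood(y_centered, C) -> float:
    """Gaussian log marginal likelihood via Cholesky factorization."""
    y = np.asarray(y_centered, dtype=float).ravel()
    C = np.asarray(C, dtype=float)
    if y.size != C.shape[0]:
        raise ValueError("observation vector does not match covariance dimension")
    L, _ = _chol_with_jitter(C)
    alpha = solve_triangular(L, y, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * alpha @ alpha - 0.5 * logdet - 0.5 * y.size * LOG2PI)


def gp_predict(t_star, t, y_centered, kernel, C):
    """Posterior mean and covariance of f at new time points t_star.

    Standard conditional-Gaussian formulas: m* = K*' C^{-1} y and
    S* = K** - K*' C^{-1} K*. Used for visualizing fitted trajectories.
    """
    length_scale, signal_variance = kernel
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y_centered, dtype=float).ravel()
    Ks = se_covariance(t_star, t, length_scale, signal_variance)
    Kss = se_covariance(t_star, t_star, length_scale, signal_variance)
    cf = cho_factor(np.asarray(C, dtype=float), lower=True)
    mean = Ks @ cho_solve(cf, y)
    cov = Kss - Ks @ cho_solve(cf, Ks.T)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


# ---------------------------------------------------------------------------
# hyperparameter optimization


def _nll_grad_se(log_params, t, y, fbb, d2):
    """Negative LML and gradient w.r.t. (log l, log sf2, log sn2)."""
    log_l, log_sf2, log_sn2 = log_params
    ell = np.exp(log_l)
    sf2 = np.exp(log_sf2)
    sn2 = np.exp(log_sn2)
    K = sf2 * np.exp(-d2 / (2.0 * ell * ell))
    C = K.copy()
    idx = np.diag_indices_from(C)
    C[idx] += sn2 + fbb
    try:
        L, _ = _chol_with_jitter(C)
    except GPNumericalError:
        return np.inf, np.zeros(3)
    a = cho_solve((L, True), y)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    nll = 0.5 * y @ a + 0.5 * logdet + 0.5 * y.size * LOG2PI
    # dLML/dtheta = 1/2 tr((a a' - C^{-1}) dC/dtheta)
    Cinv = cho_solve((L, True), np.eye(y.size))
    W = np.outer(a, a) - Cinv
    dK_dlogl = K * d2 / (ell * ell)
    grad = -0.5 * np.array(
        [
            np.sum(W * dK_dlogl),
            np.sum(W * K),  # dC/dlog sf2 = K
            sn2 * np.trace(W),  # dC/dlog sn2 = sn2 I
        ]
    )
    return float(nll), grad


def _nll_grad_diag(log_sn2, y, fbb):
    """Negative LML and gradient for the diagonal (time-independent) model."""
    sn2 = np.exp(log_sn2[0] if np.ndim(log_sn2) else log_sn2)
    v = sn2 + fbb
    nll = 0.5 * float(np.sum(np.log(2.0 * np.pi * v) + y * y / v))
    # d(-LML)/dlog sn2 = sn2/2 * sum(1/v - y^2/v^2)
    grad = 0.5 * sn2 * float(np.sum(1.0 / v - y * y / (v * v)))
    return nll, np.array([grad])


def _diag_log_ml(y, fbb, sn2):
    v = sn2 + fbb
    return -0.5 * float(np.sum(np.log(2.0 * np.pi * v) + y * y / v))


def length_scale_bounds(t) -> tuple[float, float]:
    """[shortest spacing between distinct time points, 10 * span].

    The lower bound guards against overfitting wiggly trajectories between
    samples; replicates at identical generations do not define a zero
    spacing. The upper bound caps runaway flat directions (beyond ~span the
    SE kernel is already effectively constant).
    """
    tu = np.unique(np.asarray(t, dtype=float))
    if tu.size < 2:
        raise ValueError("need at least two distinct time points")
    lo = float(np.min(np.diff(tu)))
    span = float(tu[-1] - tu[0])
    return lo, 10.0 * span


def fit_se_model(
    t,
    y_centered,
    fbb,
    extra_inits: list[tuple[float, float, float]] | None = None,
) -> GPFit:
    """Fit (l, sf2, sn2) of the SE + white + FBB model by maximum LML.

    Protocol: evaluate the LML on a scale-free grid, start a gradient-based
    local refinement (L-BFGS-B in log space) from the best grid point, and
    return whichever of the two is better. ``extra_inits`` adds candidate
    (l, sf2, sn2) triples to the grid — used to embed the time-independent
    optimum (sf2 at its floor) so the nested-model bound holds exactly.
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y_centered, dtype=float).ravel()
    fbb = np.asarray(fbb, dtype=float).ravel()
    l_lo, l_hi = length_scale_bounds(t)
    span = float(np.max(t) - np.min(t))
    var = float(np.var(y))
    var = max(var, VAR_FLOOR)

    l_grid = np.clip([span / 8, span / 4, span / 2, span, 2 * span], l_lo, l_hi)
    sf2_grid = np.clip([0.1 * var, var, 10 * var], VAR_FLOOR, None)
    sn2_grid = np.clip([0.01 * var, 0.1 * var, var], VAR_FLOOR, None)

    d = t[:, None] - t[None, :]
    d2 = d * d

    cands = [
        (li, si, ni)
        for li in np.unique(l_grid)
        for si in np.unique(sf2_grid)
        for ni in np.unique(sn2_grid)
    ]
    if extra_inits:
        cands += [
            (min(max(li, l_lo), l_hi), max(si, VAR_FLOOR), max(ni, VAR_FLOOR))
            for (li, si, ni) in extra_inits
        ]

    best_nll = np.inf
    best_p = None
    for li, si, ni in cands:
        lp = np.log([li, si, ni])
        nll, _ = _nll_grad_se(lp, t, y, fbb, d2)
        if nll < best_nll:
            best_nll = nll
            best_p = lp
    if best_p is None or not np.isfinite(best_nll):
        return GPFit(
            log_ml=-np.inf, noise_variance=np.nan, converged=False,
            n_restarts_used=len(cands),
        )

    bounds = [
        (np.log(l_lo), np.log(l_hi)),
        (np.log(VAR_FLOOR), np.log(1e2)),
        (np.log(VAR_FLOOR), np.log(1e2)),
    ]
    best_p = np.clip(best_p, [b[0] for b in bounds], [b[1] for b in bounds])
    res = minimize(
        _nll_grad_se,
        best_p,
        args=(t, y, fbb, d2),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )
    converged = bool(res.success)
    if np.isfinite(res.fun) and res.fun < best_nll:
        sol, nll = res.x, float(res.fun)
    else:  # optimizer diverged: fall back to the best grid value
        sol, nll = best_p, float(best_nll)
    ell, sf2, sn2 = np.exp(sol)
    return GPFit(
        log_ml=-nll,
        length_scale=float(ell),
        signal_variance=float(sf2),
        noise_variance=float(sn2),
        converged=converged,
        n_restarts_used=len(cands),
    )


def fit_noise_model(y_centered, fbb) -> GPFit:
    """Fit the single noise variance of the time-independent model.

    Covariance is diagonal (sn2 + fbb_j), so this is a 1-D maximization.
    Besides the grid, the closed-form stationary point mean(y^2 - fbb) is
    used as a candidate start.
    """
    y = np.asarray(y_centered, dtype=float).ravel()
    fbb = np.asarray(fbb, dtype=float).ravel()
    var = max(float(np.var(y)), VAR_FLOOR)
    moment = float(np.mean(y * y - fbb))
    starts = np.log(
        np.clip([0.01 * var, 0.1 * var, var, moment], VAR_FLOOR, 1e2)
    )
    best_nll, best_x = np.inf, None
    for s in np.unique(starts):
        nll, _ = _nll_grad_diag(s, y, fbb)
        if nll < best_nll:
            best_nll, best_x = nll, s
    res = minimize(
        _nll_grad_diag,
        np.array([best_x]),
        args=(y, fbb),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(VAR_FLOOR), np.log(1e2))],
    )
    if np.isfinite(res.fun) and res.fun < best_nll:
        sn2 = float(np.exp(res.x[0]))
        log_ml = -float(res.fun)
    else:
        sn2 = float(np.exp(best_x))
        log_ml = -float(best_nll)
    return GPFit(
        log_ml=log_ml,
        noise_variance=sn2,
        converged=bool(res.success),
        n_restarts_used=starts.size,
    )
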