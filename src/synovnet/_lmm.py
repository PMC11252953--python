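"""Random-intercept linear mixed model helpers.

statsmodels' MixedLM provides REML estimates but no small-sample degrees
of freedom. For the single-random-intercept models used here, the
per-subject covariance is compound-symmetric, V_s = σ²_e·I + σ²_u·J, which
admits closed-form inverses and determinants. This module evaluates the
restricted log-likelihood surface and contrast variances on that closed
form and derives Satterthwaite degrees of freedom by the standard
delta-method recipe: df = 2·g² / (∇g' · Var(θ̂) · ∇g), with Var(θ̂) the
inverse of the (finite-difference) REML information at the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TINY = 1e-10


@dataclass
class LMMData:
    """Sufficient statistics of a subject-grouped design, precomputed once.

    Rows must be sorted so each subject's rows are contiguous; ``sizes``
    gives the per-subject block lengths in that order.
    """

    xtx: np.ndarray          # X'X, k×k
    xty: np.ndarray          # X'y, k
    yty: float
    sx: np.ndarray           # per-subject column sums of X, n_subj×k
    sy: np.ndarray           # per-subject sums of y, n_subj
    sizes: np.ndarray        # per-subject block sizes, n_subj
    n_obs: int
    k: int


def prepare(X: np.ndarray, y: np.ndarray, subject: np.ndarray) -> LMMData:
    """Accumulate the per-subject sufficient statistics for `X`, `y`."""
    order = np.argsort(subject, kind="stable")
    X = np.asarray(X, dtype=float)[order]
    y = np.asarray(y, dtype=float)[order]
    subj = np.asarray(subject)[order]
    _, starts = np.unique(subj, return_index=True)
    starts = np.sort(starts)
    bounds = np.append(starts, len(y))
    sizes = np.diff(bounds)
    sx = np.add.reduceat(X, starts, axis=0)
    sy = np.add.reduceat(y, starts)
    return LMMData(
        xtx=X.T @ X,
        xty=X.T @ y,
        yty=float(y @ y),
        sx=sx,
        sy=sy,
        sizes=sizes,
        n_obs=len(y),
        k=X.shape[1],
    )


def _gls_mats(data: LMMData, su2: float, se2: float):
    """X'V⁻¹X, X'V⁻¹y, y'V⁻¹y and log|V| under compound symmetry."""
    se2 = max(se2, _TINY)
    su2 = max(su2, 0.0)
    c = su2 / (se2 + data.sizes * su2)  # per-subject shrinkage factor
    xtvx = (data.xtx - data.sx.T @ (c[:, None] * data.sx)) / se2
    xtvy = (data.xty - data.sx.T @ (c * data.sy)) / se2
    ytvy = (data.yty - float(c @ data.sy**2)) / se2
    logdet_v = float(
        (data.sizes - 1) @ np.full_like(c, np.log(se2))
        + np.log(se2 + data.sizes * su2).sum()
    )
    return xtvx, xtvy, ytvy, logdet_v


def reml_loglike(data: LMMData, su2: float, se2: float) -> float:
    """Restricted log-likelihood (up to an additive constant)."""
    xtvx, xtvy, ytvy, logdet_v = _gls_mats(data, su2, se2)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - float(xtvy @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy)


def contrast_variance(
    data: LMMData, su2: float, se2: float, c: np.ndarray
) -> float:
    """g(θ) = c'(X'V⁻¹X)⁻¹c for a fixed-effect contrast vector `c`."""
    xtvx, _, _, _ = _gls_mats(data, su2, se2)
    return float(c @ np.linalg.solve(xtvx, c))


def gls_fit(data: LMMData, su2: float, se2: float) -> np.ndarray:
    """GLS fixed-effect estimates at variance components (su2, se2)."""
    xtvx, xtvy, _, _ = _gls_mats(data, su2, se2)
    return np.linalg.solve(xtvx, xtvy)


def satterthwaite_df(
    data: LMMData,
    su2: float,
    se2: float,
    c: np.ndarray,
    fallback: float,
) -> float:
    """Satterthwaite degrees of freedom for one contrast.

    Finite-difference gradient of g(θ) and Hessian of the REML
    log-likelihood on the variance scale; falls back to ``fallback``
    (residual df) when the information matrix is not positive definite,
    e.g. at a boundary estimate.
    """
    theta = np.array([max(su2, 0.0), max(se2, _TINY)])
    h = np.maximum(1e-5, 1e-4 * theta)

    def g(t):
        return contrast_variance(data, t[0], t[1], c)

    def ll(t):
        if t[0] < 0 or t[1] <= 0:
            return -np.inf
        return reml_loglike(data, t[0], t[1])

    grad = np.zeros(2)
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 0.0 if i == 0 else _TINY)
        grad[i] = (g(tp) - g(tm)) / (tp[i] - tm[i])

    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[i] += h[i]; tpp[j] += h[j]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp[i] -= h[i]; tmp[j] += h[j]
            tmm[i] -= h[i]; tmm[j] -= h[j]
            for t in (tpm, tmp, tmm):
                t[0] = max(t[0], 0.0)
                t[1] = max(t[1], _TINY)
            hess[i, j] = hess[j, i] = (
                ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)
            ) / (4 * h[i] * h[j])

    try:
        var_theta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return fallback
    if not np.all(np.isfinite(var_theta)) or np.any(np.diag(var_theta) <= 0):
        return fallback
    denom = float(grad @ var_theta @ grad)
    if denom <= 0:
        return fallback
    df = 2.0 * g(theta) ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        return fallback
    return float(min(df, fallback))
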