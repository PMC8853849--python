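"""Kernel-based regularized least squares (KRLS) with marginal-effect inference.

Gaussian-kernel ridge regression on standardized predictors and outcome:

    y = K c,   c = (K + lambda I)^-1 y,   K_ij = exp(-||x_i - x_j||^2 / sigma^2)

The regularization parameter is chosen by minimizing the sum of squared
leave-one-out errors, available in closed form from one eigendecomposition
of K.  Because the fitted surface is a kernel expansion, its partial
derivative with respect to each predictor is available pointwise; the
average marginal effect (AME) — the sample mean of the pointwise
derivative, or of the 0/1 first difference for binary predictors — plays
the role of a regression coefficient while the surface itself is free to be
nonlinear.  Every pointwise effect is linear in the coefficient vector c,
so AME standard errors follow from the coefficient covariance
``sigma_e^2 (K + lambda I)^-2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

__all__ = [
    "KRLSFit",
    "build_kernel",
    "solve_coefficients",
    "loo_errors",
    "select_lambda_loocv",
    "krls_fit",
    "pointwise_derivatives",
    "average_marginal_effects",
]


@dataclass
class KRLSFit:
    """State of a solved KRLS model (standardization constants retained)."""

    x_std: np.ndarray  # n x D standardized design
    y_std: np.ndarray  # n standardized outcome
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    bandwidth: float  # sigma^2
    lam: float
    coefficients: np.ndarray
    fitted: np.ndarray  # standardized scale
    residual_variance: float  # df-adjusted, standardized scale
    eigvals: np.ndarray
    eigvecs: np.ndarray
    kernel: np.ndarray
    sqdist: np.ndarray
    binary_flags: np.ndarray
    column_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.x_std.shape[0]

    @property
    def d(self) -> int:
        return self.x_std.shape[1]

    def r_squared(self) -> float:
        return 1.0 - float(np.mean((self.y_std - self.fitted) ** 2)) / float(
            np.mean(self.y_std**2)
        )


def _squared_distances(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def build_kernel(
    x_std: np.ndarray, bandwidth: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian kernel matrix and its eigendecomposition.

    ``bandwidth`` is sigma^2; the default is D, the number of predictor
    columns, which keeps typical standardized squared distances on the scale
    of the exponent.  Returns (K, eigvals, eigvecs, sqdist).
    """
    x = np.asarray(x_std, dtype=float)
    if not np.isfinite(x).all():
        bad = np.flatnonzero(~np.isfinite(x).all(axis=0))
        raise ValueError(f"non-finite entries in predictor column(s) {bad.tolist()}")
    if bandwidth is None:
        bandwidth = float(x.shape[1])
    if bandwidth <= 0:
        raise ValueError("bandwidth (sigma^2) must be positive")
    d2 = _squared_distances(x)
    k = np.exp(-d2 / bandwidth)
    np.fill_diagonal(k, 1.0)
    w, v = np.linalg.eigh(k)
    w = np.clip(w, 0.0, None)  # Gaussian kernel is PSD; clip rounding noise
    return k, w, v, d2


def solve_coefficients(
    eigvals: np.ndarray, eigvecs: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """c = (K + lam I)^-1 y and fitted = K c via the cached eigendecomposition."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    q = eigvecs.T @ y
    c = eigvecs @ (q / (eigvals + lam))
    fitted = eigvecs @ (eigvals * q / (eigvals + lam))
    return c, fitted


def loo_errors(
    eigvals: np.ndarray, eigvecs: np.ndarray, y: np.ndarray, lam: float
) -> np.ndarray:
    """Closed-form leave-one-out residuals: e_i = c_i / [(K + lam I)^-1]_ii."""
    q = eigvecs.T @ y
    c = eigvecs @ (q / (eigvals + lam))
    ginv_diag = (eigvecs**2 @ (1.0 / (eigvals + lam)))
    return c / ginv_diag


def select_lambda_loocv(
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    y: np.ndarray,
    search_bounds: tuple[float, float] = (1e-3, 1e3),
    expand: bool = True,
    max_expansions: int = 3,
) -> float:
    """Regularization parameter minimizing the sum of squared LOO errors.

    Brent search on log(lambda) within ``search_bounds``; when the minimizer
    lands at a bound and ``expand`` is set, the bracket is widened (x100,
    up to ``max_expansions`` times) before giving up at the bound.
    """
    lo, hi = search_bounds
    if lo <= 0 or hi <= lo:
        raise ValueError("search bounds must satisfy 0 < lo < hi")
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        warnings.warn("degenerate (constant) outcome; LOO objective is flat")
        return float(np.exp((np.log(lo) + np.log(hi)) / 2))

    def objective(loglam: float) -> float:
        return float(np.sum(loo_errors(eigvals, eigvecs, y, np.exp(loglam)) ** 2))

    for _ in range(max_expansions + 1):
        res = optimize.minimize_scalar(
            objective, bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-6},
        )
        loglam = float(res.x)
        span = np.log(hi) - np.log(lo)
        at_lo = loglam - np.log(lo) < 0.02 * span
        at_hi = np.log(hi) - loglam < 0.02 * span
        if not expand or not (at_lo or at_hi):
            break
        if at_lo:
            lo /= 100.0
        if at_hi:
            hi *= 100.0
    return float(np.exp(loglam))


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant predictor column(s) {bad.tolist()}; drop them first")
    return (x - mean) / sd, mean, sd


def krls_fit(
    x,
    y,
    bandwidth: float | None = None,
    lam: float | None = None,
    binary_flags=None,
    search_bounds: tuple[float, float] = (1e-3, 1e3),
) -> KRLSFit:
    """Standardize, build the kernel, select lambda by LOO CV and solve.

    ``binary_flags`` marks predictors whose marginal effect should be the
    0-to-1 first difference rather than the derivative; by default columns
    with exactly two distinct raw values are flagged.
    """
    if isinstance(x, pd.DataFrame):
        names = [str(c) for c in x.columns]
        x_raw = x.to_numpy(dtype=float)
    else:
        x_raw = np.asarray(x, dtype=float)
        names = [f"x{j + 1}" for j in range(x_raw.shape[1])]
    y_raw = np.asarray(pd.Series(y).to_numpy(), dtype=float).ravel()
    if x_raw.shape[0] != y_raw.shape[0]:
        raise ValueError("x and y disagree on sample size")
    if binary_flags is None:
        binary_flags = np.array([np.unique(x_raw[:, j]).size == 2 for j in range(x_raw.shape[1])])
    else:
        binary_flags = np.asarray(binary_flags, dtype=bool)
    x_std, x_mean, x_sd = _standardize_columns(x_raw)
    y_sd = y_raw.std()
    y_mean = y_raw.mean()
    y_std = (y_raw - y_mean) / (y_sd if y_sd > 0 else 1.0)
    if bandwidth is None:
        bandwidth = float(x_std.shape[1])
    k, w, v, d2 = build_kernel(x_std, bandwidth)
    if lam is None:
        lam = select_lambda_loocv(w, v, y_std, search_bounds=search_bounds)
    c, fitted = solve_coefficients(w, v, y_std, lam)
    n = len(y_std)
    edf = float(np.sum(w / (w + lam)))  # effective model degrees of freedom
    rss = float(np.sum((y_std - fitted) ** 2))
    dof = max(n - edf, 1.0)
    return KRLSFit(
        x_std=x_std,
        y_std=y_std,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=float(y_mean),
        y_sd=float(y_sd if y_sd > 0 else 1.0),
        bandwidth=float(bandwidth),
        lam=float(lam),
        coefficients=c,
        fitted=fitted,
        residual_variance=rss / dof,
        eigvals=w,
        eigvecs=v,
        kernel=k,
        sqdist=d2,
        binary_flags=binary_flags,
        column_names=names,
    )


def _binary_diff_matrix(fit: KRLSFit, d: int) -> np.ndarray:
    """M = K(x with column d at raw 1) - K(x with column d at raw 0), so that
    the per-subject first difference is (M c)_i.  Uses the cached squared
    distances, updating only the d-th coordinate's contribution."""
    xd = fit.x_std[:, d]
    z1 = (1.0 - fit.x_mean[d]) / fit.x_sd[d]
    z0 = (0.0 - fit.x_mean[d]) / fit.x_sd[d]
    base = fit.sqdist - (xd[:, None] - xd[None, :]) ** 2
    k1 = np.exp(-(base + (z1 - xd[None, :]) ** 2) / fit.bandwidth)
    k0 = np.exp(-(base + (z0 - xd[None, :]) ** 2) / fit.bandwidth)
    return k1 - k0


def _effect_stats(fit: KRLSFit, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise effects and the column sums of the linear map M^(d)
    (where pointwise = M^(d) c), computing any first-difference kernel once."""
    if fit.binary_flags[d]:
        m = _binary_diff_matrix(fit, d)
        return m @ fit.coefficients, m.sum(axis=0)
    xd = fit.x_std[:, d]
    kc = fit.kernel @ fit.coefficients
    pointwise = -(2.0 / fit.bandwidth) * (xd * kc - fit.kernel @ (fit.coefficients * xd))
    k1 = fit.kernel.sum(axis=0)
    colsums = -(2.0 / fit.bandwidth) * (fit.kernel @ xd - xd * k1)
    return pointwise, colsums


def pointwise_derivatives(fit: KRLSFit) -> np.ndarray:
    """n x D matrix of pointwise effects on the standardized scale.

    Continuous predictors: the analytic derivative of the kernel expansion,
    d yhat_i / d x_id = -(2/sigma^2) sum_j c_j (x_id - x_jd) K_ij.
    Binary-flagged predictors: the fitted first difference between raw
    levels 1 and 0 (per raw unit, in standardized-outcome units).
    """
    n, dd = fit.x_std.shape
    out = np.empty((n, dd))
    for d in range(dd):
        out[:, d] = _effect_stats(fit, d)[0]
    return out


def average_marginal_effects(
    fit: KRLSFit, derivatives: np.ndarray | None = None
) -> pd.DataFrame:
    """AME table: estimate, SE, t and two-sided p per predictor.

    ``estimate`` is on the original data scale (outcome units per predictor
    unit; for binary predictors, per 0-to-1 change); ``estimate_std`` is on
    the standardized scale.  Var(AME_d) = n^-2 v' V(c) v with v the column
    sums of the pointwise-effect map and V(c) = sigma_e^2 (K + lam I)^-2;
    p-values use the standard normal reference.  A degenerate predictor with
    zero SE yields NaN SE/t/p.
    """
    n, dd = fit.x_std.shape
    rows = []
    for d in range(dd):
        pointwise, v = _effect_stats(fit, d)
        if derivatives is not None:
            pointwise = derivatives[:, d]
        est_std = float(pointwise.mean())
        q = fit.eigvecs.T @ v
        var = fit.residual_variance / n**2 * float(np.sum(q**2 / (fit.eigvals + fit.lam) ** 2))
        se_std = np.sqrt(var) if var > 0 else 0.0
        if fit.binary_flags[d]:
            scale = fit.y_sd  # per raw 0->1 change
        else:
            scale = fit.y_sd / fit.x_sd[d]
        if se_std > 0:
            t = est_std / se_std
            p = 2.0 * (1.0 - ndtr(abs(t)))
        else:
            t = np.nan
            p = np.nan
        rows.append(
            {
                "predictor": fit.column_names[d],
                "estimate": est_std * scale,
                "se": se_std * scale,
                "estimate_std": est_std,
                "se_std": se_std if se_std > 0 else np.nan,
                "t": t,
                "p": p,
                "binary": bool(fit.binary_flags[d]),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
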