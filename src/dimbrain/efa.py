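"""Exploratory factor analysis of ordinal items via polychoric correlation.

Pipeline: (1) polychoric correlation matrix of the ordinal items under the
latent bivariate-normal model, estimated by the two-step method (thresholds
from inverse-normal marginal proportions, correlation by maximizing the
contingency-table likelihood); (2) Horn's parallel analysis to choose the
number of factors; (3) principal-component extraction from the polychoric
matrix; (4) oblique geomin rotation by gradient projection, allowing the
factors to correlate; (5) regression-method factor scores.

The bivariate normal rectangle probabilities at the heart of the polychoric
likelihood are evaluated in closed form through Owen's T function, which
keeps the full 119-item matrix (7021 pairs) tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import owens_t, ndtr, ndtri

from .ica import correlate_dimension_scores, match_components

__all__ = [
    "PolychoricMatrix",
    "FactorSolution",
    "bvn_cdf",
    "estimate_polychoric_pair",
    "polychoric_matrix",
    "parallel_analysis",
    "extract_pca_loadings",
    "extract_paf_loadings",
    "default_geomin_epsilon",
    "geomin_criterion",
    "geomin_rotate",
    "factor_scores",
    "correlate_factor_scores",
    "run_efa",
    "loading_report",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen 1956 closed form)

def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized over h and k (rho scalar); supports +/- infinity in h, k.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    rho = np.clip(rho, -0.9999999, 0.9999999)
    out = np.empty(h.shape, dtype=float)

    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    finite = ~(neg_inf | h_inf | k_inf)

    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = ndtr(np.where(k_inf, np.inf, k))[h_inf & ~neg_inf]
    out[k_inf & ~neg_inf & ~h_inf] = ndtr(h)[k_inf & ~neg_inf & ~h_inf]

    if np.any(finite):
        hf = h[finite]
        kf = k[finite]
        # nudge exact zeros; the CDF is continuous so the bias is O(1e-13)
        hf = np.where(hf == 0.0, 1e-13, hf)
        kf = np.where(kf == 0.0, 1e-13, kf)
        d = np.sqrt(1.0 - rho * rho)
        with np.errstate(divide="ignore", over="ignore"):
            a_h = (kf - rho * hf) / (hf * d)
            a_k = (hf - rho * kf) / (kf * d)
        beta = np.where(hf * kf > 0, 0.0, 0.5)
        out[finite] = (
            0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - beta
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# polychoric correlation

@dataclass
class PolychoricMatrix:
    """Polychoric correlation matrix with per-item thresholds."""

    matrix: pd.DataFrame
    thresholds: dict[str, np.ndarray]
    smoothing_applied: bool = False

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy()


def _marginal_thresholds(codes: np.ndarray, n_cats: int) -> np.ndarray:
    cum = np.cumsum(np.bincount(codes, minlength=n_cats))[:-1] / codes.size
    return ndtri(cum)


def _rectangle_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate([[-np.inf], tau_x, [np.inf]])
    ay = np.concatenate([[-np.inf], tau_y, [np.inf]])
    cdf = bvn_cdf(ax[:, None], ay[None, :], rho)
    return np.diff(np.diff(cdf, axis=0), axis=1)


def _table_nll(table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> float:
    p = np.clip(_rectangle_probs(tau_x, tau_y, rho), 1e-12, None)
    return -float(np.sum(table * np.log(p)))


def _encode_ordinal(v: np.ndarray, name: str = "vector") -> np.ndarray:
    vals, codes = np.unique(v, return_inverse=True)
    if vals.size < 2:
        raise ValueError(f"{name} is constant; polychoric correlation undefined")
    if vals.size != int(vals.max() - vals.min() + 1):
        warnings.warn(f"{name}: zero-margin categories collapsed")
    return codes


def estimate_polychoric_pair(x, y) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds are fixed at the inverse-normal transform of the cumulative
    marginal proportions; the correlation maximizes the contingency-table
    log-likelihood with bivariate-normal rectangle cell probabilities, by
    bounded scalar search over (-0.999, 0.999).

    Returns ``(rho, thresholds_x, thresholds_y)``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    cx = _encode_ordinal(x, "x")
    cy = _encode_ordinal(y, "y")
    tau_x = _marginal_thresholds(cx, cx.max() + 1)
    tau_y = _marginal_thresholds(cy, cy.max() + 1)
    table = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(table, (cx, cy), 1.0)
    res = optimize.minimize_scalar(
        lambda r: _table_nll(table, tau_x, tau_y, r),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), tau_x, tau_y


def _smooth_to_psd(r: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    w = np.clip(w, eig_floor, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


def polychoric_matrix(ratings, pairwise_complete: bool = False) -> PolychoricMatrix:
    """Estimate the full polychoric correlation matrix of an item table.

    If the raw pairwise-estimated matrix has negative eigenvalues it is
    smoothed by eigenvalue clipping at 1e-6 followed by rescaling to unit
    diagonal (``smoothing_applied`` is set).
    """
    df = pd.DataFrame(ratings)
    if df.isna().any().any() and not pairwise_complete:
        raise ValueError("missing values present; set pairwise_complete=True or impute")
    items = list(df.columns)
    p = len(items)
    r = np.eye(p)
    thresholds: dict[str, np.ndarray] = {}
    cols = [df[c].to_numpy() for c in items]
    for i in range(p):
        for j in range(i + 1, p):
            xi, yj = cols[i], cols[j]
            if pairwise_complete:
                ok = ~(pd.isna(xi) | pd.isna(yj))
                xi, yj = xi[ok], yj[ok]
            try:
                rho, tx, ty = estimate_polychoric_pair(xi, yj)
            except ValueError as e:
                raise ValueError(
                    f"polychoric estimation failed for pair ({items[i]!r}, {items[j]!r}): {e}"
                ) from e
            r[i, j] = r[j, i] = rho
            thresholds.setdefault(items[i], tx)
            thresholds.setdefault(items[j], ty)
    smoothed = False
    if np.linalg.eigvalsh(r).min() < 0:
        r = _smooth_to_psd(r)
        smoothed = True
    return PolychoricMatrix(
        matrix=pd.DataFrame(r, index=items, columns=items),
        thresholds=thresholds,
        smoothing_applied=smoothed,
    )


# ---------------------------------------------------------------------------
# factor count and extraction

def parallel_analysis(
    matrix,
    n: int,
    n_sims: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
    ratings=None,
) -> int:
    """Horn's parallel analysis: retained factor count.

    Compares the observed eigenvalues of the (polychoric) correlation matrix
    against the ``quantile`` of eigenvalues from ``n_sims`` Pearson
    correlation matrices of random standard-normal data with the same
    (n, items) shape; retains leading eigenvalues until the first failure.

    If ``ratings`` is supplied, the null eigenvalues instead come from
    independently permuting each item column of the real table (preserving
    the ordinal marginals while destroying inter-item association).
    """
    if isinstance(matrix, PolychoricMatrix):
        r = matrix.to_numpy()
    else:
        r = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    p = r.shape[0]
    if n <= p:
        warnings.warn(f"n={n} <= item count {p}; parallel analysis may be unreliable")
    obs = np.sort(np.linalg.eigvalsh(r))[::-1]
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_sims, p))
    if ratings is not None:
        base = pd.DataFrame(ratings).to_numpy(dtype=float)
        for s in range(n_sims):
            perm = np.column_stack([rng.permutation(base[:, j]) for j in range(p)])
            null_eigs[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(perm.T)))[::-1]
    else:
        for s in range(n_sims):
            x = rng.standard_normal((n, p))
            null_eigs[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(x.T)))[::-1]
    thresh = np.quantile(null_eigs, quantile, axis=0)
    retained = 0
    for i in range(p):
        if obs[i] > thresh[i]:
            retained += 1
        else:
            break
    return retained


def extract_paf_loadings(
    matrix, m: int, n_iter: int = 200, tol: float = 1e-7
) -> np.ndarray:
    """Principal-axis (common-factor) loadings with iterated communalities.

    Eigendecomposes the reduced correlation matrix (communalities on the
    diagonal, initialized at squared multiple correlations) and iterates
    until the communalities stabilize.  Unlike component extraction this
    does not spread unique item variance into the loadings, which would
    otherwise attenuate the factor correlations recovered by an oblique
    rotation.
    """
    if isinstance(matrix, PolychoricMatrix):
        r = matrix.to_numpy()
    else:
        r = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    p = r.shape[0]
    if m > p:
        raise ValueError(f"m={m} exceeds item count {p}")
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    lam = None
    for _ in range(n_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        w, v = np.linalg.eigh(rr)
        order = np.argsort(w)[::-1][:m]
        lam = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
        h2_new = (lam**2).sum(axis=1)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    flip = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    return lam * flip


def default_geomin_epsilon(m: int) -> float:
    """Conventional geomin epsilon schedule: 1e-4 for two factors, 1e-3 for
    three, 1e-2 for four or more (larger epsilon over-smooths the criterion
    and attenuates recovered factor correlations)."""
    if m <= 2:
        return 1e-4
    if m == 3:
        return 1e-3
    return 1e-2


def extract_pca_loadings(matrix, m: int) -> np.ndarray:
    """Unrotated loadings: top-m eigenvectors scaled by sqrt eigenvalues.

    Columns are ordered by descending eigenvalue and oriented so each
    column's maximum-absolute entry is positive.
    """
    if isinstance(matrix, PolychoricMatrix):
        r = matrix.to_numpy()
    else:
        r = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    p = r.shape[0]
    if m > p:
        raise ValueError(f"m={m} exceeds item count {p}")
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not PSD (min eigenvalue {w.min():.3e}); smooth it first"
        )
    order = np.argsort(w)[::-1][:m]
    lam = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    flip = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    return lam * flip


# ---------------------------------------------------------------------------
# geomin rotation (oblique gradient projection)

def geomin_criterion(loadings: np.ndarray, epsilon: float = 0.01) -> tuple[float, np.ndarray]:
    """Geomin criterion and its gradient with respect to the loadings."""
    lam = np.asarray(loadings, dtype=float)
    m = lam.shape[1]
    l2 = lam**2 + epsilon
    pro = np.exp(np.mean(np.log(l2), axis=1))
    f = float(pro.sum())
    grad = (2.0 / m) * (lam / l2) * pro[:, None]
    return f, grad


def _gpa_oblique(
    a: np.ndarray,
    t0: np.ndarray,
    epsilon: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, bool, list[float]]:
    """Gradient-projection algorithm for oblique rotation of ``a``.

    Minimizes the geomin criterion over rotation matrices T with unit-norm
    columns; the rotated loadings are ``a @ inv(T).T``.  Returns
    (T, criterion, converged, per-iteration criterion history).
    """
    t = t0.copy()
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = geomin_criterion(lam, epsilon)
    g = -(lam.T @ gq @ ti).T
    al = 1.0
    history = [f]
    converged = False
    for _ in range(max_iter):
        gp = g - t * (t * g).sum(axis=0)
        s = np.sqrt((gp**2).sum())
        if s < tol:
            converged = True
            break
        al = 2.0 * al
        improved = False
        for _ in range(25):
            x = t - al * gp
            v = 1.0 / np.sqrt((x**2).sum(axis=0))
            tt = x * v
            ti = np.linalg.inv(tt)
            lam = a @ ti.T
            ft, gq = geomin_criterion(lam, epsilon)
            if ft < f - 0.5 * s**2 * al:
                improved = True
                break
            al /= 2.0
        if not improved:
            break
        t, f = tt, ft
        history.append(f)
        g = -(lam.T @ gq @ np.linalg.inv(t)).T
    return t, f, converged, history


def geomin_rotate(
    loadings: np.ndarray,
    epsilon: float = 0.01,
    n_starts: int = 30,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Oblique geomin rotation from multiple random orthonormal starts.

    Keeps the start with the lowest criterion value.  Returns a dict with
    rotated ``loadings``, factor correlation ``phi``, ``criterion``, the
    rotation matrix ``T``, the winning start's monotone criterion
    ``history``, and per-start diagnostics.
    """
    a = np.asarray(loadings, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("need at least 2 factors to rotate")
    m = a.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for start in range(n_starts):
        if start == 0:
            t0 = np.eye(m)
        else:
            q, _ = np.linalg.qr(rng.standard_normal((m, m)))
            t0 = q
        t, f, conv, hist = _gpa_oblique(a, t0, epsilon, tol, max_iter)
        diagnostics.append({"start": start, "criterion": f, "converged": conv})
        if best is None or f < best[1] - 1e-12:
            best = (t, f, conv, hist)
    if not any(d["converged"] for d in diagnostics):
        raise RuntimeError(f"geomin rotation failed to converge from any start: {diagnostics}")
    t, f, conv, hist = best
    lam = a @ np.linalg.inv(t).T
    phi = t.T @ t
    # orient: max-|loading| entry positive per factor (flip phi consistently)
    flip = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    lam = lam * flip
    phi = phi * np.outer(flip, flip)
    np.fill_diagonal(phi, 1.0)
    return {
        "loadings": lam,
        "phi": phi,
        "criterion": f,
        "T": t,
        "history": hist,
        "starts": diagnostics,
    }


# ---------------------------------------------------------------------------
# factor scores and the assembled solution

@dataclass
class FactorSolution:
    """Rotated EFA solution for an item-rating table."""

    m: int
    loadings_rotated: pd.DataFrame
    phi: np.ndarray
    loadings_unrotated: pd.DataFrame
    scores: pd.DataFrame
    geomin_epsilon: float
    criterion_value: float
    polychoric: PolychoricMatrix | None = None
    retained_by_parallel: int | None = None


def factor_scores(ratings, matrix, loadings_rotated, phi) -> pd.DataFrame:
    """Regression-method (Thurstone) factor scores on standardized items.

    Weights are ``R^-1 Lambda Phi`` with R the polychoric matrix; applied to
    the standardized numeric item values and re-standardized columnwise.
    A singular R falls back to a ridge-regularized inverse with a warning.
    """
    df = pd.DataFrame(ratings)
    if isinstance(matrix, PolychoricMatrix):
        r = matrix.to_numpy()
    else:
        r = np.asarray(matrix, dtype=float)
    lam = np.asarray(pd.DataFrame(loadings_rotated).to_numpy(), dtype=float)
    phi = np.asarray(phi, dtype=float)
    z = df.to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) > 0, z.std(axis=0), 1.0)
    structure = lam @ phi  # item-factor correlations under the oblique model
    evals = np.linalg.eigvalsh(r)
    if evals.min() <= 0 or evals.max() / max(evals.min(), 1e-300) > 1e6:
        # near-singular (e.g. heavily smoothed) matrix: ridge keeps the
        # score weights bounded instead of amplifying estimation noise
        jitter = max(1e-8, 1e-3 * evals.max() / r.shape[0])
        warnings.warn(
            f"ill-conditioned correlation matrix; ridge-regularized inverse "
            f"(jitter {jitter:.2e})"
        )
        w = np.linalg.solve(r + jitter * np.eye(r.shape[0]), structure)
    else:
        w = np.linalg.solve(r, structure)
    s = z @ w
    s = (s - s.mean(axis=0)) / np.where(s.std(axis=0) > 0, s.std(axis=0), 1.0)
    cols = [f"F{j + 1}" for j in range(s.shape[1])]
    return pd.DataFrame(s, index=df.index, columns=cols)


def correlate_factor_scores(scores) -> pd.DataFrame:
    """Spearman correlation matrix among factor scores (shared implementation
    with the ICA dimension-score correlation)."""
    return correlate_dimension_scores(scores, scores)


def loading_report(loadings, threshold: float = 0.3) -> dict[str, list[str]]:
    """Items with |loading| >= threshold per factor — an interpretability
    aid for a human analyst, never an automatic decision."""
    df = pd.DataFrame(loadings)
    return {
        str(col): [str(i) for i in df.index[df[col].abs() >= threshold]] for col in df.columns
    }


def run_efa(
    ratings,
    max_factors: int | None = None,
    n_factors: int | None = None,
    epsilon: float | None = None,
    n_starts: int = 30,
    n_sims: int = 100,
    seed: int = 0,
    extraction: str = "paf",
) -> FactorSolution:
    """Full EFA pipeline: polychoric matrix -> parallel analysis ->
    common-factor extraction -> geomin rotation -> regression scores.

    ``n_factors`` overrides parallel analysis; ``max_factors`` caps the
    retained count.  ``extraction`` is "paf" (principal axis, default) or
    "pca" (component extraction).  ``epsilon=None`` uses the conventional
    per-m geomin schedule (:func:`default_geomin_epsilon`).
    """
    df = pd.DataFrame(ratings)
    poly = polychoric_matrix(df)
    retained = parallel_analysis(poly, n=len(df), n_sims=n_sims, seed=seed)
    m = n_factors if n_factors is not None else retained
    if max_factors is not None:
        m = min(m, max_factors)
    if m < 2:
        raise ValueError(f"retained factor count {m} < 2; nothing to rotate")
    if epsilon is None:
        epsilon = default_geomin_epsilon(m)
    if extraction == "paf":
        unrot = extract_paf_loadings(poly, m)
    elif extraction == "pca":
        unrot = extract_pca_loadings(poly, m)
    else:
        raise ValueError(f"unknown extraction {extraction!r}")
    rot = geomin_rotate(unrot, epsilon=epsilon, n_starts=n_starts, seed=seed)
    scores = factor_scores(df, poly, rot["loadings"], rot["phi"])
    items = list(df.columns)
    cols = [f"F{j + 1}" for j in range(m)]
    return FactorSolution(
        m=m,
        loadings_rotated=pd.DataFrame(rot["loadings"], index=items, columns=cols),
        phi=rot["phi"],
        loadings_unrotated=pd.DataFrame(unrot, index=items, columns=cols),
        scores=scores,
        geomin_epsilon=epsilon,
        criterion_value=rot["criterion"],
        polychoric=poly,
        retained_by_parallel=retained,
    )
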