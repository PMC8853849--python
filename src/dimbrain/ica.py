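"""ICA decomposition of item ratings with stability-based model-order selection.

Ordinal item ratings (treated as numeric 0/1/2 and centered) are decomposed
into maximally statistically independent dimensions by fixed-point ICA.
Because fixed-point ICA converges to different solutions from different
random starts, the model order is chosen by a stability criterion: for each
candidate component count ``k`` the decomposition is re-run from many random
initializations, components are matched across runs by the absolute Pearson
correlation of their item-loading vectors, and the stability index is the
mean matched |r|.  The most stable ``k`` is selected (ties toward the
smaller model).  Robustness across acquisition sites is quantified by a
leave-one-site-out refit, comparing each reduced-sample solution to the
full-sample one with the same matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "Whitening",
    "ComponentSolution",
    "StabilityCurve",
    "SiteStabilityReport",
    "center_and_whiten",
    "fastica_single_run",
    "stability_for_k",
    "select_model_order",
    "leave_one_site_out_stability",
    "correlate_dimension_scores",
    "match_components",
]


@dataclass
class Whitening:
    """Centered, variance-normalized principal subspace of the rating matrix.

    ``whitened`` has identity sample covariance; ``components`` (items x r)
    and ``scales`` allow back-projection of component loadings to item space.
    """

    whitened: np.ndarray  # n x r, sample covariance = I
    mean: np.ndarray  # item means
    components: np.ndarray  # items x r right singular vectors
    scales: np.ndarray  # r singular values / sqrt(n)
    item_names: list[str]
    dropped_items: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.whitened.shape[1]

    def back_project(self, w_unmix: np.ndarray) -> np.ndarray:
        """Item-space mixing (loading) matrix for an orthonormal unmixing
        matrix acting on the first k whitened columns."""
        k = w_unmix.shape[0]
        return self.components[:, :k] @ np.diag(self.scales[:k]) @ w_unmix.T

    def reconstruct(self, z: np.ndarray | None = None) -> np.ndarray:
        """Centered data implied by (a subset of) the whitened columns."""
        if z is None:
            z = self.whitened
        r = z.shape[1]
        return z @ np.diag(self.scales[:r]) @ self.components[:, :r].T


@dataclass
class ComponentSolution:
    """Consensus ICA solution at a fixed component count."""

    k: int
    loadings: pd.DataFrame  # items x k
    scores: pd.DataFrame  # subjects x k, mean 0 sd 1
    per_component_stability: np.ndarray
    overall_stability: float
    runs_used: int
    seed: int
    converged_runs: int = 0


@dataclass
class StabilityCurve:
    k_range: list[int]
    stability_by_k: dict[int, float]
    selected_k: int


@dataclass
class SiteStabilityReport:
    per_site: dict[str, float]
    range: tuple[float, float]
    skipped_sites: list[str] = field(default_factory=list)


def _as_matrix(ratings) -> tuple[np.ndarray, list[str], list]:
    if isinstance(ratings, pd.DataFrame):
        return ratings.to_numpy(dtype=float), list(ratings.columns), list(ratings.index)
    x = np.asarray(ratings, dtype=float)
    return x, [f"item_{j + 1:03d}" for j in range(x.shape[1])], list(range(x.shape[0]))


def center_and_whiten(ratings) -> Whitening:
    """Center items and whiten via SVD, dropping zero-variance items.

    The retained principal directions have identity sample covariance;
    directions with relatively negligible singular values (rank deficiency,
    e.g. duplicated items) are discarded.
    """
    x, names, _ = _as_matrix(ratings)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed; impute or drop first")
    sd = x.std(axis=0)
    dropped = [names[j] for j in np.flatnonzero(sd == 0)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance item(s): {dropped[:5]}...")
        keep = sd > 0
        x = x[:, keep]
        names = [n for n, k_ in zip(names, keep) if k_]
    mean = x.mean(axis=0)
    xc = x - mean
    n = x.shape[0]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    whitened = u * np.sqrt(n)  # sample covariance exactly I (ddof=0)
    return Whitening(
        whitened=whitened,
        mean=mean,
        components=vt.T,
        scales=s / np.sqrt(n),
        item_names=names,
        dropped_items=dropped,
    )


def fastica_single_run(
    whitening: Whitening,
    k: int,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> dict:
    """One fixed-point ICA run (logcosh contrast, symmetric decorrelation).

    Operates on the top-k whitened directions from a random orthonormal
    start.  Returns the orthonormal unmixing matrix, item-space loadings,
    subject scores and a convergence flag; non-converged runs are returned
    flagged rather than raised, since the stability clustering tolerates
    them.
    """
    if k > whitening.rank:
        raise ValueError(f"k={k} exceeds whitened rank {whitening.rank}")
    z = whitening.whitened[:, :k]
    rng = np.random.default_rng(seed)
    w_init = rng.standard_normal((k, k))
    ica = FastICA(
        whiten=False,
        fun="logcosh",
        algorithm="parallel",
        tol=tol,
        max_iter=max_iter,
        w_init=w_init,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(z)
    converged = ica.n_iter_ < max_iter
    w = ica.components_  # k x k, orthonormal rows
    loadings = whitening.back_project(w)
    scores = (sources - sources.mean(axis=0)) / sources.std(axis=0)
    return {
        "unmixing": w,
        "loadings": loadings,
        "scores": scores,
        "converged": converged,
        "n_iter": ica.n_iter_,
    }


def match_components(
    reference: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of candidate columns to reference columns
    by descending absolute Pearson correlation.

    Returns (permutation, signs, matched |r| per reference column): candidate
    column ``perm[i]`` with sign ``signs[i]`` corresponds to reference column
    ``i``.
    """
    k = reference.shape[1]
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(reference.T, candidate.T)[:k, k:]
    c = np.nan_to_num(c)
    perm = np.full(k, -1, dtype=int)
    signs = np.ones(k)
    matched_r = np.zeros(k)
    absc = np.abs(c).copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(absc), absc.shape)
        perm[i] = j
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
        matched_r[i] = absc[i, j]
        absc[i, :] = -1.0
        absc[:, j] = -1.0
    return perm, signs, matched_r


def _orient(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its maximum-absolute loading entry is positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip, scores * flip


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(w @ w.T)
    return (u / np.sqrt(s)) @ u.T @ w


def _run_loadings_full(run_loadings: np.ndarray, run_items: list[str],
                       all_items: list[str]) -> np.ndarray:
    """Embed a run's loading matrix into the full item list (zeros for items
    the run's whitening dropped)."""
    if run_items == all_items:
        return run_loadings
    out = np.zeros((len(all_items), run_loadings.shape[1]))
    pos = {name: i for i, name in enumerate(all_items)}
    for r_i, name in enumerate(run_items):
        out[pos[name]] = run_loadings[r_i]
    return out


def _prepare_run_whitenings(
    x: np.ndarray, item_names: list[str], n_runs: int, run_frac: float,
    sub_seeds: list[int], full_whitening: Whitening,
) -> list[Whitening]:
    """Whitenings of each stability run's subsample (shared across k when
    model orders are compared on paired subsamples)."""
    if run_frac >= 1.0:
        return [full_whitening] * n_runs
    n = x.shape[0]
    m = max(int(round(run_frac * n)), 2)
    out = []
    for s in sub_seeds:
        idx = np.random.default_rng(s).choice(n, size=m, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(center_and_whiten(pd.DataFrame(x[idx], columns=item_names)))
    return out


def stability_for_k(
    ratings,
    k: int,
    n_runs: int = 100,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    run_frac: float = 0.5,
    whitening: Whitening | None = None,
    run_seeds: list[int] | None = None,
    _run_whitenings: list[Whitening] | None = None,
) -> ComponentSolution:
    """Stability of the k-component solution over randomized ICA runs.

    Each run refits fixed-point ICA on a random ``run_frac`` subsample from
    a random start (``run_frac=1.0`` reduces to pure random restarts on the
    full data; on strongly structured data restarts alone are nearly
    deterministic and carry little model-order signal, so perturbing the
    sample is the default).  Components of every run are matched to the
    first run's components by greedy one-to-one absolute loading
    correlation; per-component stability is the mean matched |r| across
    runs, overall stability the mean of those.  Consensus loadings are the
    sign-aligned average of matched run loadings; consensus scores are the
    least-squares projection of the centered data onto them, symmetrically
    decorrelated so score columns are exactly uncorrelated.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a stability estimate")
    x, item_names, subj = _as_matrix(ratings)
    if whitening is None:
        whitening = center_and_whiten(ratings)
    if k > whitening.rank:
        raise ValueError(f"k={k} exceeds whitened rank {whitening.rank}")
    rng = np.random.default_rng(seed)
    if run_seeds is None:
        base = [int(s) for s in rng.integers(0, 2**31 - 2, size=n_runs)]
    else:
        if len(run_seeds) != n_runs:
            raise ValueError("run_seeds length must equal n_runs")
        base = [int(s) for s in run_seeds]
    init_seeds = [s + 1 for s in base]
    if _run_whitenings is None:
        _run_whitenings = _prepare_run_whitenings(
            x, item_names, n_runs, run_frac, base, whitening
        )
    runs = []
    for wh_run, s_init in zip(_run_whitenings, init_seeds):
        run = fastica_single_run(wh_run, k, seed=s_init, tol=tol, max_iter=max_iter)
        run["loadings_full"] = _run_loadings_full(
            run["loadings"], wh_run.item_names, whitening.item_names
        )
        runs.append(run)
    ref = runs[0]["loadings_full"]
    stab = np.zeros((n_runs - 1, k))
    a_sum = ref.copy()
    for r_i, run in enumerate(runs[1:]):
        perm, signs, matched_r = match_components(ref, run["loadings_full"])
        stab[r_i] = matched_r
        a_sum += run["loadings_full"][:, perm] * signs[None, :]
    per_component = stab.mean(axis=0)
    a_bar = a_sum / n_runs
    # consensus scores: least-squares projection, then exact decorrelation
    keep = [i for i, name in enumerate(item_names) if name in set(whitening.item_names)]
    xc = x[:, keep] - x[:, keep].mean(axis=0)
    s_raw, *_ = np.linalg.lstsq(a_bar.T @ a_bar, a_bar.T @ xc.T, rcond=None)
    s_raw = s_raw.T
    cov = (s_raw.T @ s_raw) / len(s_raw)
    evals, evecs = np.linalg.eigh(cov)
    scores = s_raw @ (evecs / np.sqrt(np.clip(evals, 1e-12, None))) @ evecs.T
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    loadings, scores = _orient(a_bar, scores)
    comp_names = [f"IC{c + 1}" for c in range(k)]
    return ComponentSolution(
        k=k,
        loadings=pd.DataFrame(loadings, index=whitening.item_names, columns=comp_names),
        scores=pd.DataFrame(scores, index=pd.Index(subj), columns=comp_names),
        per_component_stability=per_component,
        overall_stability=float(per_component.mean()),
        runs_used=n_runs,
        seed=seed,
        converged_runs=sum(r["converged"] for r in runs),
    )


def select_model_order(
    ratings,
    k_range=range(2, 11),
    n_runs: int = 100,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    run_frac: float = 0.5,
) -> tuple[StabilityCurve, ComponentSolution]:
    """Choose the component count maximizing run-to-run stability.

    Evaluates :func:`stability_for_k` over ``k_range`` (default 2-10) and
    selects the argmax, breaking ties toward the smaller model.  All model
    orders are scored on the same set of subsamples (paired comparison).
    Emits a warning when no candidate reaches stability 0.5 (a sign of
    noise-only data).
    """
    k_list = sorted(set(int(k) for k in k_range))
    whitening = center_and_whiten(ratings)
    x, item_names, _ = _as_matrix(ratings)
    rng = np.random.default_rng(seed)
    base = [int(s) for s in rng.integers(0, 2**31 - 2, size=n_runs)]
    run_whitenings = _prepare_run_whitenings(
        x, item_names, n_runs, run_frac, base, whitening
    )
    solutions: dict[int, ComponentSolution] = {}
    stability_by_k: dict[int, float] = {}
    for k in k_list:
        sol = stability_for_k(
            ratings,
            k,
            n_runs=n_runs,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
            run_frac=run_frac,
            whitening=whitening,
            run_seeds=base,
            _run_whitenings=run_whitenings,
        )
        solutions[k] = sol
        stability_by_k[k] = sol.overall_stability
    best = max(stability_by_k.values())
    selected_k = min(k for k, v in stability_by_k.items() if v == best)
    if best < 0.5:
        warnings.warn(
            f"no model order reached stability 0.5 (best {best:.2f} at k={selected_k}); "
            "the data may contain no reliably separable dimensions"
        )
    curve = StabilityCurve(k_range=k_list, stability_by_k=stability_by_k, selected_k=selected_k)
    return curve, solutions[selected_k]


def leave_one_site_out_stability(
    ratings,
    sites,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    min_site_size: int = 10,
    full_solution: ComponentSolution | None = None,
) -> SiteStabilityReport:
    """Refit the consensus solution with each site excluded and compare to
    the full-sample solution.

    For each site, components of the reduced-sample consensus are matched
    one-to-one to the full-sample components by absolute loading correlation;
    the site's stability is the mean matched |r|.  Sites with fewer than
    ``min_site_size`` subjects are skipped with a warning.
    """
    if isinstance(ratings, pd.DataFrame):
        x = ratings
    else:
        x = pd.DataFrame(np.asarray(ratings, dtype=float))
    sites = pd.Series(np.asarray(sites), index=x.index)
    site_levels = sites.unique()
    if len(site_levels) < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    if full_solution is None:
        full_solution = stability_for_k(
            x, k, n_runs=n_runs, seed=int(rng.integers(0, 2**31 - 1))
        )
    ref_loadings = full_solution.loadings.to_numpy()
    per_site: dict[str, float] = {}
    skipped: list[str] = []
    for site in sorted(map(str, site_levels)):
        mask = sites.astype(str) != site
        n_held = int((~mask).sum())
        if n_held < min_site_size:
            warnings.warn(f"site {site} has only {n_held} subjects; skipped")
            skipped.append(site)
            continue
        sol = stability_for_k(
            x.loc[mask], k, n_runs=n_runs, seed=int(rng.integers(0, 2**31 - 1))
        )
        # align on shared items (zero-variance drops may differ)
        common = [i for i in full_solution.loadings.index if i in sol.loadings.index]
        _, _, matched_r = match_components(
            full_solution.loadings.loc[common].to_numpy(),
            sol.loadings.loc[common].to_numpy(),
        )
        per_site[site] = float(matched_r.mean())
    values = np.array(list(per_site.values()))
    return SiteStabilityReport(
        per_site=per_site,
        range=(float(values.min()), float(values.max())),
        skipped_sites=skipped,
    )


def correlate_dimension_scores(scores_a, scores_b) -> pd.DataFrame:
    """Spearman cross-correlation between two score sets (ties get average
    ranks).  Constant columns produce NaN entries and a warning rather than a
    silent zero."""
    a = pd.DataFrame(scores_a)
    b = pd.DataFrame(scores_b)
    if len(a) != len(b):
        raise ValueError("score sets must have equal subject counts")
    out = np.empty((a.shape[1], b.shape[1]))
    const_a = a.std(axis=0).to_numpy() == 0
    const_b = b.std(axis=0).to_numpy() == 0
    if const_a.any() or const_b.any():
        warnings.warn("constant score column(s): correlations undefined (NaN)")
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            if const_a[i] or const_b[j]:
                out[i, j] = np.nan
            else:
                out[i, j] = stats.spearmanr(a.iloc[:, i], b.iloc[:, j]).statistic
    return pd.DataFrame(out, index=a.columns, columns=b.columns)
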