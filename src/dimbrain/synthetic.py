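"""Synthetic multi-site cohort generator with planted latent structure.

Emulates the statistical shape of a large pediatric neurodevelopment cohort:
ordinal behavior-checklist item ratings (119 items scored 0/1/2) driven by a
small number of latent psychopathology dimensions, demographic/anthropometric
covariates with multi-site structure, and per-modality imaging feature tables
with planted linear and nonlinear effects plus pure-null features.  Every
stage of the downstream analysis (ICA, polychoric EFA, kernel regression,
stability mapping) can therefore be tested against known ground truth.

Two latent regimes are supported:

* independent, non-Gaussian latents (standardized exponential marginals) —
  the regime in which an ICA decomposition is identifiable;
* correlated latents via a Gaussian copula — the regime an oblique factor
  model targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "CohortConfig",
    "generate_latent_scores",
    "generate_item_ratings",
    "generate_covariates",
    "generate_imaging_features",
    "default_loadings",
    "default_thresholds",
    "default_effect_map",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]

#: covariate columns that are categorical (one-hot encoded downstream)
CATEGORICAL_COVARIATES = ("sex", "race", "handedness", "scanner")
#: covariate columns treated as continuous
CONTINUOUS_COVARIATES = ("age", "weight", "height", "pubertal_stage", "motion")


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic cohort.

    Attributes
    ----------
    loadings : (items, k) array
        Item weights on each latent dimension; all-zero rows are pure-noise
        items.
    latent_corr : (k, k) array
        Copula (normal-score) correlation of the latent dimensions.
    thresholds : (items, 2) array
        Strictly increasing cut points mapping latent item propensity to the
        ordinal categories {0, 1, 2}.
    effect_map : dict of modality -> (features, k) DataFrame
        Planted association weights; rows of zeros are null features.
    nonlinear_flags : dict of modality -> bool Series
        Features whose planted effect is a centered quadratic of the latent
        score rather than linear.
    """

    loadings: np.ndarray
    latent_corr: np.ndarray
    thresholds: np.ndarray
    effect_map: dict[str, pd.DataFrame]
    nonlinear_flags: dict[str, pd.Series]
    #: per-item sub-syndrome index within its owning dimension (-1 for null items)
    item_subfactor: np.ndarray | None = None
    sub_corr: float = 1.0
    n_sub: int = 1

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        _validate_corr(self.latent_corr)
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("per-item thresholds must be strictly increasing")


@dataclass
class SyntheticCohort:
    """A fully generated cohort: all tables share subject order."""

    ratings: pd.DataFrame
    covariates: pd.DataFrame
    sites: pd.Series
    features: dict[str, pd.DataFrame]
    latent_scores: pd.DataFrame
    truth: GroundTruth
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.ratings)


@dataclass
class CohortConfig:
    """Generation parameters; the defaults are the reference study conditions.

    ``n=2000`` subjects, 119 ordinal items, ``k=3`` latent dimensions,
    22 sites and 60 features in each of three imaging-like modalities give a
    desk-scale cohort with the shape of the target application.
    """

    n: int = 2000
    n_items: int = 119
    k: int = 3
    n_sites: int = 22
    latent_corr_offdiag: float = 0.0
    marginal: str = "exponential"
    n_sub: int = 3
    sub_corr: float = 0.8
    item_noise_sd: float = 1.0
    feature_noise_sd: float = 1.0
    n_features: int = 60
    modalities: tuple[str, ...] = ("smri", "dmri", "rsfmri")
    motion_modalities: tuple[str, ...] = ("dmri", "rsfmri")
    confound_strength: float = 0.3
    site_shift: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def latent_corr(self) -> np.ndarray:
        c = np.full((self.k, self.k), self.latent_corr_offdiag, dtype=float)
        np.fill_diagonal(c, 1.0)
        return c

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate_corr(c: np.ndarray) -> None:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(most negative eigenvalue {w.min():.3e})"
        )


def generate_latent_scores(
    n: int,
    k: int,
    latent_corr: np.ndarray | None = None,
    seed: int = 0,
    marginal: str = "exponential",
) -> np.ndarray:
    """Draw n x k latent dimension scores.

    Scores are generated through a Gaussian copula: draw multivariate normal
    deviates with correlation ``latent_corr``, map through the normal CDF and
    then through the inverse CDF of the requested marginal, and standardize.
    ``latent_corr`` is therefore the normal-score (copula) correlation; for
    the normal marginal it equals the Pearson correlation exactly, for the
    exponential marginal the Pearson correlation is mildly attenuated.

    Parameters
    ----------
    marginal : {"exponential", "normal"}
        "exponential" gives standardized-exponential (skewed, non-Gaussian)
        marginals, required for ICA identifiability; "normal" gives Gaussian
        marginals matching the latent model behind polychoric correlation.
    """
    if latent_corr is None:
        latent_corr = np.eye(k)
    latent_corr = np.asarray(latent_corr, dtype=float)
    if latent_corr.shape != (k, k):
        raise ValueError(f"latent_corr must be {k}x{k}")
    _validate_corr(latent_corr)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k subjects (got n={n}, k={k})")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(latent_corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ chol.T
    if marginal == "normal":
        x = z
    elif marginal == "exponential":
        # standardized exponential: Exp(1) - 1 via inverse-CDF of the copula
        from scipy.stats import norm

        u = norm.cdf(z)
        u = np.clip(u, 1e-15, 1 - 1e-15)
        x = -np.log1p(-u) - 1.0
    else:
        raise ValueError(f"unknown marginal {marginal!r}")
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x


def generate_item_ratings(
    scores: np.ndarray,
    loadings: np.ndarray,
    thresholds: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
    item_names: list[str] | None = None,
) -> pd.DataFrame:
    """Map latent scores to ordinal {0,1,2} item ratings.

    Graded-response-style mechanism: the latent propensity of item *j* is
    ``scores @ loadings[j] + N(0, noise_sd^2)``, cut at the item's two
    thresholds.  Items with all-zero loadings are pure noise.
    """
    scores = np.asarray(scores, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if loadings.shape[1] != scores.shape[1]:
        raise ValueError("loadings column count must equal latent dimension count")
    if thresholds.shape != (loadings.shape[0], 2):
        raise ValueError("thresholds must be (n_items, 2)")
    if np.any(np.diff(thresholds, axis=1) <= 0):
        raise ValueError("thresholds must be strictly increasing per item")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n, _ = scores.shape
    p = loadings.shape[0]
    propensity = scores @ loadings.T
    if noise_sd > 0:
        propensity = propensity + rng.normal(0.0, noise_sd, size=(n, p))
    ratings = (propensity > thresholds[:, 0]).astype(np.int64) + (
        propensity > thresholds[:, 1]
    )
    if item_names is None:
        item_names = [f"item_{j + 1:03d}" for j in range(p)]
    idx = pd.Index([f"sub_{i + 1:05d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(ratings, index=idx, columns=item_names)


def generate_covariates(
    n: int,
    n_sites: int = 22,
    seed: int = 0,
    site_shift: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate the adjustment-covariate table and site labels.

    Columns: sex, age (years), race, handedness, scanner, weight (kg),
    height (cm), pubertal stage (1-4), and in-scanner head motion (mean
    framewise displacement, mm).  Site assignment is balanced (sizes differ
    by at most one).  ``site_shift`` adds independent per-site mean shifts of
    that standard deviation to the continuous covariates, emulating site
    heterogeneity.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    site_labels = np.array([f"site_{s + 1:02d}" for s in range(n_sites)])
    site_idx = np.tile(np.arange(n_sites), n // n_sites + 1)[:n]
    rng.shuffle(site_idx)

    cov = pd.DataFrame(index=pd.Index([f"sub_{i + 1:05d}" for i in range(n)], name="subject_id"))
    cov["sex"] = rng.choice(["F", "M"], size=n)
    cov["age"] = rng.uniform(9.0, 11.0, size=n)
    cov["race"] = rng.choice(
        ["white", "black", "hispanic", "other"], size=n, p=[0.52, 0.15, 0.20, 0.13]
    )
    cov["handedness"] = rng.choice(["right", "left", "mixed"], size=n, p=[0.85, 0.10, 0.05])
    # scanner model is a property of the site (3 vendor types)
    scanner_of_site = np.array([f"scanner_{chr(65 + s % 3)}" for s in range(n_sites)])
    cov["scanner"] = scanner_of_site[site_idx]
    cov["weight"] = rng.normal(36.0, 7.0, size=n).clip(18.0)
    cov["height"] = rng.normal(140.0, 7.0, size=n)
    cov["pubertal_stage"] = rng.choice([1, 2, 3, 4], size=n, p=[0.45, 0.35, 0.15, 0.05]).astype(
        float
    )
    cov["motion"] = np.exp(rng.normal(np.log(0.2), 0.5, size=n))

    if site_shift > 0:
        for col in ("age", "weight", "height", "motion"):
            shifts = rng.normal(0.0, site_shift * cov[col].std(), size=n_sites)
            cov[col] = cov[col] + shifts[site_idx]

    sites = pd.Series(site_labels[site_idx], index=cov.index, name="site")
    return cov, sites


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def generate_imaging_features(
    scores: np.ndarray,
    covariates: pd.DataFrame,
    effect_map: dict[str, pd.DataFrame],
    nonlinear_flags: dict[str, pd.Series],
    noise_sd: float = 1.0,
    seed: int = 0,
    confound_strength: float = 0.0,
    motion_modalities: tuple[str, ...] = ("dmri", "rsfmri"),
) -> dict[str, pd.DataFrame]:
    """Generate per-modality feature tables with planted effects.

    Each feature is a weighted sum (per its ``effect_map`` row) of the latent
    scores — or of their standardized centered square when the feature is
    flagged nonlinear — plus covariate confounding and Gaussian noise.
    Null features (all-zero effect row) depend only on confounds and noise.

    Confounding loads age and sex onto all features, plus head motion for
    modalities listed in ``motion_modalities``, each with weight
    ``confound_strength``.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    rng = np.random.default_rng(seed)

    age_z = _standardize(covariates["age"].to_numpy(float))
    sex_z = _standardize((covariates["sex"] == "M").to_numpy(float))
    motion_z = _standardize(covariates["motion"].to_numpy(float))
    # centered, standardized quadratic transform per latent dimension
    sq = scores**2
    sq = (sq - sq.mean(axis=0)) / sq.std(axis=0)

    out: dict[str, pd.DataFrame] = {}
    for modality, emap in effect_map.items():
        flags = nonlinear_flags[modality]
        if not emap.index.equals(flags.index):
            raise ValueError(
                f"feature names of effect_map and nonlinear_flags disagree for {modality!r}"
            )
        if emap.shape[1] != k:
            raise ValueError(f"effect_map for {modality!r} must have {k} columns")
        e = emap.to_numpy(float)
        lin = scores @ e.T
        nlin = sq @ e.T
        signal = np.where(flags.to_numpy(bool)[None, :], nlin, lin)
        conf = confound_strength * (age_z + 0.5 * sex_z)
        if modality in motion_modalities:
            conf = conf + confound_strength * motion_z
        x = signal + conf[:, None] + rng.normal(0.0, noise_sd, size=signal.shape)
        out[modality] = pd.DataFrame(x, index=covariates.index, columns=emap.index)
    return out


def _item_structure(
    n_items: int, k: int, n_null_items: int, n_sub: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple-structure item layout.

    Returns (loadings, owner, subfactor): ``loadings`` is the effective
    items x k weight matrix (main weight ~ U(0.5, 0.9) on the owning
    dimension, cross-loadings ~ U(-0.1, 0.1) elsewhere); ``owner`` is the
    owning dimension per item (-1 for the trailing pure-noise items);
    ``subfactor`` assigns each signal item to one of its dimension's
    ``n_sub`` sub-syndromes.
    """
    rng = np.random.default_rng(seed)
    lo = np.zeros((n_items, k))
    owner = np.full(n_items, -1)
    subfactor = np.full(n_items, -1)
    n_signal = n_items - n_null_items
    for j in range(n_signal):
        owner[j] = j % k
        subfactor[j] = (j // k) % n_sub
        # small secondary loadings; large ones would bias any oblique
        # rotation's factor-correlation estimate (geomin attenuation)
        lo[j] = rng.uniform(-0.05, 0.05, size=k)
        lo[j, owner[j]] = rng.uniform(0.5, 0.9)
    return lo, owner, subfactor


def default_loadings(
    n_items: int = 119, k: int = 3, n_null_items: int = 9, seed: int = 0
) -> np.ndarray:
    """Effective item-by-dimension loadings of the default item layout; the
    last ``n_null_items`` items are pure noise."""
    return _item_structure(n_items, k, n_null_items, n_sub=1, seed=seed)[0]


def default_thresholds(n_items: int = 119, seed: int = 0) -> np.ndarray:
    """Mildly right-skewed ordinal cuts, jittered per item.

    Base cuts near (0, 1) on the propensity scale produce category
    frequencies of roughly 50/35/15 percent — skewed toward 0 the way
    behavior-problem items are, while keeping all cells populated for
    polychoric estimation at the default sample size.
    """
    rng = np.random.default_rng(seed)
    t1 = rng.normal(0.0, 0.15, size=n_items)
    gap = rng.uniform(0.8, 1.2, size=n_items)
    return np.column_stack([t1, t1 + gap])


def default_effect_map(
    n_features: int = 60,
    k: int = 3,
    modality: str = "smri",
    n_linear_per_dim: int = 12,
    n_nonlinear_per_dim: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted effect layout for one modality.

    Per latent dimension: ``n_linear_per_dim`` features with a linear effect
    of magnitude U(0.4, 0.8) and random sign, ``n_nonlinear_per_dim``
    flagged quadratic features with the same magnitude; remaining features
    are pure null.
    """
    rng = np.random.default_rng(seed)
    names = [f"{modality}_feat_{j + 1:03d}" for j in range(n_features)]
    emap = np.zeros((n_features, k))
    flags = np.zeros(n_features, dtype=bool)
    pos = 0
    for d in range(k):
        for _ in range(n_linear_per_dim):
            if pos >= n_features:
                break
            emap[pos, d] = rng.uniform(0.4, 0.8) * rng.choice([-1.0, 1.0])
            pos += 1
    for d in range(k):
        for _ in range(n_nonlinear_per_dim):
            if pos >= n_features:
                break
            emap[pos, d] = rng.uniform(0.4, 0.8) * rng.choice([-1.0, 1.0])
            flags[pos] = True
            pos += 1
    idx = pd.Index(names, name="feature")
    return pd.DataFrame(emap, index=idx, columns=[f"dim_{d + 1}" for d in range(k)]), pd.Series(
        flags, index=idx, name="nonlinear"
    )


def ica_regime_config(**overrides) -> CohortConfig:
    """Study conditions for the independence-based decomposition: three
    statistically independent, non-Gaussian (standardized exponential)
    latent dimensions, each composed of correlated sub-syndromes.  These
    are the :class:`CohortConfig` defaults."""
    return CohortConfig(**overrides)


def efa_regime_config(**overrides) -> CohortConfig:
    """Study conditions for the correlated-factor decomposition: three
    latent dimensions with pairwise correlation 0.6, Gaussian marginals
    (matching the latent-response model behind polychoric correlation), and
    no sub-syndrome splitting — the generator emulates the broad 3-factor
    level of the hierarchy."""
    base = dict(latent_corr_offdiag=0.6, marginal="normal", n_sub=1, sub_corr=1.0)
    return CohortConfig(**{**base, **overrides})


def make_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a complete seeded cohort from a :class:`CohortConfig`.

    Keyword overrides are applied on top of the supplied (or default) config.
    Identical config + seed gives a bit-identical cohort.
    """
    if config is None:
        config = CohortConfig()
    if overrides:
        config = CohortConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    # independent child seeds per stage, all derived from the master seed
    s_scores, s_items, s_cov, s_feat, s_struct, s_miss = rng.integers(0, 2**31 - 1, size=6)

    latent_corr = config.latent_corr()
    scores = generate_latent_scores(
        config.n, config.k, latent_corr, seed=int(s_scores), marginal=config.marginal
    )
    loadings, owner, subfactor = _item_structure(
        config.n_items, config.k, n_null_items=9, n_sub=config.n_sub, seed=int(s_struct)
    )
    thresholds = default_thresholds(config.n_items, seed=int(s_struct))

    # Hierarchical item mechanism: each dimension is composed of n_sub
    # correlated sub-syndromes; an item loads on one sub-syndrome of its
    # owning dimension (plus its small cross-loadings on the other parents).
    # Realized by handing generate_item_ratings an augmented latent matrix
    # [sub-syndrome scores | parent scores] with matching augmented loadings.
    k, n_sub = config.k, config.n_sub
    sub_rng = np.random.default_rng(int(s_scores) + 1)
    beta = np.sqrt(max(0.0, 1.0 - config.sub_corr**2))
    sub_scores = np.empty((config.n, k * n_sub))
    for d in range(k):
        for m in range(n_sub):
            if config.marginal == "exponential":
                e = sub_rng.exponential(1.0, config.n) - 1.0
            else:
                e = sub_rng.standard_normal(config.n)
            f = config.sub_corr * scores[:, d] + beta * e
            sub_scores[:, d * n_sub + m] = f / f.std()
    aug_scores = np.hstack([sub_scores, scores])
    aug_loadings = np.zeros((config.n_items, k * n_sub + k))
    for j in range(config.n_items):
        if owner[j] < 0:
            continue
        d = owner[j]
        aug_loadings[j, d * n_sub + subfactor[j]] = loadings[j, d]
        cross = loadings[j].copy()
        cross[d] = 0.0
        aug_loadings[j, k * n_sub:] = cross
    ratings = generate_item_ratings(
        aug_scores, aug_loadings, thresholds, noise_sd=config.item_noise_sd, seed=int(s_items)
    )
    covariates, sites = generate_covariates(
        config.n, config.n_sites, seed=int(s_cov), site_shift=config.site_shift
    )
    effect_map: dict[str, pd.DataFrame] = {}
    nonlinear_flags: dict[str, pd.Series] = {}
    for i, modality in enumerate(config.modalities):
        emap, flags = default_effect_map(
            config.n_features, config.k, modality=modality, seed=int(s_struct) + i
        )
        effect_map[modality] = emap
        nonlinear_flags[modality] = flags
    features = generate_imaging_features(
        scores,
        covariates,
        effect_map,
        nonlinear_flags,
        noise_sd=config.feature_noise_sd,
        seed=int(s_feat),
        confound_strength=config.confound_strength,
        motion_modalities=config.motion_modalities,
    )
    truth = GroundTruth(
        loadings=loadings,
        latent_corr=latent_corr,
        thresholds=thresholds,
        effect_map=effect_map,
        nonlinear_flags=nonlinear_flags,
        item_subfactor=subfactor,
        sub_corr=config.sub_corr,
        n_sub=config.n_sub,
    )
    score_df = pd.DataFrame(
        scores, index=ratings.index, columns=[f"dim_{d + 1}" for d in range(config.k)]
    )
    if config.missing_rate > 0:
        miss_rng = np.random.default_rng(int(s_miss))
        mask = miss_rng.random(ratings.shape) < config.missing_rate
        ratings = ratings.astype(float).mask(mask)
    return SyntheticCohort(
        ratings=ratings,
        covariates=covariates,
        sites=sites,
        features=features,
        latent_scores=score_df,
        truth=truth,
        seed=config.seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort to TSV/JSON files (ratings.tsv, covariates.tsv,
    features_<modality>.tsv, truth.json, cohort_meta.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.ratings.to_csv(outdir / "ratings.tsv", sep="\t")
    cov = cohort.covariates.copy()
    cov["site"] = cohort.sites
    cov.to_csv(outdir / "covariates.tsv", sep="\t")
    for modality, table in cohort.features.items():
        table.to_csv(outdir / f"features_{modality}.tsv", sep="\t")
    cohort.latent_scores.to_csv(outdir / "latent_scores.tsv", sep="\t")
    truth = {
        "loadings": cohort.truth.loadings.tolist(),
        "latent_corr": cohort.truth.latent_corr.tolist(),
        "thresholds": cohort.truth.thresholds.tolist(),
        "effect_map": {m: df.to_dict(orient="index") for m, df in cohort.truth.effect_map.items()},
        "nonlinear_flags": {
            m: s.astype(bool).to_dict() for m, s in cohort.truth.nonlinear_flags.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
    meta = {"seed": cohort.seed, "n_subjects": cohort.n_subjects}
    (outdir / "cohort_meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(indir: str | Path) -> dict:
    """Read cohort tables back from a directory written by :func:`write_cohort`.

    Returns a dict with keys ratings, covariates, sites, features (dict) and,
    if present, latent_scores.  Ground truth is not reconstructed.
    """
    indir = Path(indir)
    ratings = pd.read_csv(indir / "ratings.tsv", sep="\t", index_col="subject_id")
    cov = pd.read_csv(indir / "covariates.tsv", sep="\t", index_col="subject_id")
    sites = cov.pop("site")
    features = {}
    for f in sorted(indir.glob("features_*.tsv")):
        modality = f.stem.removeprefix("features_")
        features[modality] = pd.read_csv(f, sep="\t", index_col="subject_id")
    out = {"ratings": ratings, "covariates": cov, "sites": sites, "features": features}
    scores_path = indir / "latent_scores.tsv"
    if scores_path.exists():
        out["latent_scores"] = pd.read_csv(scores_path, sep="\t", index_col="subject_id")
    return out
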