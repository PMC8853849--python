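"""Association mapping between psychopathology dimensions and brain features.

For each (dimension, modality) pair a single KRLS model regresses the
dimension score on all of that modality's features entered jointly, plus the
adjustment covariates (sex, age, race, handedness, scanner, weight, height,
pubertal stage; head motion for diffusion- and resting-state-like
modalities).  The feature t-values from the full-data model form the
dimension's association profile.  Robustness to sample composition is
quantified by rerunning the model on random half-samples: each feature's
signed stability count is the number of reruns in which it is significant
at the Benjamini-Hochberg FDR level, multiplied by the sign of its
full-data effect.  Profiles of different dimensions are compared by
Spearman correlation of their t-value vectors (regardless of significance).

The same machinery runs in the validation direction, with an external
outcome regressed on all dimension scores entered together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .krls import KRLSFit, average_marginal_effects, krls_fit
from .ica import correlate_dimension_scores
from .synthetic import CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES, SyntheticCohort

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "StabilityMap",
    "build_covariate_design",
    "bh_fdr",
    "fit_association_model",
    "fit_full_model",
    "resample_stability",
    "profile_similarity",
    "run_comparison_suite",
    "SuiteResult",
]

#: modalities whose models additionally adjust for head motion
DEFAULT_MOTION_MODALITIES = ("dmri", "rsfmri")


@dataclass
class ModelSpec:
    """Declarative description of one association model."""

    outcome_role: str  # "dimension" (brain-correlates direction) or "external"
    modality: str
    motion_included: bool
    predictor_block: list[str] = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    """Full-data association profile plus the complete AME table."""

    profile: pd.DataFrame  # per block predictor: t, sign, estimate, p
    ame_table: pd.DataFrame  # all predictors incl. covariates
    fit: KRLSFit
    spec: ModelSpec


@dataclass
class StabilityMap:
    """Signed FDR-significance counts over half-sample reruns."""

    table: pd.DataFrame  # per feature: signed_count, n_significant, full_t, full_sign
    n_reps: int
    n_reps_used: int
    frac: float
    alpha: float
    rerun_seeds: list[int] = field(default_factory=list)


def build_covariate_design(
    covariates: pd.DataFrame, motion_included: bool = False
) -> pd.DataFrame:
    """Numeric adjustment design: continuous covariates as-is, categorical
    covariates one-hot encoded with the first (reference) level dropped.
    Head motion enters only when ``motion_included``; total intracranial
    volume is never an adjuster."""
    cols = {}
    for c in CONTINUOUS_COVARIATES:
        if c == "motion" and not motion_included:
            continue
        if c in covariates:
            cols[c] = covariates[c].astype(float)
    parts = [pd.DataFrame(cols, index=covariates.index)]
    cats = [c for c in CATEGORICAL_COVARIATES if c in covariates]
    if cats:
        parts.append(pd.get_dummies(covariates[cats], drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def _drop_constant(block: pd.DataFrame) -> pd.DataFrame:
    sd = block.std(axis=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(f"dropping constant predictor(s): {const}")
        block = block.drop(columns=const)
    return block


def fit_association_model(
    outcome: pd.Series,
    predictor_block: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    motion_included: bool = False,
    modality: str = "",
    outcome_role: str = "dimension",
    n_cap: int = 2500,
    cap_seed: int = 0,
    lam: float | None = None,
) -> AssociationResult:
    """One KRLS association model with covariate adjustment.

    The block of interest (imaging features, or dimension scores in the
    validation direction) and the covariate design are entered jointly;
    the returned profile covers the block columns only, while the AME table
    retains the covariate rows.  Samples larger than ``n_cap`` are reduced
    to a seeded random subset to keep the O(n^3) solve desk-scale.
    """
    outcome = pd.Series(outcome)
    block = _drop_constant(pd.DataFrame(predictor_block).astype(float))
    parts = [block]
    if covariates is not None:
        parts.append(build_covariate_design(covariates, motion_included))
    design = pd.concat(parts, axis=1)
    if not outcome.index.equals(design.index):
        raise ValueError("outcome and predictors must share subject index")
    if len(design) > n_cap:
        rng = np.random.default_rng(cap_seed)
        keep = np.sort(rng.choice(len(design), size=n_cap, replace=False))
        design = design.iloc[keep]
        outcome = outcome.iloc[keep]
    fit = krls_fit(design, outcome, lam=lam)
    ame = average_marginal_effects(fit)
    prof = ame.loc[[c for c in block.columns if c in ame.index]].copy()
    prof["sign"] = np.sign(prof["t"]).fillna(0).astype(int)
    spec = ModelSpec(
        outcome_role=outcome_role,
        modality=modality,
        motion_included=motion_included,
        predictor_block=list(block.columns),
        covariate_columns=[c for c in design.columns if c not in block.columns],
    )
    return AssociationResult(profile=prof, ame_table=ame, fit=fit, spec=spec)


def fit_full_model(
    dimension_score: pd.Series,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    motion_included: bool = False,
    modality: str = "",
    **kwargs,
) -> AssociationResult:
    """Brain-correlates direction: dimension score regressed on all features
    of one modality plus covariates."""
    return fit_association_model(
        dimension_score,
        features,
        covariates,
        motion_included=motion_included,
        modality=modality,
        outcome_role="dimension",
        **kwargs,
    )


def resample_stability(
    dimension_score: pd.Series,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    motion_included: bool = False,
    modality: str = "",
    n_reps: int = 100,
    frac: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
    full_result: AssociationResult | None = None,
    n_cap: int = 2500,
) -> StabilityMap:
    """Signed FDR-significance counts over random half-sample reruns.

    Each rep draws a seeded ``frac`` subsample without replacement, refits
    the KRLS model (lambda re-selected), applies BH-FDR within the model's
    feature p-values, and records significance.  The count is signed by the
    full-data model's effect direction; reps that fail numerically are
    skipped and the denominator reported.
    """
    if full_result is None:
        full_result = fit_full_model(
            dimension_score, features, covariates,
            motion_included=motion_included, modality=modality, n_cap=n_cap,
        )
    feat_names = list(full_result.profile.index)
    n = len(dimension_score)
    m = int(round(frac * n))
    d_total = len(feat_names) + len(full_result.spec.covariate_columns)
    if m < 10 * d_total:
        warnings.warn(
            f"subsample size {m} is below 10x predictor count {d_total}; "
            "rerun fits may be unstable"
        )
    rng = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]
    counts = pd.Series(0, index=feat_names, dtype=int)
    used = 0
    for rs in rep_seeds:
        idx = np.sort(np.random.default_rng(rs).choice(n, size=m, replace=False))
        try:
            res = fit_association_model(
                dimension_score.iloc[idx],
                features.iloc[idx],
                covariates.iloc[idx] if covariates is not None else None,
                motion_included=motion_included,
                modality=modality,
                n_cap=n_cap,
            )
        except (np.linalg.LinAlgError, ValueError) as e:
            warnings.warn(f"rerun (seed {rs}) failed and was skipped: {e}")
            continue
        used += 1
        common = [f for f in feat_names if f in res.profile.index]
        _, reject = bh_fdr(res.profile.loc[common, "p"].fillna(1.0), alpha=alpha)
        counts.loc[common] += reject.astype(int)
    full_sign = full_result.profile["sign"].reindex(feat_names).fillna(0).astype(int)
    table = pd.DataFrame(
        {
            "signed_count": counts * full_sign,
            "n_significant": counts,
            "full_t": full_result.profile["t"].reindex(feat_names),
            "full_sign": full_sign,
        }
    )
    table.index.name = "feature"
    return StabilityMap(
        table=table, n_reps=n_reps, n_reps_used=used, frac=frac, alpha=alpha,
        rerun_seeds=rep_seeds,
    )


def profile_similarity(profile_a, profile_b) -> float:
    """Spearman correlation of two t-value vectors over the same features
    (average ranks on ties)."""
    a = pd.Series(profile_a)
    b = pd.Series(profile_b)
    if len(a) != len(b):
        raise ValueError("profiles must cover the same feature set")
    if len(a) < 3:
        raise ValueError("need at least 3 features to compare profiles")
    if not a.index.equals(b.index):
        raise ValueError("profiles must share feature order")
    return float(stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic)


@dataclass
class SuiteResult:
    """All outputs of the cross-method comparison suite."""

    profiles: dict  # (method, dimension, modality) -> t-value Series
    stability: dict  # (method, dimension, modality) -> StabilityMap
    similarity: dict[str, pd.DataFrame]  # modality -> labeled similarity matrix
    score_correlation: pd.DataFrame  # ICA dims x EFA dims (Spearman)


def run_comparison_suite(
    ica_scores: pd.DataFrame,
    efa_scores: pd.DataFrame,
    cohort: SyntheticCohort | dict,
    n_reps: int = 100,
    frac: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
    compute_stability: bool = True,
    motion_modalities: tuple[str, ...] = DEFAULT_MOTION_MODALITIES,
    n_cap: int = 2500,
) -> SuiteResult:
    """Fit every (method, dimension, modality) association model and compare.

    Emits full-data t-profiles (and optionally half-sample stability maps)
    for both decompositions, all pairwise profile similarities within and
    between methods per modality, and the cross-method Spearman correlation
    of the dimension scores themselves.
    """
    if isinstance(cohort, SyntheticCohort):
        features = cohort.features
        covariates = cohort.covariates
    else:
        features = cohort["features"]
        covariates = cohort["covariates"]
    methods = {"ICA": pd.DataFrame(ica_scores), "EFA": pd.DataFrame(efa_scores)}
    rng = np.random.default_rng(seed)
    profiles: dict = {}
    stability: dict = {}
    for method, scores in methods.items():
        for dim in scores.columns:
            for modality, feats in features.items():
                res = fit_full_model(
                    scores[dim], feats, covariates,
                    motion_included=modality in motion_modalities,
                    modality=modality, n_cap=n_cap,
                )
                key = (method, str(dim), modality)
                profiles[key] = res.profile["t"]
                if compute_stability:
                    stability[key] = resample_stability(
                        scores[dim], feats, covariates,
                        motion_included=modality in motion_modalities,
                        modality=modality, n_reps=n_reps, frac=frac, alpha=alpha,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        full_result=res, n_cap=n_cap,
                    )
    similarity: dict[str, pd.DataFrame] = {}
    for modality in features:
        labels = [
            f"{method}:{dim}"
            for method, scores in methods.items()
            for dim in scores.columns
        ]
        mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
        keys = [
            (method, str(dim), modality)
            for method, scores in methods.items()
            for dim in scores.columns
        ]
        for i, ki in enumerate(keys):
            for j, kj in enumerate(keys):
                if i < j:
                    rho = profile_similarity(profiles[ki], profiles[kj])
                    mat.iloc[i, j] = mat.iloc[j, i] = rho
        similarity[modality] = mat
    score_corr = correlate_dimension_scores(methods["ICA"], methods["EFA"])
    return SuiteResult(
        profiles=profiles,
        stability=stability,
        similarity=similarity,
        score_correlation=score_corr,
    )
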