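import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dimbrain.mapping import (
    bh_fdr,
    build_covariate_design,
    fit_association_model,
    fit_full_model,
    profile_similarity,
    resample_stability,
    run_comparison_suite,
)
from dimbrain.synthetic import generate_imaging_features, make_cohort


def _bh_stepup_oracle(p, alpha=0.05):
    """Textbook step-up rule, written independently of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj, adj <= alpha


class TestBhFdr:
    def test_hand_worked_example(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones_no_rejections(self):
        adj, rej = bh_fdr([1.0] * 5)
        assert not rej.any() and np.all(adj == 1.0)

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_textbook_stepup_rule(self, p):
        adj, rej = bh_fdr(p)
        adj_o, rej_o = _bh_stepup_oracle(p)
        np.testing.assert_allclose(adj, adj_o, atol=1e-12)
        np.testing.assert_array_equal(rej, rej_o)


class TestCovariateDesign:
    def test_one_hot_and_motion_flag(self, ica_cohort):
        d0 = build_covariate_design(ica_cohort.covariates, motion_included=False)
        d1 = build_covariate_design(ica_cohort.covariates, motion_included=True)
        assert "motion" not in d0.columns and "motion" in d1.columns
        assert "sex_M" in d0.columns and "sex" not in d0.columns
        assert d0.select_dtypes(exclude="number").empty

    def test_reference_levels_dropped(self, ica_cohort):
        d = build_covariate_design(ica_cohort.covariates)
        n_race = ica_cohort.covariates["race"].nunique()
        assert sum(c.startswith("race_") for c in d.columns) == n_race - 1


@pytest.fixture(scope="module")
def planted():
    """Cohort with one modality of 10 features: two strong planted effects on
    dimension 1, the rest pure null."""
    c = make_cohort(n=600, n_features=10, n_items=30, seed=21, modalities=("smri",))
    emap = c.truth.effect_map["smri"].copy()
    emap.iloc[:, :] = 0.0
    emap.iloc[0, 0] = 1.0
    emap.iloc[1, 0] = -1.0
    flags = c.truth.nonlinear_flags["smri"].copy()
    flags.iloc[:] = False
    feats = generate_imaging_features(
        c.latent_scores.to_numpy(), c.covariates, {"smri": emap}, {"smri": flags},
        noise_sd=1.0, seed=5, confound_strength=0.3,
    )["smri"]
    return c, feats


class TestFullModel:
    def test_planted_feature_has_largest_t(self, planted):
        c, feats = planted
        res = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates)
        t = res.profile["t"].abs()
        assert set(t.nlargest(2).index) == {"smri_feat_001", "smri_feat_002"}
        assert res.profile.loc["smri_feat_001", "sign"] == 1
        assert res.profile.loc["smri_feat_002", "sign"] == -1

    def test_covariates_in_ame_but_not_profile(self, planted):
        c, feats = planted
        res = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates)
        assert "age" in res.ame_table.index
        assert "age" not in res.profile.index
        assert len(res.profile) == feats.shape[1]

    def test_all_null_modality_small_t(self, planted):
        c, _ = planted
        null_feats = c.features["smri"].copy()
        emap = c.truth.effect_map["smri"].copy()
        emap.iloc[:, :] = 0.0
        flags = c.truth.nonlinear_flags["smri"].copy()
        flags.iloc[:] = False
        null_feats = generate_imaging_features(
            c.latent_scores.to_numpy(), c.covariates, {"smri": emap},
            {"smri": flags}, noise_sd=1.0, seed=9, confound_strength=0.3,
        )["smri"]
        res = fit_full_model(c.latent_scores["dim_1"], null_feats, c.covariates)
        assert res.profile["t"].abs().max() < 4.0

    def test_constant_feature_dropped_with_warning(self, planted):
        c, feats = planted
        feats = feats.copy()
        feats["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates)
        assert "flat" not in res.profile.index

    def test_covariate_adjustment_attenuates_confounded_association(self):
        # feature and outcome both driven by age; adjustment shrinks |t|
        rng = np.random.default_rng(3)
        n = 500
        c = make_cohort(n=n, n_features=4, n_items=20, seed=33, modalities=("smri",))
        age_z = (c.covariates["age"] - c.covariates["age"].mean()) / c.covariates["age"].std()
        outcome = pd.Series(age_z + rng.normal(0, 0.5, n), index=c.ratings.index)
        feats = pd.DataFrame(
            {"conf_feat": age_z + rng.normal(0, 0.5, n)}, index=c.ratings.index
        )
        adj = fit_association_model(outcome, feats, c.covariates)
        unadj = fit_association_model(outcome, feats, None)
        assert abs(adj.profile.loc["conf_feat", "t"]) < abs(unadj.profile.loc["conf_feat", "t"])

    def test_n_cap_subsamples_deterministically(self, planted):
        c, feats = planted
        r1 = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates, n_cap=200)
        r2 = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates, n_cap=200)
        pd.testing.assert_frame_equal(r1.profile, r2.profile)
        assert r1.fit.n == 200


class TestResampleStability:
    def test_planted_high_null_low(self, planted):
        c, feats = planted
        with np.errstate(all="ignore"):
            smap = resample_stability(
                c.latent_scores["dim_1"], feats, c.covariates, n_reps=30, seed=4
            )
        t = smap.table
        assert t.loc["smri_feat_001", "signed_count"] >= 27
        assert t.loc["smri_feat_002", "signed_count"] <= -27
        assert smap.n_reps_used == 30

    def test_full_fraction_reps_reproduce_full_fit(self, planted):
        c, feats = planted
        full = fit_full_model(c.latent_scores["dim_1"], feats, c.covariates)
        smap = resample_stability(
            c.latent_scores["dim_1"], feats, c.covariates, n_reps=2, frac=1.0,
            seed=5, full_result=full,
        )
        assert set(smap.table["signed_count"].unique()) <= {-2, 0, 2}

    def test_count_symmetry_under_outcome_negation(self, planted):
        c, feats = planted
        kw = dict(n_reps=10, seed=6)
        a = resample_stability(c.latent_scores["dim_1"], feats, c.covariates, **kw)
        b = resample_stability(-c.latent_scores["dim_1"], feats, c.covariates, **kw)
        np.testing.assert_array_equal(
            a.table["signed_count"].to_numpy(), -b.table["signed_count"].to_numpy()
        )
        np.testing.assert_allclose(
            a.table["full_t"].to_numpy(), -b.table["full_t"].to_numpy(), atol=1e-8
        )

    def test_seeded_determinism(self, planted):
        c, feats = planted
        kw = dict(n_reps=5, seed=8)
        a = resample_stability(c.latent_scores["dim_1"], feats, c.covariates, **kw)
        b = resample_stability(c.latent_scores["dim_1"], feats, c.covariates, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.rerun_seeds == b.rerun_seeds


class TestProfileSimilarity:
    def test_self_and_negation(self, rng):
        p = pd.Series(rng.normal(size=10))
        assert profile_similarity(p, p) == pytest.approx(1.0)
        assert profile_similarity(p, -p) == pytest.approx(-1.0)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            profile_similarity(pd.Series([1, 2.0]), pd.Series([2, 1.0]))

    def test_shared_vs_disjoint_planted_supports(self):
        # each feature carries its own independent driver; two outcomes built
        # from the same driver weights share an association pattern, a third
        # outcome uses disjoint drivers.  Independent drivers keep features
        # non-collinear so joint-model partial t-values stay informative.
        rng2 = np.random.default_rng(7)
        n, q = 1500, 16
        u = rng2.normal(size=(n, q))
        idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
        feats = pd.DataFrame(
            u + rng2.normal(0, 0.3, size=(n, q)), index=idx,
            columns=[f"feat_{j:02d}" for j in range(q)],
        )
        w = rng2.uniform(0.3, 1.0, q) * rng2.choice([-1, 1], q)
        w_shared = w.copy()
        w_shared[q // 2:] = 0.0  # outcomes 1,2 driven by the first half
        w_disjoint = w.copy()
        w_disjoint[: q // 2] = 0.0  # outcome 3 by the second half
        y1 = pd.Series(u @ w_shared + rng2.normal(0, 1, n), index=idx)
        y2 = pd.Series(u @ w_shared + rng2.normal(0, 1, n), index=idx)
        y3 = pd.Series(u @ w_disjoint + rng2.normal(0, 1, n), index=idx)
        profs = [
            fit_association_model(y, feats).profile["t"] for y in (y1, y2, y3)
        ]
        assert profile_similarity(profs[0], profs[1]) > 0.8
        assert abs(profile_similarity(profs[0], profs[2])) < 0.5


class TestComparisonSuite:
    def test_single_dimension_single_modality_reduces_to_one_map(self, planted):
        c, feats = planted
        scores = c.latent_scores[["dim_1"]]
        suite = run_comparison_suite(
            scores, scores, {"features": {"smri": feats}, "covariates": c.covariates},
            n_reps=3, seed=9,
        )
        assert len(suite.stability) == 2  # one per method label
        assert list(suite.similarity) == ["smri"]
        assert suite.similarity["smri"].shape == (2, 2)

    def test_motion_flag_respected_per_modality(self, planted):
        c, feats = planted
        scores = c.latent_scores[["dim_1"]]
        suite = run_comparison_suite(
            scores, scores,
            {"features": {"rsfmri": feats}, "covariates": c.covariates},
            n_reps=2, seed=10, compute_stability=False,
        )
        assert ("ICA", "dim_1", "rsfmri") in suite.profiles
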