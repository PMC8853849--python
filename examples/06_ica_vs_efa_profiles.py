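"""The central methodological contrast: ICA vs EFA brain-profile overlap.

On a cohort whose latent dimensions truly correlate (0.6), the oblique EFA
factors inherit that correlation, so their feature-association t-profiles
look alike; ICA forces statistically independent dimensions, whose profiles
are far more dissociable.  This mirrors the motivation for preferring ICA
when the goal is dimensions with distinct neural correlates.
"""

import itertools

import numpy as np

from dimbrain import fit_full_model, make_cohort, profile_similarity, run_efa
from dimbrain.ica import stability_for_k
from dimbrain.synthetic import ica_regime_config

cohort = make_cohort(ica_regime_config(
    n=800, seed=1, latent_corr_offdiag=0.6, n_sub=1, sub_corr=1.0,
    modalities=("smri",),
))

ica_sol = stability_for_k(cohort.ratings, 3, n_runs=10, seed=2)
efa_sol = run_efa(cohort.ratings, n_factors=3, seed=3, n_sims=30)

for name, scores in [("ICA", ica_sol.scores), ("EFA", efa_sol.scores)]:
    profiles = [
        fit_full_model(scores.iloc[:, d], cohort.features["smri"],
                       cohort.covariates).profile["t"]
        for d in range(3)
    ]
    sims = [profile_similarity(profiles[i], profiles[j])
            for i, j in itertools.combinations(range(3), 2)]
    print(f"{name}: between-dimension profile Spearman rho = "
          f"{np.round(sims, 2)} (mean {np.mean(sims):+.2f})")

print("\nEFA profiles overlap strongly; ICA profiles stay near zero —")
print("independent dimensions map onto dissociable brain patterns.")
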