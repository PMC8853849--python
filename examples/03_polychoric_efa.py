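"""Polychoric EFA with geomin rotation on correlated latent dimensions.

Ordinal items are modeled as discretized bivariate-normal latents; the
polychoric correlation matrix feeds parallel analysis (factor count),
principal-axis extraction and an oblique geomin rotation that lets the
factors correlate — the regime where the generator planted a pairwise
latent correlation of 0.6.
"""

import numpy as np

from dimbrain import efa_regime_config, make_cohort, run_efa
from dimbrain.efa import loading_report

cohort = make_cohort(efa_regime_config(n=1200, n_items=60, seed=5))
solution = run_efa(cohort.ratings, max_factors=8, seed=1, n_sims=50)

print(f"parallel analysis retained {solution.retained_by_parallel} factors")
print("factor correlation matrix (phi):")
print(np.round(solution.phi, 3))
print("(planted latent correlation was 0.6; geomin recovers it up to a")
print(" small, documented attenuation)")

report = loading_report(solution.loadings_rotated, threshold=0.4)
for factor, items in report.items():
    print(f"{factor}: {len(items)} items with |loading| >= 0.4")
print("\nFactor scores correlate strongly across factors — the signature of")
print("an oblique solution:")
print(np.round(solution.scores.corr(method='spearman').to_numpy(), 3))
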