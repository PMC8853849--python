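"""Generate a synthetic multi-site cohort and look at its structure.

The generator emulates a pediatric psychopathology study: ordinal 0/1/2
item ratings driven by three latent dimensions (each split into correlated
sub-syndromes), adjustment covariates with site structure, and three
imaging-like feature tables with planted linear, nonlinear and null effects.
"""

import numpy as np

from dimbrain import ica_regime_config, make_cohort

cohort = make_cohort(ica_regime_config(n=500, seed=7))

print(f"subjects: {cohort.n_subjects}, items: {cohort.ratings.shape[1]}, "
      f"sites: {cohort.sites.nunique()}")
freq = np.bincount(cohort.ratings.to_numpy().ravel(), minlength=3) / cohort.ratings.size
print(f"rating frequencies 0/1/2: {np.round(freq, 3)}  (skewed toward 0, "
      "like parent-rated problem items)")
print("covariates:", ", ".join(cohort.covariates.columns))
for modality, feats in cohort.features.items():
    planted = (cohort.truth.effect_map[modality].abs().sum(axis=1) > 0).sum()
    print(f"modality {modality}: {feats.shape[1]} features, {planted} with planted effects")
print("\nThe `truth` attribute records the generating loadings, thresholds and")
print("effect maps, so downstream estimates can be scored against ground truth.")
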