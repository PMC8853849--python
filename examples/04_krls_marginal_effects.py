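"""Kernel-regularized least squares: average marginal effects with inference.

KRLS fits a Gaussian-kernel ridge surface (lambda chosen by closed-form
leave-one-out CV) and reports each predictor's average marginal effect —
the sample mean of the pointwise derivative — as a coefficient analogue.
Unlike a linear model it detects a symmetric quadratic effect whose Pearson
correlation with the outcome is ~0.
"""

import numpy as np

from dimbrain import average_marginal_effects, krls_fit
from dimbrain.krls import pointwise_derivatives

rng = np.random.default_rng(0)
n = 600
x = rng.normal(size=(n, 3))
y = 1.5 * x[:, 0] + x[:, 1] ** 2 + rng.normal(0, 0.3, n)

print(f"Pearson r of the quadratic predictor with y: "
      f"{np.corrcoef(x[:, 1], y)[0, 1]:+.3f}  (a linear screen would miss it)")

fit = krls_fit(x, y)
print(f"selected lambda = {fit.lam:.4g}, fitted R^2 = {fit.r_squared():.3f}")

ame = average_marginal_effects(fit)
print("\naverage marginal effects (original scale):")
print(ame[["estimate", "se", "t", "p"]].round(3))

d = pointwise_derivatives(fit)
print(f"\nquadratic predictor: AME = {ame['estimate'].iloc[1]:.2f} is small "
      f"relative to the mean |pointwise derivative| of {np.abs(d[:, 1]).mean():.2f}")
print("(positive and negative slopes of the symmetric surface nearly cancel).")
print("x3 is pure null: its AME is small with |t| < 2.")
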