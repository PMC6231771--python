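"""Hierarchical Bayesian regression of synchrony on its drivers.

Random intercepts for species and pixel; N(0, 1000) priors on the
coefficients and Uniform(0, 100) priors on the random-intercept
variances, sampled by Gibbs with slice updates for the variances.
All variables are 2-SD standardized so effect sizes are comparable.
"""

import warnings

import numpy as np
import pandas as pd

from phenosync import fit_hb_model
from phenosync.hbayes import HBData

# synthetic pixel-year table: synchrony responds to temperature, with
# species- and pixel-level baseline differences
rng = np.random.default_rng(11)
rows = []
for sp, sp_eff in zip("abcde", rng.normal(0, 0.8, 5)):
    for px, px_eff in zip(range(8), rng.normal(0, 0.8, 8)):
        for _ in range(12):
            temp = rng.uniform(2, 8)
            los = 3.0 + 0.5 * temp + sp_eff + px_eff + rng.normal(0, 0.7)
            rows.append({"los": los, "preseason_temp": temp,
                         "species": sp, "pixel": f"p{px}"})
table = pd.DataFrame(rows)

data = HBData.from_frame(table, "los", ["preseason_temp"],
                         species_col="species", pixel_col="pixel")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    post = fit_hb_model(data, chains=3, iterations=4000, burnin=1000, seed=0)

print(post.summary().loc[
    ["alpha", "beta[preseason_temp]", "sigma2", "tau2_species", "tau2_pixel"]
].round(3))
print(f"\nconverged (all Rhat <= 1.1): {post.converged}")
print("beta[preseason_temp] is the standardized temperature effect on "
      "synchrony; its 95% credible interval excluding 0 indicates a "
      "clear loss of synchrony with warming.")
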