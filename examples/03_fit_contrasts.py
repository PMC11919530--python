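"""Simultaneous Bayesian fit of the six nuisance parameters to 7 contrasts.

Generates synthetic reflectivity data at 5% relative noise from known
parameters, then samples the posterior with a seeded ensemble MCMC and
reports marginal modes, 95% credible intervals and per-contrast χ².
A short chain keeps the example quick; production fits default to
50 000 draws with the last 10 000 summarized.
"""

import warnings

import numpy as np

from mononr import MCMCSettings, fit_contrasts
from mononr.density import compute_nd_profiles, symmetrize_leaflets, water_volume_fraction
from mononr.synth import (
    MonolayerSpec,
    default_true_params,
    gen_monolayer_frames,
    gen_reflectivity_data,
)

profile = water_volume_fraction(symmetrize_leaflets(compute_nd_profiles(
    gen_monolayer_frames(MonolayerSpec(apl=50.0), n_frames=3, seed=1))))

truth = default_true_params()
q = np.geomspace(0.01, 0.6, 60)
data = gen_reflectivity_data(profile, noise_rel=0.05, q_grid=q, seed=7,
                             true_params=truth)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    summary = fit_contrasts(profile, data,
                            mcmc=MCMCSettings(n_draws=5000, n_walkers=16),
                            seed=3)

print(f"{'parameter':16s} {'truth':>10s} {'mode':>10s} {'95% CI':>24s}")
for name in ("roughness", "scale", "background_D2O", "background_ACMW",
             "sld_D2O", "sld_ACMW"):
    t = getattr(truth, name)
    m = getattr(summary.modes, name)
    lo, hi = summary.intervals[name]
    print(f"{name:16s} {t:10.3g} {m:10.3g} [{lo:10.3g}, {hi:10.3g}]")
print(f"\nχ² per contrast: " + ", ".join(
    f"{k}={v:.2f}" for k, v in summary.chi2_per_contrast.items()))
print(f"total χ² = {summary.chi2_total:.2f} "
      f"(≈ number of contrasts when the model matches at the noise level)")
# Each truth value falls inside its 95% credible interval for ~95% of noise
# realizations; the reduced χ² per contrast sits near 1 because the noise
# model is well specified.
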