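"""Build contrast-specific SLD profiles and compute specular reflectivity.

Shows the seven-contrast bookkeeping: deuterated pools swap b(H) → b(D),
the water fraction is multiplied by the bulk solvent SLD, the profile is
smeared by the capillary roughness, and the Abelès/Parratt recursion turns
it into R(q).
"""

import numpy as np

from mononr import (
    pure_water_sld,
    reflectivity,
    sld_from_nd,
    smear_profile,
    solve_acmw_fraction,
    standard_schemes,
)
from mononr.density import compute_nd_profiles, symmetrize_leaflets, water_volume_fraction
from mononr.synth import MonolayerSpec, gen_monolayer_frames

profile = water_volume_fraction(symmetrize_leaflets(compute_nd_profiles(
    gen_monolayer_frames(MonolayerSpec(apl=50.0), n_frames=5, seed=1))))

rho_d2o = pure_water_sld(heavy=True)
print(f"bulk D2O SLD: {rho_d2o:.3e} Å⁻²  (literature ≈ 6.35e-6)")
print(f"ACMW match point: {100 * solve_acmw_fraction():.1f}% D2O v/v")

q = np.geomspace(0.01, 0.6, 60)
qc = np.sqrt(16 * np.pi * rho_d2o)
print(f"critical edge of the D2O subphase: q_c = {qc:.4f} Å⁻¹\n")

print(f"{'contrast':10s} {'max SLD (Å⁻²)':>14s} {'R(q=0.05)':>10s}")
for scheme in standard_schemes():
    solvent = rho_d2o if scheme.solvent == "D2O" else 0.0
    sld = smear_profile(sld_from_nd(profile, scheme, solvent_sld=solvent), 3.0)
    R = reflectivity(sld, q).R
    print(f"{scheme.name:10s} {sld.rho.max():14.3e} {np.interp(0.05, q, R):10.2e}")
# Tail-deuterated contrasts peak near 8e-6 Å⁻² in the tail band; the
# hydrogenated lipid on D2O is dominated by the subphase, giving the
# largest low-q reflectivity through its critical edge.
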