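"""Structural and dynamic observables: |S_CD|, tail tilt, lateral diffusion.

Uses idealized all-trans chains with known geometry and mobility, so every
printed number has an exact or statistical expectation to compare against.
"""

from mononr import lateral_diffusion, order_parameter_scd, tail_tilt
from mononr.synth import gen_chain_frames

# perfectly upright all-trans chains: C–H ⊥ z → |S_CD| = 0.5, tilt = 0°
upright = gen_chain_frames(n_lipids=20, n_carbons=18, tilt_deg=0.0,
                           n_frames=3, seed=1)
print(f"upright chains:  |S_CD| = {order_parameter_scd(upright, range(4, 17)):.3f} "
      f"(exact 0.5), tilt = {tail_tilt(upright):.1f}° (exact 0)")

tilted = gen_chain_frames(n_lipids=20, n_carbons=18, tilt_deg=30.0,
                          n_frames=3, seed=2)
print(f"30°-tilted:      |S_CD| = {order_parameter_scd(tilted, range(4, 17)):.3f}, "
      f"tilt = {tail_tilt(tilted):.1f}° (exact 30)")

# chains performing a 2-D random walk with D = 0.8 Å²/ns ≡ 0.8e-7 cm²/s
mobile = gen_chain_frames(n_lipids=150, n_carbons=2, diffusion=0.8,
                          n_frames=300, dt=1.0, seed=3)
d_hat = lateral_diffusion(mobile, dt=1.0, lag_window=(0.05, 0.2))
print(f"random walk:     D = {d_hat:.3f} ×1e-7 cm²/s (generated 0.8)")
# Order and tilt follow the exact all-trans geometry; the diffusion estimate
# carries ~5% statistical error from the finite trajectory.
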