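# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Density profiles

Trajectory frames are binned into half-open slices [z, z+Δz), Δz = 0.5 Å by
default, spanning [0, L_z); atoms are wrapped into the primary cell before
binning (wrapping can be disabled, in which case an out-of-cell atom is an
error). Counts are divided by the slice volume A·Δz and averaged over
frames. Hydrogens are booked into substitution pools (`H_head`, `H_tail`,
`H_backbone`) rather than one H channel, because isotopic contrasts swap
whole pools at a time; for DSPC the pools are 70 tail H, 13 head (choline)
H and 5 glycerol-backbone H, the backbone never being substituted (so the
fully deuterated label counts 70 + 13 = 83 deuteriums). Water is counted as
molecules — one count per oxygen — because downstream it enters as a volume
fraction multiplied by a fitted bulk SLD, not atom by atom.

The double-monolayer cell is mirror-symmetric about the centre of its water
slab; the two leaflets are averaged by reflecting the profile about a
midpoint and averaging, the output covering one half-space re-originated at
the mirror plane. The midpoint defaults to the number-weighted centre of
the water distribution (the mirror plane is not otherwise defined by the
cell); off-grid reflections use linear interpolation. The water channel is
normalized by its mean over a bulk window — by default the 10 Å of water
farthest from the monolayer — and clipped into [0, 1] at output, the
clipping count being logged. All provided frames are averaged; a tail
window is the caller's slicing choice.

## SLD construction and contrasts

ρ(z) = Σᵢ nᵢ(z)·bᵢ + φ_w(z)·ρ_solvent, with b in Å (1 fm = 1e-5 Å). The
shipped bound coherent scattering lengths (fm) are H −3.739, D 6.671,
C 6.646, N 9.36, O 5.803, P 5.13; they are data, overridable by a text
table. Lipid and solvent contributions add without an excluded-volume
correction, consistent with summing number densities directly. The solvent
SLDs are *fit parameters*; the closed-form helpers (`pure_water_sld`,
`solve_acmw_fraction`) exist for validation, using H₂O/D₂O mass densities
0.997 and 1.105 g·cm⁻³. They give ρ(D₂O) = 6.361e-6 Å⁻² and an ACMW match
point of 8.07 ≈ 8.1 vol-% D₂O.

Capillary-wave smearing convolves the fully assembled ρ(z) with a
bin-integrated Gaussian kernel (erf differences), truncated at 6σ
(truncation error < 1e-9 of the kernel mass). Bin-integration makes the
convolution of a piecewise-constant profile exact: a step maps to ρ₀·Φ(z/σ)
with no sampling error. The output grid is extended by the kernel
half-width so smeared structure spilling past the input grid is retained —
cropping it would create a spurious step against the bulk medium.

## Reflectivity

Each grid bin is a uniform slab between semi-infinite fronting (air) and
backing (solvent); |r|² follows from the recursive Fresnel (Parratt)
solution, vectorized over q and, in the fitting path, over contrasts.
Leading/trailing slabs indistinguishable from the bulk media are trimmed
(they cannot scatter). q is in Å⁻¹ throughout. Slab discretization carries
an O((q·Δz)²) phase error — at q = 0.6 Å⁻¹ and Δz = 0.5 Å roughly 0.5% on
tiny reflectivities — which is far below the few-percent noise of monolayer
NR data; the kernel itself converges to < 1e-6 once Δz ≲ 0.005 Å.
Instrument resolution smearing (constant Δq/q) exists behind a flag and is
off by default.

The model for one contrast is R_model = scale·R + background, background
applied after scaling because incoherent background is not attenuated by
the direct-beam normalization that motivates the scale factor.

## The six-parameter fit

All contrasts at one surface pressure share: roughness σ, scale, one
background per solvent class (D₂O vs ACMW, reflecting their very different
incoherent levels), and the two bulk SLDs. Likelihood:
log L = −½ Σ_contrasts Σᵢ (R_exp − R_model)²/δR², i.e. Gaussian with the
experimental errors as weights (the natural reading of a χ²-weighted fit);
priors are independent uniforms. Default bounds: σ ∈ [1, 10] Å, scale ∈
[0.5, 1.5], backgrounds ∈ [0, 1e-4], SLD_D2O ∈ [6.0, 6.4]e-6 Å⁻²,
SLD_ACMW ∈ [−0.1, 0.3]e-6 Å⁻² — physically motivated brackets around the
known values.

Sampling uses emcee's affine-invariant ensemble (any seeded sampler meeting
the chain-length contract would do): 16 walkers, 50 000 total draws by
default, marginals summarized from the last 10 000 draws; when a shorter
chain is requested the window is capped at 80% of the chain so the first
fifth is always discarded as equilibration. Walkers start around a
preliminary bounded least-squares optimum (L-BFGS-B in unit-cube
coordinates, from the prior midpoint), jittered by 1% of each prior range.
Starting the ensemble at the prior midpoint instead leaves a short chain
still migrating toward the posterior when the summary window opens — the
recorded mode can then sit at twice the optimal χ² — so the optimizer start
is a correctness choice for short chains, not a speed-up.

Marginal modes use Freedman–Diaconis histograms (capped at 500 bins);
credible intervals are central 95%. A mode within 1% of a prior bound
triggers a warning. Reported χ² values are the per-contrast reduced
χ² = (1/(N−P))Σ(ΔR/δR)² at the marginal modes, P = 6, plus their sum; the
summary also carries the best single point seen anywhere (optimizer, modes,
or chain) with its χ², which in the perfect-data limit recovers the
generating parameters to machine level even though histogram modes carry
bin resolution.

The likelihood path caches the lipid-only SLD per deuteration scheme (the
water term is linear in the fitted solvent SLD) and trims the profile to
its structured support; it reproduces the public forward-model composition
to ~1e-13 relative.

## APL scan and isotherm

One independent seeded chain per area (seed offset by rank); best total χ²
recorded at the posterior mode; a least-squares polynomial of degree 2
(default) or 3 is fitted and its argmin located analytically from the real
roots of the derivative restricted to the scanned interval. Both degrees
are supported because quadratic and cubic fits are each defensible near a
minimum; the choice is logged. Without an interior minimum the better
endpoint is returned and flagged as extrapolation. Isotherm assembly sorts
(Π, APL*) by pressure and reports — without enforcing — monotonicity.

## Surface tension

Pressure-tensor scheme: γ = (L_z/2)·⟨P_zz − ½(P_xx+P_yy)⟩ over uniform
slices, the ½ because the cell contains two equivalent interfaces;
1 bar·Å = 1e-2 mN·m⁻¹. Wall scheme: γ = ⟨F_wall⟩/(4·L_Y), APL =
2·x_wall·L_Y/N. Unit declarations (bar/atm; pN, nN, kcal/mol/Å) are
mandatory in input headers and conversions centralized. Π = γ(aw) − γ(m)
with presets γ(aw) = 55 mN·m⁻¹ (typical of rigid water models) and 72
(experimental).

The width correction takes the 90%→10% decay distance of the water density
(linear interpolation of both crossings on the decaying side; for a
Φ-shaped decay the width is 2.563σ), fits L = a·exp(b·APL) + c (offset
fixable at zero; constant data short-circuit to b = 0), and multiplies the
surface pressure by L_ref/L_fit. The correction targets the pressure by
default; applying it to the tension before the Π subtraction is the same
arithmetic and is left to the caller. The low-coverage reference width is
an input, not recomputed.

## Observables

|S_CD| = |⟨(3cos²θ−1)/2⟩| over C–H bonds of tail carbons C4–C16 by default;
C–H pairs resolve from the atom-name convention C\<k\>\<chain\> /
H\<k\>\<chain\>\<a|b|c\> (no bond topology in the frame format) or from
explicit index pairs. Tail tilt uses the chain end-to-end vector (first to
last carbon), folded into [0°, 90°]; the end-to-end definition was chosen
over a principal-axis one for its robustness on short chains, and is what
the tests' closed-form geometries assume. Lateral diffusion: per-lipid
centre-of-mass MSD in x–y after periodic unwrapping, D = slope/4 over a lag
window of 10–50% of the span by default (standard practice: above the
rattling regime, below the noise-dominated tail); Å²·ns⁻¹ output,
numerically equal to 1e-7 cm²·s⁻¹. A log–log MSD slope above 1.25 flags
drift (slope 2) against diffusion (slope 1).

## Synthetic generators

`gen_monolayer_frames` emulates the study cell: 100 lipids per leaflet,
box area exactly N·APL, two leaflets mirrored through the centre of a
water slab, vacuum beyond the tails. Heads are a Gaussian band (centre
17 Å from the mirror plane, σ = 3 Å), the backbone a narrower band at
21 Å, tails a uniform band (23–39 Å) with 2 Å Gaussian jitter, water a
uniform core (±15 Å) with 2.5 Å edge jitter — uniform-plus-jitter gives the
erf-shaped edges real interfaces show. Atom counts per lipid are exactly
DSPC's C₄₄H₈₈NO₈P split into the substitution pools above. Water is one
site per molecule. These shapes resemble simulated monolayer profiles but
make no claim to force-field realism: there are no atom–atom correlations,
no chain connectivity, no interdigitation, and the bands do not deform
under compression beyond the box-area change — so passing tests demonstrate
the correctness of the analysis chain, not the realism of any simulation.

`gen_reflectivity_data` evaluates the exact forward model at the generating
parameters and applies multiplicative Gaussian noise: R_exp = R(1+ε),
ε ~ N(0, noise²), δR = noise·R (δR = R at zero noise so χ² stays defined).
Real counting errors are Poisson-derived; after instrument q-binning a
constant relative error is the conventional stand-in, and the difference
matters only at the lowest counts. Generating defaults: σ = 3 Å, scale 1,
backgrounds 2e-6 (D₂O) and 8e-6 (ACMW), SLD_D2O = 6.36e-6 Å⁻²,
SLD_ACMW = 0, noise 5%, 60 log-spaced q points in 0.01–0.6 Å⁻¹ — plausible
monolayer-NR values throughout.

`gen_pressure_profile` shapes the tensor anisotropy as two interface peaks
scaled so the tension estimate is exact at zero noise; component noise is
Gaussian and leaves the (linear) estimator unbiased. `gen_wall_trace` makes
a force series with an exact mean.

## Problem sizes and test design

The test suite's stochastic studies use the synthetic cell at APL 50 Å²
averaged over 3 frames, 7 contrasts × 60 q points, and 5 000-draw chains:
the parameter-recovery study runs 20 seeded replicates and checks that each
parameter's 95% credible interval covers the truth in at least 90% of them
(counted per parameter; demanding all six jointly would fail even for a
perfect sampler, since 0.95⁶ ≈ 0.74). The area scan study uses five
candidate areas (46–54 Å²) with data generated at 50 Å². These sizes hold
the full suite to roughly a quarter hour on one core while keeping every
statistical margin at 3σ or wider.

## Known limitations

- No instrument resolution by default; no polarization, absorption or
  off-specular scattering.
- No exchangeable-hydrogen modelling (DSPC has no labile H) and no X-ray
  SLDs.
- Non-orthorhombic boxes, trajectory alignment and cross-frame unwrapping
  (beyond x–y for diffusion) are out of scope.
- Density profiles are not interpolated between simulated areas; the scan
  is only as fine as the compression series.
- The wall-scheme number densities are known to fluctuate at the headgroups
  under stepwise wall placement; the package computes the tension and APL
  arithmetic for that scheme but fits reflectivity from the
  gradual-compression profiles.
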