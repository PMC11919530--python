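"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the study system — a double DSPC monolayer cell with
a sandwiched water slab — closely enough to exercise every stage of the
analysis without any trajectory download: layered monolayer configurations
at a prescribed area per lipid, multi-contrast reflectivity data with scale,
background and noise, and pressure-tensor profiles with a known surface
tension.  Everything is bit-reproducible under a fixed seed.

The synthetic lipid carries exactly DSPC's atom inventory (C₄₄H₈₈NO₈P) with
the hydrogen substitution pools H_tail = 70, H_head = 13 and 5 backbone
hydrogens, so the deuteration labels D83 = 70 + 13, D70 and D13 come out
right by construction.  z-distributions are simple parametric bands (heads
Gaussian, tails and water uniform slabs with Gaussian edge jitter) chosen to
resemble simulated monolayer profiles, not to reproduce any force field.
Water is represented by one site per molecule, since only the molecule count
enters the analysis (the water channel becomes a volume fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import DensityProfile
from .fit import FitParameters
from .frames import Frame
from .reflect import ReflectivityCurve
from .contrast import ContrastScheme, ScatteringLengthTable, standard_schemes
from .tension import PressureProfile
from . import units

#: per-lipid atom inventory: species channel → count (sums to C44 H88 N O8 P)
DSPC_ATOM_COUNTS = {
    "tail": {"C": 34, "H_tail": 70},
    "head": {"C": 5, "N": 1, "O": 4, "P": 1, "H_head": 13},
    "backbone": {"C": 5, "O": 4, "H_backbone": 5},
}

WATER_NUMBER_DENSITY = 0.0333  # molecules·Å⁻³, bulk liquid water


@dataclass
class MonolayerSpec:
    """Geometry of a synthetic double-monolayer cell at a prescribed APL.

    Distances are measured from the cell's mirror plane (the centre of the
    water slab); the two leaflets are generated as exact mirror images in
    distribution.  Defaults give a DSPC-like monolayer at full coverage.
    """

    apl: float = 50.0               # Å² per lipid
    n_lipids: int = 100             # per leaflet
    water_half_thickness: float = 15.0   # Å, uniform water core half-width
    water_edge_width: float = 2.5   # Å, Gaussian jitter of the water edge
    head_center: float = 17.0       # Å from mirror plane
    head_width: float = 3.0         # Å (Gaussian σ)
    backbone_center: float = 21.0   # Å
    backbone_width: float = 2.0     # Å
    tail_start: float = 23.0        # Å, start of the tail band
    tail_length: float = 16.0       # Å, uniform band length
    tail_edge_width: float = 2.0    # Å, Gaussian jitter of tail positions
    vacuum: float = 30.0            # Å of vacuum beyond the tails, per side

    def __post_init__(self):
        if self.apl <= 0 or self.n_lipids <= 0:
            raise ValueError("APL and lipid count must be positive")
        if self.head_center <= self.water_half_thickness - 3 * self.water_edge_width:
            raise ValueError("head band overlaps the bulk water core")
        if self.tail_start <= self.head_center:
            raise ValueError("tail band must lie beyond the head band")

    @property
    def area(self) -> float:
        """Box area L_x·L_y = N·APL (exact, by construction)."""
        return self.n_lipids * self.apl

    @property
    def box(self) -> np.ndarray:
        L = np.sqrt(self.area)
        lz = 2.0 * (self.tail_start + self.tail_length + self.vacuum)
        return np.array([L, L, lz])


def _sample_lipid_z(spec: MonolayerSpec, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-region z offsets (distance from the mirror plane) for n lipids."""
    out = {}
    counts = {region: sum(c.values()) for region, c in DSPC_ATOM_COUNTS.items()}
    out["head"] = rng.normal(spec.head_center, spec.head_width, size=(n, counts["head"]))
    out["backbone"] = rng.normal(spec.backbone_center, spec.backbone_width, size=(n, counts["backbone"]))
    out["tail"] = (
        spec.tail_start
        + rng.uniform(0.0, spec.tail_length, size=(n, counts["tail"]))
        + rng.normal(0.0, spec.tail_edge_width, size=(n, counts["tail"]))
    )
    return out


def gen_monolayer_frames(
    spec: MonolayerSpec | None = None,
    n_frames: int = 5,
    seed: int = 0,
) -> list[Frame]:
    """Generate frames of two mirrored leaflets sandwiching a water slab.

    Atom z positions are drawn independently from the per-region
    distributions of ``spec`` (heads Gaussian, tails a jittered uniform
    band), x–y uniformly over the box; the lower leaflet mirrors the upper
    through the water mid-plane.  Water molecules fill a uniform core with
    Gaussian-jittered edges, giving the smooth sigmoidal decay real
    interfaces show.
    """
    spec = spec or MonolayerSpec()
    rng = np.random.default_rng(seed)
    box = spec.box
    z_mid = box[2] / 2.0

    # fixed per-lipid label arrays, region by region
    region_labels = []
    for region, counts in DSPC_ATOM_COUNTS.items():
        group = "tail" if region == "tail" else "head"
        # backbone atoms ride with the head group for head/tail bookkeeping,
        # but keep their own hydrogen class (never substituted)
        for species, cnt in counts.items():
            elem = "H" if species.startswith("H_") else species
            hcl = species if species.startswith("H_") else "none"
            region_labels += [(region, elem, group, hcl)] * cnt
    atoms_per_lipid = len(region_labels)
    lipid_elements = np.array([r[1] for r in region_labels])
    lipid_groups = np.array([r[2] for r in region_labels])
    lipid_hclass = np.array([r[3] for r in region_labels])
    region_of_atom = np.array([r[0] for r in region_labels])

    n_water = int(round(2.0 * spec.water_half_thickness * spec.area * WATER_NUMBER_DENSITY))
    frames = []
    for _ in range(n_frames):
        pos_blocks, elem_blocks, group_blocks, hcl_blocks, mol_blocks = [], [], [], [], []
        mol_offset = 0
        for leaflet_sign in (+1.0, -1.0):
            z_by_region = _sample_lipid_z(spec, spec.n_lipids, rng)
            z = np.empty((spec.n_lipids, atoms_per_lipid))
            for region in DSPC_ATOM_COUNTS:
                z[:, region_of_atom == region] = z_by_region[region]
            z = z_mid + leaflet_sign * z
            xy = rng.uniform(0.0, [box[0], box[1]], size=(spec.n_lipids, atoms_per_lipid, 2))
            pos = np.concatenate([xy, z[..., None]], axis=2).reshape(-1, 3)
            pos_blocks.append(pos)
            elem_blocks.append(np.tile(lipid_elements, spec.n_lipids))
            group_blocks.append(np.tile(lipid_groups, spec.n_lipids))
            hcl_blocks.append(np.tile(lipid_hclass, spec.n_lipids))
            mol_blocks.append(
                np.repeat(np.arange(spec.n_lipids) + mol_offset, atoms_per_lipid)
            )
            mol_offset += spec.n_lipids

        zw = z_mid + rng.uniform(
            -spec.water_half_thickness, spec.water_half_thickness, size=n_water
        ) + rng.normal(0.0, spec.water_edge_width, size=n_water)
        xyw = rng.uniform(0.0, [box[0], box[1]], size=(n_water, 2))
        pos_blocks.append(np.column_stack([xyw, zw]))
        elem_blocks.append(np.full(n_water, "O"))
        group_blocks.append(np.full(n_water, "water"))
        hcl_blocks.append(np.full(n_water, "none"))
        mol_blocks.append(np.arange(n_water) + mol_offset)

        frames.append(
            Frame(
                positions=np.concatenate(pos_blocks),
                elements=np.concatenate(elem_blocks),
                groups=np.concatenate(group_blocks),
                hclass=np.concatenate(hcl_blocks),
                mol_index=np.concatenate(mol_blocks),
                box=box.copy(),
            )
        )
    return frames


def gen_reflectivity_data(
    profile: DensityProfile,
    schemes: list[ContrastScheme] | None = None,
    true_params: FitParameters | None = None,
    noise_rel: float = 0.05,
    q_grid: np.ndarray | None = None,
    seed: int = 0,
    table: ScatteringLengthTable | None = None,
) -> dict[ContrastScheme, ReflectivityCurve]:
    """Synthetic multi-contrast reflectivity data from a density profile.

    For each scheme the exact forward model is evaluated at ``true_params``
    and degraded with multiplicative Gaussian noise:
    R_exp = R_model·(1+ε), ε ~ N(0, noise_rel²), δR = noise_rel·R_model.
    Real counting errors are Poisson-derived; after the instrument's q-binning
    a constant relative error is the conventional stand-in.  At zero noise the
    quoted errors fall back to δR = R_model (unit relative weight) so χ²
    stays defined.
    """
    from .fit import forward_model  # deferred: fit imports this module's types

    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    schemes = schemes if schemes is not None else standard_schemes()
    true_params = true_params or default_true_params()
    q = q_grid if q_grid is not None else default_q_grid()
    rng = np.random.default_rng(seed)
    datasets = {}
    for scheme in schemes:
        model = forward_model(profile, scheme, true_params, q, table)
        sigma = (noise_rel if noise_rel > 0 else 1.0) * model.R
        R_exp = model.R * (1.0 + noise_rel * rng.standard_normal(len(q)))
        datasets[scheme] = ReflectivityCurve(
            q, np.clip(R_exp, 0.0, None), dR=sigma, name=scheme.name
        )
    return datasets


def default_q_grid(n: int = 60, q_min: float = 0.01, q_max: float = 0.6) -> np.ndarray:
    """Log-spaced momentum-transfer grid over the measured range (Å⁻¹)."""
    return np.geomspace(q_min, q_max, n)


def default_true_params() -> FitParameters:
    """Generating truth for synthetic datasets: plausible monolayer values."""
    return FitParameters(
        roughness=3.0,          # Å, typical capillary-wave roughness
        scale=1.0,
        background_D2O=2.0e-6,  # D₂O scatters little incoherently
        background_ACMW=8.0e-6, # H-rich subphase → higher background
        sld_D2O=6.36e-6,        # Å⁻², pure D₂O
        sld_ACMW=0.0,           # matched to air by construction
    )


def gen_pressure_profile(
    gamma_true: float,
    lz: float = 160.0,
    n_slices: int = 160,
    noise: float = 0.0,
    seed: int = 0,
) -> PressureProfile:
    """Pressure-tensor profile whose tension estimate equals ``gamma_true``.

    The anisotropy P_zz − ½(P_xx+P_yy) is shaped as two Gaussian interface
    peaks (the cell's two monolayers) scaled so its slice average reproduces
    ``gamma_true`` (mN·m⁻¹) exactly at zero noise; Gaussian noise of the
    given width (bar) is then added independently to each component.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    rng = np.random.default_rng(seed)
    dz = lz / n_slices
    z = (np.arange(n_slices) + 0.5) * dz
    if gamma_true == 0.0:
        bracket = np.zeros(n_slices)
    else:
        shape = np.exp(-0.5 * ((z - 0.3 * lz) / (0.05 * lz)) ** 2) + np.exp(
            -0.5 * ((z - 0.7 * lz) / (0.05 * lz)) ** 2
        )
        target_mean = gamma_true / (0.5 * lz * units.BAR_ANGSTROM_TO_MN_PER_M)
        bracket = shape * (target_mean / shape.mean())
    pzz = np.ones(n_slices)  # 1 bar normal pressure
    pxx = pzz - bracket
    pyy = pzz - bracket
    if noise > 0:
        pxx = pxx + rng.normal(0.0, noise, n_slices)
        pyy = pyy + rng.normal(0.0, noise, n_slices)
        pzz = pzz + rng.normal(0.0, noise, n_slices)
    return PressureProfile(z=z, pxx=pxx, pyy=pyy, pzz=pzz, lz=lz, unit="bar")


def gen_wall_trace(
    mean_force: float,
    n_samples: int = 1000,
    noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Wall-force time series with the given mean (units of the caller)."""
    rng = np.random.default_rng(seed)
    trace = np.full(n_samples, float(mean_force))
    if noise > 0:
        jitter = rng.normal(0.0, noise, n_samples)
        trace = trace + jitter - jitter.mean()  # keep the mean exact
    return trace


def gen_chain_frames(
    n_lipids: int = 16,
    n_carbons: int = 18,
    tilt_deg: float = 0.0,
    diffusion: float = 0.0,
    n_frames: int = 5,
    dt: float = 1.0,
    box: float = 200.0,
    seed: int = 0,
) -> list[Frame]:
    """Idealized all-trans chains for exercising the structural observables.

    Each lipid is one straight chain of ``n_carbons`` carbons tilted by
    ``tilt_deg`` from z, every carbon carrying two hydrogens perpendicular
    to the chain axis (named C<k>A / H<k>Aa / H<k>Ab so the observables can
    pair them).  Chain anchors perform an x–y random walk with per-axis step
    variance 2·diffusion·dt, so the generating self-diffusion coefficient is
    ``diffusion`` (Å²·ns⁻¹).
    """
    rng = np.random.default_rng(seed)
    spacing = 1.27  # Å, all-trans C–C projection
    tilt = np.radians(tilt_deg)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    # two C–H unit vectors perpendicular to the chain axis
    perp1 = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    perp2 = np.array([0.0, 1.0, 0.0])
    ch_len = 1.09

    names, elements, groups, hclass, mol_index = [], [], [], [], []
    template = []  # offsets relative to the chain anchor
    for k in range(1, n_carbons + 1):
        base = axis * spacing * (k - 1)
        template.append(base)
        names.append(f"C{k}A")
        elements.append("C")
        groups.append("tail")
        hclass.append("none")
        for suffix, perp in (("a", perp1), ("b", perp2)):
            template.append(base + ch_len * perp)
            names.append(f"H{k}A{suffix}")
            elements.append("H")
            groups.append("tail")
            hclass.append("H_tail")
    template = np.array(template)
    per_lipid = len(template)
    names = np.tile(np.array(names), n_lipids)
    elements = np.tile(np.array(elements), n_lipids)
    groups = np.tile(np.array(groups), n_lipids)
    hclass = np.tile(np.array(hclass), n_lipids)
    mol_index = np.repeat(np.arange(n_lipids), per_lipid)

    anchors = rng.uniform(0.2 * box, 0.8 * box, size=(n_lipids, 2))
    z0 = box / 2.0
    frames = []
    step_sd = np.sqrt(2.0 * diffusion * dt)
    for t in range(n_frames):
        if t > 0 and diffusion > 0:
            anchors = anchors + rng.normal(0.0, step_sd, size=anchors.shape)
        pos = np.empty((n_lipids * per_lipid, 3))
        for m in range(n_lipids):
            block = template.copy()
            block[:, 0] += anchors[m, 0]
            block[:, 1] += anchors[m, 1]
            block[:, 2] += z0
            pos[m * per_lipid:(m + 1) * per_lipid] = block
        frames.append(
            Frame(
                positions=pos,
                elements=elements,
                groups=groups,
                hclass=hclass,
                mol_index=mol_index,
                box=np.array([box, box, box]),
                names=names,
            )
        )
    return frames
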