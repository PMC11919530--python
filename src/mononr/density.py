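"""Number-density profiles along the interface normal.

The simulation cell holds two monolayers arranged normal to z that sandwich a
water slab; reflectivity averages over the x–y plane, so the only structure
that matters is the laterally averaged composition along z.  The cell is cut
into thin slices (0.5 Å by default), atoms are counted per slice and species,
and counts are divided by the slice volume and averaged over frames.

Hydrogens are counted into their substitution pool (``H_head`` / ``H_tail`` /
``H_backbone``) rather than a single H channel, because isotopic contrasts
swap the scattering length of whole pools at a time.  Water is counted as
molecules (one count per oxygen) and later normalized into a volume fraction,
since in the scattering model the solvent enters as (volume fraction) ×
(fitted bulk SLD) rather than atom by atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frames import LIPID_SPECIES, Frame

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.5  # Å


@dataclass
class DensityProfile:
    """Per-species number densities on a uniform z grid.

    ``densities`` maps a species channel (C, N, O, P, H_head, H_tail,
    H_backbone) to atoms·Å⁻³ per bin; ``water`` is the water *molecule*
    number density until :func:`water_volume_fraction` rescales it to a
    dimensionless volume fraction (``water_is_fraction`` records which).
    """

    z: np.ndarray                      # bin centres, Å, uniform spacing
    densities: dict[str, np.ndarray]   # species → atoms·Å⁻³
    water: np.ndarray                  # molecules·Å⁻³ or volume fraction
    area: float                        # L_x·L_y, Å²
    n_frames: int
    water_is_fraction: bool = False

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        self.densities = {k: np.asarray(v, dtype=float) for k, v in self.densities.items()}
        if len(self.z) < 1:
            raise ValueError("empty z grid")
        if len(self.z) > 1:
            dz = np.diff(self.z)
            if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-12):
                raise ValueError("z grid must be uniform")
        for name, arr in self.densities.items():
            if arr.shape != self.z.shape:
                raise ValueError(f"species {name!r} shape mismatch")
            if np.any(arr < -1e-12):
                raise ValueError(f"negative density in species {name!r}")
        if self.water.shape != self.z.shape:
            raise ValueError("water channel shape mismatch")

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else np.nan

    def species_count(self, species: str) -> float:
        """Mean per-frame atom count of ``species``: Σ ρ·A·Δz."""
        return float(np.sum(self.densities[species]) * self.area * self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        data = {"z": self.z}
        data.update({k: v for k, v in self.densities.items()})
        data["water"] = self.water
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bin_width={self.bin_width:.17g} area={self.area:.17g} "
                     f"n_frames={self.n_frames} water_is_fraction={int(self.water_is_fraction)}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "DensityProfile":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing metadata header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            df = pd.read_csv(fh)
        densities = {c: df[c].to_numpy() for c in df.columns if c not in ("z", "water")}
        return cls(
            z=df["z"].to_numpy(),
            densities=densities,
            water=df["water"].to_numpy(),
            area=float(meta["area"]),
            n_frames=int(meta["n_frames"]),
            water_is_fraction=bool(int(meta.get("water_is_fraction", 0))),
        )


def _species_masks(frame: Frame) -> dict[str, np.ndarray]:
    """Boolean per-atom masks for every species channel plus water molecules."""
    masks = {}
    is_water = frame.groups == "water"
    is_h = frame.elements == "H"
    for elem in ("C", "N", "O", "P"):
        masks[elem] = (frame.elements == elem) & ~is_water
    for hcl in ("H_head", "H_tail", "H_backbone"):
        masks[hcl] = frame.hclass == hcl
    # one count per water molecule, via its oxygen
    masks["water"] = is_water & (frame.elements == "O")
    stray = is_water & is_h & (frame.hclass != "H_water")
    if stray.any():
        raise ValueError("water hydrogen not tagged H_water")
    return masks


def compute_nd_profiles(
    frames: Sequence[Frame] | Iterable[Frame],
    bin_width: float = DEFAULT_BIN_WIDTH,
    *,
    wrap: bool = True,
) -> DensityProfile:
    """Average per-species number-density profiles over trajectory frames.

    Each frame's atoms are binned into half-open slices [z, z+Δz) spanning
    [0, L_z); counts are divided by the slice volume A·Δz and the per-frame
    histograms averaged.  All frames must share box dimensions (the fixed-area
    ensemble guarantees L_x·L_y; L_z must agree for a common grid).

    With ``wrap`` (default) atoms are wrapped into the primary cell before
    binning; with ``wrap=False`` an out-of-cell atom is an error.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    box = frames[0].box
    n_bins = int(np.ceil(box[2] / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    area = frames[0].area
    species = list(LIPID_SPECIES) + ["water"]
    sums = {s: np.zeros(n_bins) for s in species}
    counts0 = {s: None for s in species}

    for frame in frames:
        if not np.allclose(frame.box, box, rtol=1e-9):
            raise ValueError("frames disagree on box dimensions")
        masks = _species_masks(frame)
        if counts0["C"] is None:
            counts0 = {s: int(masks[s].sum()) for s in species}
        else:
            for s in species:
                if int(masks[s].sum()) != counts0[s]:
                    raise ValueError(f"species inventory changed across frames ({s})")
        zpos = frame.positions[:, 2]
        if wrap:
            zpos = np.mod(zpos, box[2])
        elif np.any((zpos < 0) | (zpos >= box[2])):
            raise ValueError("atom outside [0, L_z) and wrapping disabled")
        for s in species:
            hist, _ = np.histogram(zpos[masks[s]], bins=edges)
            sums[s] += hist

    volume = area * bin_width
    n_frames = len(frames)
    densities = {s: sums[s] / (volume * n_frames) for s in LIPID_SPECIES}
    water = sums["water"] / (volume * n_frames)
    z_centres = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        z=z_centres, densities=densities, water=water, area=area, n_frames=n_frames
    )


def _reflect_average(z_out: np.ndarray, z: np.ndarray, values: np.ndarray, midpoint: float) -> np.ndarray:
    """(f(mid+d) + f(mid−d))/2 sampled at z_out, linear interpolation off-grid."""
    up = np.interp(z_out, z, values, left=values[0], right=values[-1])
    down = np.interp(2.0 * midpoint - z_out, z, values, left=values[0], right=values[-1])
    return 0.5 * (up + down)


def symmetrize_leaflets(profile: DensityProfile, midpoint: float | None = None) -> DensityProfile:
    """Average the two leaflets of a double-monolayer cell into one profile.

    The cell holds mirror-image monolayers on either side of the water slab;
    averaging the profile with its reflection about the mirror plane halves
    the statistical noise.  The output covers the half-space z ≥ midpoint
    (water side at the origin, one monolayer, then vacuum).

    ``midpoint`` defaults to the number-weighted centre of the water
    distribution.
    """
    if midpoint is None:
        midpoint = leaflet_midpoint(profile)
    if not (profile.z[0] <= midpoint <= profile.z[-1]):
        raise ValueError(f"midpoint {midpoint} outside z grid [{profile.z[0]}, {profile.z[-1]}]")
    dz = profile.bin_width
    n_half = int(np.floor((profile.z[-1] - midpoint) / dz)) + 1
    z_out = midpoint + dz * np.arange(n_half)
    densities = {
        s: _reflect_average(z_out, profile.z, v, midpoint) for s, v in profile.densities.items()
    }
    water = _reflect_average(z_out, profile.z, profile.water, midpoint)
    return DensityProfile(
        z=z_out - midpoint,  # re-origin at the mirror plane
        densities=densities,
        water=water,
        area=profile.area,
        n_frames=profile.n_frames,
        water_is_fraction=profile.water_is_fraction,
    )


def leaflet_midpoint(profile: DensityProfile) -> float:
    """Number-weighted centre of the water distribution."""
    w = profile.water
    total = w.sum()
    if total <= 0:
        raise ValueError("no water density; cannot locate midpoint")
    return float(np.sum(profile.z * w) / total)


def water_volume_fraction(
    profile: DensityProfile,
    bulk_window: tuple[float, float] | None = None,
    *,
    bulk_span: float = 10.0,
) -> DensityProfile:
    """Normalize the water channel to a volume fraction.

    The water number density is divided by its mean over a bulk window where
    the water is at its bulk value, so the channel runs from ≈1 in bulk to 0
    on the vacuum side.  ``bulk_window`` is a (z_lo, z_hi) interval; if None,
    the ``bulk_span`` Å of the water slab farthest from the monolayer are
    used (for a symmetrized profile that is the start of the grid).  Values
    above 1 from noise are clipped to [0, 1] with the clipping logged.
    """
    if profile.water_is_fraction:
        raise ValueError("water channel already normalized")
    if bulk_window is None:
        bulk_window = (float(profile.z[0]), float(profile.z[0]) + bulk_span)
    lo, hi = bulk_window
    sel = (profile.z >= lo) & (profile.z <= hi)
    if sel.sum() < 5:
        raise ValueError("bulk window must span at least 5 bins")
    bulk = profile.water[sel].mean()
    if bulk <= 0:
        raise ValueError("zero water density in bulk window")
    frac = profile.water / bulk
    n_clip = int(np.sum((frac > 1.0) | (frac < 0.0)))
    if n_clip:
        logger.info("water volume fraction: clipped %d of %d bins into [0, 1]", n_clip, len(frac))
    frac = np.clip(frac, 0.0, 1.0)
    return replace(profile, water=frac, water_is_fraction=True)
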