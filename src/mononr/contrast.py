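"""Scattering-length-density profiles under isotopic contrast variation.

The SLD at depth z is the sum over species of (number density × bound
coherent scattering length).  Deuteration schemes swap the scattering length
of the head and/or tail hydrogen pools from b(H) to b(D); backbone hydrogens
are never substituted.  Water enters as a volume fraction multiplied by the
bulk solvent SLD, which is a fit parameter (D₂O or air-contrast matched
water, ACMW).  Capillary waves smear the profile as seen by the neutron
beam; the model is convolved with a Gaussian whose width ("substrate
roughness") is also fitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.special import ndtr

from . import units
from .density import DensityProfile

#: bound coherent scattering lengths, fm
DEFAULT_SCATTERING_LENGTHS = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
}

# standard liquid mass densities near room temperature, g·cm⁻³
H2O_DENSITY = 0.997
D2O_DENSITY = 1.105
H2O_MOLAR_MASS = 18.0153
D2O_MOLAR_MASS = 20.0276


class ScatteringLengthTable:
    """Isotope/element symbol → bound coherent scattering length b (fm).

    Immutable once constructed; a fit must not change scattering lengths
    midway.  H must be negative and D positive — the sign difference is the
    entire basis of contrast variation.
    """

    def __init__(self, lengths: dict[str, float] | None = None):
        table = dict(DEFAULT_SCATTERING_LENGTHS if lengths is None else lengths)
        if "H" in table and table["H"] >= 0:
            raise ValueError("b(H) must be negative")
        if "D" in table and table["D"] <= 0:
            raise ValueError("b(D) must be positive")
        self._table = table

    def b_fm(self, species: str) -> float:
        try:
            return self._table[species]
        except KeyError:
            raise KeyError(f"species {species!r} missing from scattering-length table") from None

    def b_angstrom(self, species: str) -> float:
        return self.b_fm(species) * units.FM_TO_ANGSTROM

    def __contains__(self, species: str) -> bool:
        return species in self._table

    @classmethod
    def from_text(cls, text: str) -> "ScatteringLengthTable":
        lengths = {}
        for line in io.StringIO(text):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            sym, b = line.split()
            lengths[sym] = float(b)
        return cls(lengths)

    @classmethod
    def read(cls, path) -> "ScatteringLengthTable":
        with open(path) as fh:
            return cls.from_text(fh.read())

    @classmethod
    def shipped(cls) -> "ScatteringLengthTable":
        text = resources.files("mononr.data").joinpath("scattering_lengths.txt").read_text()
        return cls.from_text(text)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# symbol b_fm (bound coherent scattering length)\n")
            for sym, b in self._table.items():
                fh.write(f"{sym} {b:.6g}\n")

    def molecule_sld(self, counts: dict[str, int], number_density_A3: float) -> float:
        """SLD (Å⁻²) of a molecular liquid from per-molecule atom counts."""
        b = sum(n * self.b_angstrom(sym) for sym, n in counts.items())
        return b * number_density_A3


@dataclass(frozen=True)
class ContrastScheme:
    """One deuteration/solvent combination, e.g. tail-deuterated lipid on D₂O."""

    name: str
    head_deuterated: bool
    tail_deuterated: bool
    solvent: str  # "D2O" or "ACMW"

    def __post_init__(self):
        if self.solvent not in ("D2O", "ACMW"):
            raise ValueError(f"unknown solvent {self.solvent!r}")


def standard_schemes() -> list[ContrastScheme]:
    """The seven measured contrasts: D83/D70/D13 on both solvents, H on D₂O only.

    The labels count substitutable hydrogens of DSPC: D83 = fully deuterated
    (70 tail + 13 head), D70 = tail only, D13 = head only.
    """
    out = []
    for label, head, tail in (("D83", True, True), ("D70", False, True), ("D13", True, False)):
        for solvent in ("D2O", "ACMW"):
            out.append(ContrastScheme(f"{label}-{solvent}", head, tail, solvent))
    out.append(ContrastScheme("H-D2O", False, False, "D2O"))
    return out


@dataclass
class SLDProfile:
    """ρ(z) in Å⁻² on a uniform grid, with semi-infinite fronting/backing."""

    z: np.ndarray
    rho: np.ndarray
    fronting: float = 0.0   # air
    backing: float = 0.0    # bulk solvent

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape:
            raise ValueError("z/rho shape mismatch")
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("non-finite SLD")
        if len(self.z) > 1:
            dz = np.diff(self.z)
            if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-12):
                raise ValueError("z grid must be uniform")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else np.nan

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fronting={self.fronting:.17g} backing={self.backing:.17g}\n")
            fh.write("z,rho\n")
            for z, r in zip(self.z, self.rho):
                fh.write(f"{z:.10g},{r:.17g}\n")

    @classmethod
    def read_csv(cls, path) -> "SLDProfile":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header[1:].split())
            df = pd.read_csv(fh)
        return cls(df["z"].to_numpy(), df["rho"].to_numpy(),
                   float(meta["fronting"]), float(meta["backing"]))


def sld_from_nd(
    profile: DensityProfile,
    scheme: ContrastScheme,
    table: ScatteringLengthTable | None = None,
    solvent_sld: float = 0.0,
) -> SLDProfile:
    """Assemble ρ(z) = Σᵢ nᵢ(z)·bᵢ + φ_water(z)·ρ_solvent for one contrast.

    ``profile`` must carry a normalized water volume fraction and is expected
    in symmetrized half-space orientation (water at low z).  The output is
    flipped so that air (fronting) is at low z and solvent (backing) at high
    z, the orientation the reflectivity kernel expects.
    """
    if table is None:
        table = ScatteringLengthTable()
    if not profile.water_is_fraction:
        raise ValueError("water channel must be a volume fraction (run water_volume_fraction)")
    if not np.isfinite(solvent_sld):
        raise ValueError("solvent_sld must be finite")

    substitution = {
        "H_head": "D" if scheme.head_deuterated else "H",
        "H_tail": "D" if scheme.tail_deuterated else "H",
        "H_backbone": "H",
    }
    rho = np.zeros_like(profile.z)
    for species, dens in profile.densities.items():
        sym = substitution.get(species, species)
        rho += dens * table.b_angstrom(sym)
    rho += profile.water * solvent_sld

    # flip: water side (low z in the symmetrized profile) becomes the backing
    return SLDProfile(
        z=profile.z.copy(),
        rho=rho[::-1].copy(),
        fronting=0.0,
        backing=float(solvent_sld),
    )


def pure_water_sld(
    table: ScatteringLengthTable | None = None,
    *,
    heavy: bool,
    mass_density: float | None = None,
) -> float:
    """SLD (Å⁻²) of pure D₂O (heavy=True) or H₂O at standard density."""
    if table is None:
        table = ScatteringLengthTable()
    if heavy:
        rho_m = D2O_DENSITY if mass_density is None else mass_density
        n = units.number_density_per_A3(rho_m, D2O_MOLAR_MASS)
        return table.molecule_sld({"D": 2, "O": 1}, n)
    rho_m = H2O_DENSITY if mass_density is None else mass_density
    n = units.number_density_per_A3(rho_m, H2O_MOLAR_MASS)
    return table.molecule_sld({"H": 2, "O": 1}, n)


def solve_acmw_fraction(
    table: ScatteringLengthTable | None = None,
    densities: tuple[float, float] = (H2O_DENSITY, D2O_DENSITY),
) -> float:
    """Volume fraction φ of D₂O at which φ·ρ_D2O + (1−φ)·ρ_H2O = 0.

    Air-contrast matched water: the mixture whose SLD equals that of air.
    Exists only because ρ(H₂O) < 0 < ρ(D₂O).  Validation helper — in fits the
    solvent SLDs are free parameters, not computed constants.
    """
    d_h2o, d_d2o = densities
    if d_h2o < 0 or d_d2o <= 0:
        raise ValueError("mass densities must be positive")
    rho_h = pure_water_sld(table, heavy=False, mass_density=d_h2o)
    rho_d = pure_water_sld(table, heavy=True, mass_density=d_d2o)
    if rho_h * rho_d > 0:
        raise ValueError("H2O and D2O SLDs have the same sign; no zero crossing")
    if rho_d == rho_h:
        raise ValueError("degenerate SLDs")
    return float(-rho_h / (rho_d - rho_h))


def smear_profile(sld: SLDProfile, sigma: float) -> SLDProfile:
    """Convolve ρ(z) with a unit-area Gaussian of standard deviation ``sigma``.

    Models capillary-wave roughness averaged over the beam footprint.  The
    profile is padded with its fronting/backing constants over 6σ each side,
    and the kernel uses bin-integrated Gaussian weights (erf differences), so
    a step input reproduces ρ₀·Φ(z/σ) exactly up to truncation.  The output
    grid is extended by the kernel half-width so smeared structure spilling
    past the input grid is retained rather than cropped.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0 or len(sld.z) < 2:
        return replace(sld, z=sld.z.copy(), rho=sld.rho.copy())
    dz = sld.dz
    kernel = gaussian_bin_kernel(sigma, dz)
    half = (len(kernel) - 1) // 2
    pad = 2 * half + 1
    rho_pad = np.concatenate([
        np.full(pad, sld.fronting), sld.rho, np.full(pad, sld.backing)
    ])
    # indices ≥ half from either end of the padded array see no zero-padding
    # from np.convolve; keep them all, extending the grid by half+1 bins
    smeared = np.convolve(rho_pad, kernel, mode="same")[half:-half]
    n_ext = half + 1
    z_out = np.concatenate([
        sld.z[0] + dz * np.arange(-n_ext, 0),
        sld.z,
        sld.z[-1] + dz * np.arange(1, n_ext + 1),
    ])
    return replace(sld, z=z_out, rho=smeared)


def gaussian_bin_kernel(sigma: float, dz: float, truncate: float = 6.0) -> np.ndarray:
    """Bin-integrated unit-area Gaussian: w_j = Φ((j+½)Δz/σ) − Φ((j−½)Δz/σ).

    Integrating the Gaussian over each bin makes the discrete convolution of
    a piecewise-constant profile exact (a step maps to ρ₀·Φ(z/σ) with no
    sampling error); truncation at ``truncate``·σ leaves < 1e-9 of the mass.
    """
    half = int(np.ceil(truncate * sigma / dz))
    j = np.arange(-half, half + 1)
    kernel = ndtr((j + 0.5) * dz / sigma) - ndtr((j - 0.5) * dz / sigma)
    return kernel / kernel.sum()
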