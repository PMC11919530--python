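"""Surface tension and surface pressure from simulation outputs.

Two independent estimates of the monolayer surface tension are supported:

* **Pressure-tensor scheme** — from per-slice diagonal pressure-tensor
  components of the double-monolayer cell,
  γ = (L_z/2)·⟨P_zz − ½(P_xx + P_yy)⟩, the ½ accounting for the cell's two
  interfaces.
* **Semi-permeable wall scheme** — lipids are confined laterally by virtual
  walls transparent to water; γ = ⟨F_wall⟩ / (4·L_Y) from the mean wall
  force, with the area per lipid given directly by the wall geometry,
  APL = 2·x_wall·L_Y / N.

The surface pressure follows as Π = γ(aw) − γ(m) against a clean air–water
reference.  A semi-empirical correction rescales the wall-scheme result by
the ratio of interfacial water widths (the 90%→10% decay distance of the
water density), fitted as an exponential in APL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import units

logger = logging.getLogger(__name__)

#: presets for the clean air–water surface tension γ(aw), mN·m⁻¹:
#: 55 is typical of simple rigid water models, 72 the experimental value
GAMMA_AW_PRESETS = {"model_water": 55.0, "experimental": 72.0}


@dataclass
class PressureProfile:
    """Diagonal pressure-tensor components per z-slice of the cell (bar)."""

    z: np.ndarray       # slice centres, Å (uniform, default 1 Å slices)
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: float           # box length along z, Å
    unit: str = "bar"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        for name in ("pxx", "pyy", "pzz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.z.shape:
                raise ValueError(f"{name} shape mismatch")
            setattr(self, name, arr)
        if len(self.z) > 1:
            dz = np.diff(self.z)
            if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-12):
                raise ValueError("slices must be uniform")
            span = len(self.z) * dz[0]
            if not np.isclose(span, self.lz, rtol=1e-6):
                raise ValueError(
                    f"L_z={self.lz} inconsistent with slice span {span:.6g}"
                )
        if self.unit not in units.PRESSURE_TO_BAR:
            raise ValueError(f"undeclared pressure unit {self.unit!r}")

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n# lz: {self.lz:.17g}\n")
            fh.write("# columns: z pxx pyy pzz\n")
            np.savetxt(fh, np.column_stack([self.z, self.pxx, self.pyy, self.pzz]))

    @classmethod
    def read_ascii(cls, path) -> "PressureProfile":
        unit, lz = None, None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    stripped = line[1:].strip()
                    if stripped.startswith("unit:"):
                        unit = stripped.split(":", 1)[1].strip()
                    elif stripped.startswith("lz:"):
                        lz = float(stripped.split(":", 1)[1])
        if unit is None:
            raise ValueError("pressure-profile file must declare its unit")
        if lz is None:
            raise ValueError("pressure-profile file must declare lz")
        data = np.loadtxt(path, comments="#", ndmin=2)
        return cls(data[:, 0], data[:, 1], data[:, 2], data[:, 3], lz=lz, unit=unit)


@dataclass
class WallRecord:
    """Geometry and mean force of the semi-permeable wall confinement."""

    x_wall: float        # walls at ±x_wall, Å
    ly: float            # box length along y, Å
    mean_force: float    # ⟨F_wall⟩ in ``force_unit``
    n_lipids: int        # lipids per leaflet
    force_unit: str = "pN"

    def __post_init__(self):
        if self.x_wall < 0:
            raise ValueError("x_wall must be non-negative")
        if self.ly <= 0:
            raise ValueError("L_Y must be positive")
        if self.n_lipids <= 0:
            raise ValueError("need at least one lipid per leaflet")
        if self.force_unit not in units.FORCE_TO_PN:
            raise ValueError(f"undeclared force unit {self.force_unit!r}")


@dataclass
class WidthRecord:
    """Interfacial water width (90%→10% decay distance) at one APL."""

    apl: float      # Å²
    width: float    # Å

    def __post_init__(self):
        if self.width < 0:
            raise ValueError("width must be non-negative")


def gamma_from_pressure_profile(profile: PressureProfile) -> float:
    """γ = (L_z/2)·⟨P_zz − ½(P_xx+P_yy)⟩ in mN·m⁻¹.

    The slice average of the anisotropy bracket times L_z/2 equals
    Σ Δz·bracket/2, i.e. half the integrated anisotropy — half because the
    double-monolayer cell contains two equivalent interfaces.
    """
    bracket = profile.pzz - 0.5 * (profile.pxx + profile.pyy)
    bracket_bar = units.pressure_to_bar(bracket, profile.unit)
    gamma_bar_A = 0.5 * profile.lz * float(np.mean(bracket_bar))
    return gamma_bar_A * units.BAR_ANGSTROM_TO_MN_PER_M


def surface_pressure(gamma_monolayer: float, gamma_aw: float = GAMMA_AW_PRESETS["model_water"]) -> float:
    """Π = γ(aw) − γ(m), both in mN·m⁻¹."""
    if not (np.isfinite(gamma_monolayer) and np.isfinite(gamma_aw)):
        raise ValueError("surface tensions must be finite")
    return gamma_aw - gamma_monolayer


def gamma_from_walls(rec: WallRecord) -> float:
    """γ = ⟨F_wall⟩ / (4·L_Y) in mN·m⁻¹.

    The factor 4 counts the four wall–interface contacts (two walls, each
    crossed by the cell's two interfaces).
    """
    force_pn = units.force_to_pn(rec.mean_force, rec.force_unit)
    gamma_pn_per_A = force_pn / (4.0 * rec.ly)
    return gamma_pn_per_A * units.PN_PER_ANGSTROM_TO_MN_PER_M


def mean_wall_force(trace: np.ndarray, window: tuple[int, int] | None = None) -> float:
    """Mean of a wall-force time series over a declared frame window."""
    trace = np.asarray(trace, dtype=float)
    if window is not None:
        lo, hi = window
        trace = trace[lo:hi]
    if len(trace) == 0:
        raise ValueError("empty averaging window")
    return float(trace.mean())


def read_wall_trace(path) -> tuple[np.ndarray, str]:
    """Read a wall-force time series (one column) with a '# unit:' header."""
    unit = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "unit:" in line:
                unit = line.split("unit:", 1)[1].strip()
    if unit is None:
        raise ValueError("wall-force trace must declare its unit")
    data = np.loadtxt(path, comments="#")
    return np.atleast_1d(data), unit


def apl_from_walls(rec: WallRecord) -> float:
    """APL = 2·x_wall·L_Y / N (Å²): inter-wall distance × depth per lipid."""
    return 2.0 * rec.x_wall * rec.ly / rec.n_lipids


def width_90_10(z: np.ndarray, density: np.ndarray) -> float:
    """Distance over which a water profile decays from 90% to 10% of its max.

    The profile is scanned from its maximum toward the interfacial (decaying)
    side; both threshold crossings are located by linear interpolation.
    Scale-invariant: rescaling the density leaves the width unchanged.
    """
    z = np.asarray(z, dtype=float)
    density = np.asarray(density, dtype=float)
    if z.shape != density.shape or len(z) < 3:
        raise ValueError("need matching z/density arrays with ≥3 points")
    peak = float(density.max())
    if peak <= 0:
        raise ValueError("profile maximum must be positive")
    i_max = int(np.argmax(density))
    tail = density[i_max:]
    z_tail = z[i_max:]
    if tail.min() > 0.1 * peak:
        # decay must be on the other side; flip
        tail = density[: i_max + 1][::-1]
        z_tail = -z[: i_max + 1][::-1]
        if tail.min() > 0.1 * peak:
            raise ValueError("profile never decays below 10% of its maximum")

    def crossing(level: float) -> float:
        below = np.nonzero(tail <= level)[0]
        if len(below) == 0:
            raise ValueError(f"profile never crosses {level / peak:.0%} of its maximum")
        j = below[0]
        if j == 0:
            return float(z_tail[0])
        z0, z1 = z_tail[j - 1], z_tail[j]
        d0, d1 = tail[j - 1], tail[j]
        return float(z0 + (d0 - level) * (z1 - z0) / (d0 - d1))

    return abs(crossing(0.1 * peak) - crossing(0.9 * peak))


def fit_width_vs_apl(
    records,
    fix_offset: bool = False,
) -> tuple[float, float, float, np.ndarray]:
    """Least-squares fit of L_width = a·exp(b·APL) + c over width records.

    Returns ``(a, b, c, residuals)``; with ``fix_offset`` the additive
    constant c is pinned at zero.  Degenerate constant data short-circuit to
    (L̄, 0, 0) without touching the optimizer.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 width records")
    x = np.array([r.apl for r in records], dtype=float)
    y = np.array([r.width for r in records], dtype=float)
    if np.allclose(y, y[0], rtol=1e-12, atol=1e-12):
        residuals = y - y[0]
        return float(y[0]), 0.0, 0.0, residuals

    # log-linear initial guess on the positive part
    c0 = 0.0 if fix_offset else max(0.0, 0.9 * y.min() if y.min() > 0 else 0.0)
    shifted = np.clip(y - c0, 1e-12, None)
    slope, intercept = np.polyfit(x, np.log(shifted), 1)
    p0_a, p0_b = float(np.exp(intercept)), float(slope)

    try:
        if fix_offset:
            popt, _ = curve_fit(
                lambda t, a, b: a * np.exp(b * t), x, y, p0=[p0_a, p0_b], maxfev=20000
            )
            a, b, c = float(popt[0]), float(popt[1]), 0.0
        else:
            popt, _ = curve_fit(
                lambda t, a, b, c: a * np.exp(b * t) + c,
                x, y, p0=[p0_a, p0_b, c0], maxfev=20000,
            )
            a, b, c = map(float, popt)
    except RuntimeError as err:
        residuals = y - (p0_a * np.exp(p0_b * x) + c0)
        raise RuntimeError(
            f"exponential width fit did not converge (residual norm "
            f"{np.linalg.norm(residuals):.3g} at the initial guess)"
        ) from err
    residuals = y - (a * np.exp(b * x) + c)
    return a, b, c, residuals


def corrected_pressure(pi_raw: float, l_ref: float, l_fit: float) -> float:
    """Semi-empirical width correction: Π_corr = Π_raw · (L_ref / L_fit).

    ``l_ref`` is the interfacial water width at a low-coverage reference
    (taken as given input); ``l_fit`` the exponential-fit width at the APL
    in question.  By default the correction targets the surface pressure;
    applying it to the tension instead is a caller-side choice (the same
    arithmetic, applied before the Π = γ(aw) − γ(m) subtraction).
    """
    if l_fit <= 0:
        raise ValueError("fitted width must be positive")
    return pi_raw * (l_ref / l_fit)


def read_width_table(path) -> list[WidthRecord]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return [WidthRecord(float(a), float(w)) for a, w in data[:, :2]]
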