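"""Goodness-of-fit scan over area per lipid and isotherm assembly.

One reflectivity dataset (seven contrasts at one surface pressure) is fitted
against every member of a compression series of density profiles, each
simulated at a fixed area per lipid (APL).  The total χ² traces out a curve
in APL with a minimum at the simulation cell that best matches the measured
monolayer; a low-order polynomial locates that minimum, and repeating the
scan at every measured pressure yields a surface-pressure–area isotherm
derived from the reflectivity data itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityProfile
from .fit import MCMCSettings, PosteriorSummary, PriorSet, fit_contrasts

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """χ²(APL) samples with a fitted polynomial and its minimum."""

    apl: np.ndarray                   # Å², ascending
    chi2: np.ndarray                  # best total χ² per APL
    degree: int
    coefficients: np.ndarray          # numpy polyfit order (highest first)
    apl_min: float                    # Å², polynomial argmin over scan range
    pressure: float | None = None     # mN·m⁻¹ label of the dataset
    extrapolated: bool = False        # argmin pinned to an endpoint
    summaries: dict[float, PosteriorSummary] | None = None

    def polynomial(self) -> np.poly1d:
        return np.poly1d(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"apl": self.apl, "chi2": self.chi2})

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            coeffs = ",".join(f"{c:.17g}" for c in self.coefficients)
            fh.write(
                f"# degree={self.degree} apl_min={self.apl_min:.17g} "
                f"pressure={self.pressure if self.pressure is not None else 'nan'} "
                f"coefficients={coeffs}\n"
            )
            self.to_frame().to_csv(fh, index=False)


@dataclass(frozen=True)
class IsothermPoint:
    """One (surface pressure, APL) point with its provenance."""

    pressure: float   # Π, mN·m⁻¹
    apl: float        # Å²
    source: str       # "experimental" | "simulated" | "fitted"

    def __post_init__(self):
        if not (np.isfinite(self.pressure) and np.isfinite(self.apl)):
            raise ValueError("pressure and APL must be finite")
        if self.pressure <= 0 or self.apl <= 0:
            raise ValueError("pressure and APL must be positive")
        if self.source not in ("experimental", "simulated", "fitted"):
            raise ValueError(f"unknown source tag {self.source!r}")


def poly_min(
    points,
    degree: int = 2,
) -> tuple[float, np.ndarray, bool]:
    """Least-squares polynomial through (APL, χ²) points and its argmin.

    Returns ``(apl_min, coefficients, extrapolated)``.  The argmin is found
    analytically from the real roots of the derivative restricted to the
    scanned interval; if no interior minimum exists the better endpoint is
    returned and flagged.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (APL, chi2) pairs")
    if degree not in (2, 3):
        raise ValueError("degree must be 2 or 3")
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite scan points")
    x, y = pts[:, 0], pts[:, 1]
    coeffs = np.polyfit(x, y, degree)
    poly = np.poly1d(coeffs)
    lo, hi = float(x.min()), float(x.max())
    candidates = [lo, hi]
    for r in poly.deriv().roots:
        if abs(r.imag) < 1e-12 and lo <= r.real <= hi:
            candidates.append(float(r.real))
    values = poly(candidates)
    best = candidates[int(np.argmin(values))]
    extrapolated = best in (lo, hi) and len(candidates) == 2
    if extrapolated:
        warnings.warn(
            "no interior minimum of the fitted polynomial; returning the "
            "better endpoint (extrapolation flagged)",
            stacklevel=2,
        )
    return float(best), coeffs, extrapolated


def scan_apl(
    profiles: dict[float, DensityProfile],
    datasets,
    priors: PriorSet | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    degree: int = 2,
    pressure: float | None = None,
    keep_summaries: bool = False,
) -> ScanResult:
    """Fit one multi-contrast dataset against every APL-labelled profile.

    Each APL gets an independent seeded chain (seed offset by its rank so the
    scan is reproducible as a whole); the best total χ² — evaluated at the
    posterior mode — is recorded per APL, then a polynomial of ``degree``
    locates the optimum area.

    The quadratic default follows common practice near a minimum; a cubic is
    available for visibly asymmetric scans (the choice is logged).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 APL values to scan")
    apls = np.array(sorted(profiles), dtype=float)
    logger.info("APL scan: %d areas, polynomial degree %d", len(apls), degree)
    chi2 = np.empty_like(apls)
    summaries = {}
    for rank, apl in enumerate(apls):
        summary = fit_contrasts(
            profiles[apl], datasets, priors=priors, mcmc=mcmc,
            seed=seed + rank, keep_chain=False,
        )
        chi2[rank] = summary.chi2_total
        if keep_summaries:
            summaries[float(apl)] = summary
        logger.info("  APL %.2f Å² → χ²_total %.4g", apl, summary.chi2_total)
    apl_best, coeffs, extrapolated = poly_min(np.column_stack([apls, chi2]), degree)
    return ScanResult(
        apl=apls,
        chi2=chi2,
        degree=degree,
        coefficients=coeffs,
        apl_min=apl_best,
        pressure=pressure,
        extrapolated=extrapolated,
        summaries=summaries or None,
    )


def build_isotherm(scans) -> list[IsothermPoint]:
    """Assemble (Π, APL*) pairs from per-pressure scans, sorted by pressure.

    Physically the area should shrink as the film is compressed; a
    non-monotone sequence is reported (warning) but not altered.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("need scans at ≥2 pressures to build an isotherm")
    pressures = [s.pressure for s in scans]
    if any(p is None for p in pressures):
        raise ValueError("every scan needs a surface-pressure label")
    if len(set(pressures)) != len(pressures):
        raise ValueError("duplicate surface pressures")
    points = sorted(
        (IsothermPoint(float(s.pressure), float(s.apl_min), "fitted") for s in scans),
        key=lambda p: p.pressure,
    )
    apls = [p.apl for p in points]
    if not all(b < a for a, b in zip(apls, apls[1:])):
        warnings.warn(
            "fitted isotherm is not monotone (APL should decrease with pressure)",
            stacklevel=2,
        )
    return points


def isotherm_frame(points) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pressure_mN_per_m": [p.pressure for p in points],
            "apl_A2": [p.apl for p in points],
            "source": [p.source for p in points],
        }
    )


def write_isotherm_csv(points, path) -> None:
    isotherm_frame(points).to_csv(path, index=False)


def read_isotherm_csv(path) -> list[IsothermPoint]:
    df = pd.read_csv(path)
    return [
        IsothermPoint(float(r.pressure_mN_per_m), float(r.apl_A2), str(r.source))
        for r in df.itertuples()
    ]


def plot_isotherms(curves: dict[str, list[IsothermPoint]], path) -> None:
    """Overlay experimental / simulated / fitted isotherms and save a figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, points in curves.items():
        apl = [p.apl for p in points]
        pi = [p.pressure for p in points]
        ax.plot(apl, pi, marker="o", label=label)
    ax.set_xlabel("area per lipid (Å²)")
    ax.set_ylabel("surface pressure Π (mN·m⁻¹)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
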