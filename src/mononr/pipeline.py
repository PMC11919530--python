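"""End-to-end orchestration: density profiles → fits → scans → isotherm.

A :class:`RunConfig` (usually read from YAML) names the inputs — density
profiles per area per lipid (or trajectories to reduce first), reflectivity
datasets per contrast and surface pressure — plus the fitting settings.
:func:`run_pipeline` executes the whole analysis and writes every artifact
together with a manifest recording inputs, seeds and the decisions in force,
sufficient to reproduce any output exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contrast import ContrastScheme, ScatteringLengthTable, standard_schemes
from .density import DensityProfile, compute_nd_profiles, symmetrize_leaflets, water_volume_fraction
from .fit import MCMCSettings, PriorSet
from .frames import ClassificationMap, read_frames
from .reflect import ReflectivityCurve
from .scan import build_isotherm, scan_apl, write_isotherm_csv

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Pipeline failure annotated with the offending stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def scheme_by_name(name: str) -> ContrastScheme:
    for scheme in standard_schemes():
        if scheme.name == name:
            return scheme
    raise KeyError(f"unknown contrast name {name!r}; known: "
                   f"{[s.name for s in standard_schemes()]}")


@dataclass
class RunConfig:
    """Validated inputs and settings for one full pipeline run."""

    profiles: dict[float, str]                 # APL (Å²) → density-profile CSV
    pressures: dict[float, dict[str, str]]     # Π (mN·m⁻¹) → {contrast name → data file}
    output_dir: str = "mononr_out"
    seed: int = 0
    degree: int = 2
    gamma_aw: float = 55.0
    bin_width: float = 0.5
    scattering_table: str | None = None
    classification_map: str | None = None
    trajectories: dict[float, str] = field(default_factory=dict)  # APL → coordinate file
    priors: dict[str, tuple[float, float]] | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc = MCMCSettings(**raw.pop("mcmc", {}))
        profiles = {float(k): str(v) for k, v in raw.pop("profiles", {}).items()}
        pressures = {
            float(p): {str(c): str(f) for c, f in files.items()}
            for p, files in raw.pop("pressures", {}).items()
        }
        trajectories = {float(k): str(v) for k, v in raw.pop("trajectories", {}).items()}
        priors = raw.pop("priors", None)
        if priors is not None:
            priors = {k: (float(v[0]), float(v[1])) for k, v in priors.items()}
        return cls(profiles=profiles, pressures=pressures, trajectories=trajectories,
                   priors=priors, mcmc=mcmc, **raw)

    def validate(self) -> None:
        if not self.profiles and not self.trajectories:
            raise ValueError("config names neither density profiles nor trajectories")
        for apl, path in {**self.profiles, **self.trajectories}.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"APL {apl}: missing file {path}")
        for pressure, files in self.pressures.items():
            for cname, path in files.items():
                scheme_by_name(cname)  # raises on unknown contrast
                if not Path(path).exists():
                    raise FileNotFoundError(f"{pressure} mN/m {cname}: missing {path}")
        if self.degree not in (2, 3):
            raise ValueError("polynomial degree must be 2 or 3")

    def prior_set(self) -> PriorSet:
        if self.priors is None:
            return PriorSet()
        base = PriorSet()
        base.bounds.update(self.priors)
        return PriorSet(base.bounds)


def _load_profiles(config: RunConfig) -> dict[float, DensityProfile]:
    profiles = {}
    cmap = None
    if config.trajectories:
        if config.classification_map is None:
            raise ValueError("trajectories given without a classification map")
        cmap = ClassificationMap.read(config.classification_map)
    for apl, path in config.trajectories.items():
        frames = read_frames(path, cmap)
        prof = compute_nd_profiles(frames, config.bin_width)
        prof = symmetrize_leaflets(prof)
        profiles[apl] = water_volume_fraction(prof)
    for apl, path in config.profiles.items():
        prof = DensityProfile.read_csv(path)
        if not prof.water_is_fraction:
            prof = water_volume_fraction(symmetrize_leaflets(prof))
        profiles[apl] = prof
    return profiles


def run_pipeline(config: RunConfig) -> dict:
    """Execute density → fit → scan → isotherm and write all artifacts.

    Returns a result bundle: scan results per pressure, isotherm points (when
    ≥2 pressures), and the manifest dictionary.  Fails fast with the
    offending stage named.
    """
    try:
        config.validate()
    except Exception as err:
        raise StageError("validate", err) from err

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = (
        ScatteringLengthTable.read(config.scattering_table)
        if config.scattering_table
        else ScatteringLengthTable()
    )

    try:
        profiles = _load_profiles(config)
    except Exception as err:
        raise StageError("density", err) from err

    priors = config.prior_set()
    scans = {}
    for rank, (pressure, files) in enumerate(sorted(config.pressures.items())):
        try:
            datasets = {
                scheme_by_name(cname): ReflectivityCurve.read_ascii(path, name=cname)
                for cname, path in files.items()
            }
            result = scan_apl(
                profiles, datasets, priors=priors, mcmc=config.mcmc,
                seed=config.seed + 1000 * rank, degree=config.degree,
                pressure=pressure,
            )
        except Exception as err:
            raise StageError(f"scan@{pressure}mN/m", err) from err
        scans[pressure] = result
        result.write_csv(out / f"scan_{pressure:g}mNm.csv")
        logger.info("pressure %g mN/m: best APL %.2f Å²", pressure, result.apl_min)

    isotherm = None
    if len(scans) >= 2:
        try:
            isotherm = build_isotherm(scans.values())
            write_isotherm_csv(isotherm, out / "isotherm.csv")
        except Exception as err:
            raise StageError("isotherm", err) from err
    else:
        logger.warning("only one pressure configured; scan written, isotherm skipped")

    manifest = {
        "mononr_version": __version__,
        "seed": config.seed,
        "mcmc": {
            "n_draws": config.mcmc.n_draws,
            "n_walkers": config.mcmc.n_walkers,
            "summary_draws": config.mcmc.summary_draws,
        },
        "polynomial_degree": config.degree,
        "gamma_aw_mN_per_m": config.gamma_aw,
        "bin_width_A": config.bin_width,
        "priors": {k: list(v) for k, v in config.prior_set().bounds.items()},
        "inputs": {
            "profiles": {str(k): v for k, v in config.profiles.items()},
            "trajectories": {str(k): v for k, v in config.trajectories.items()},
            "pressures": {
                str(p): dict(files) for p, files in config.pressures.items()
            },
            "scattering_table": config.scattering_table or "shipped defaults",
        },
        "decisions": {
            "polynomial_degree": f"{config.degree} (quadratic default; cubic available)",
            "gamma_aw": f"{config.gamma_aw} mN/m clean-surface reference",
            "width_correction_target": "surface pressure (switchable to tension)",
            "leaflet_midpoint": "number-weighted centre of the water distribution",
            "bulk_window": "10 Å of the water slab farthest from the monolayer",
        },
        "outputs": {
            "scans": {str(p): f"scan_{p:g}mNm.csv" for p in scans},
            "isotherm": "isotherm.csv" if isotherm else None,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"scans": scans, "isotherm": isotherm, "manifest": manifest}
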