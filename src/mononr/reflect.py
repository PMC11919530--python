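"""Specular reflectivity from an SLD profile by exact slab recursion.

The profile is discretized into slabs at its grid spacing and the reflected
amplitude computed by the recursive Fresnel (Parratt/Abelès) solution with
semi-infinite fronting and backing media.  This is the exact dynamical
solution for a piecewise-constant profile: total external reflection below
the critical edge q_c = √(16πρ) and the kinematic R ∝ 16π²ρ²/q⁴ fall-off
both emerge from it rather than being imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .contrast import SLDProfile


@dataclass
class ReflectivityCurve:
    """(q, R[, δR[, δq]]) for one contrast; q ascending, in Å⁻¹."""

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None
    dq: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
            if np.any(self.dR <= 0):
                raise ValueError("δR must be positive where present")
            if self.dR.shape != self.q.shape:
                raise ValueError("δR shape mismatch")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if np.any(self.R < 0):
            raise ValueError("R must be non-negative")
        if self.R.shape != self.q.shape:
            raise ValueError("R shape mismatch")

    def __len__(self) -> int:
        return len(self.q)

    def write_ascii(self, path) -> None:
        cols = [self.q, self.R]
        header = "q R"
        if self.dR is not None:
            cols.append(self.dR)
            header += " dR"
            if self.dq is not None:
                cols.append(self.dq)
                header += " dq"
        with open(path, "w") as fh:
            if self.name:
                fh.write(f"# contrast: {self.name}\n")
            fh.write(f"# columns: {header}\n")
            np.savetxt(fh, np.column_stack(cols))

    @classmethod
    def read_ascii(cls, path, name: str = "") -> "ReflectivityCurve":
        stored_name = name
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "contrast:" in line and not name:
                    stored_name = line.split("contrast:", 1)[1].strip()
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError("need at least 2 columns (q, R)")
        dR = data[:, 2] if data.shape[1] >= 3 else None
        dq = data[:, 3] if data.shape[1] >= 4 else None
        return cls(data[:, 0], data[:, 1], dR, dq, name=stored_name)


def _parratt(kz: np.ndarray, thickness: float) -> np.ndarray:
    """|r|² for a stack of uniform slabs, vectorized over the last axis.

    ``kz`` has shape (n_media, m): z-components of the wavevector in the
    fronting (row 0), each slab, and the backing (last row).  All interior
    slabs share one ``thickness``.
    """
    n_media = kz.shape[0]
    # Fresnel coefficient of every interface and phase factor of every slab,
    # computed in two vectorized passes; the recursion itself is sequential
    r_if = (kz[:-1] - kz[1:]) / (kz[:-1] + kz[1:])
    r = r_if[-1]  # bottom interface (last slab | backing)
    if n_media == 2:
        return np.abs(r) ** 2
    beta = np.exp((2j * thickness) * kz[1:-1])
    for j in range(n_media - 3, -1, -1):
        rb = r * beta[j]
        rj = r_if[j]
        r = (rj + rb) / (1.0 + rj * rb)
    return np.abs(r) ** 2


def _kz_stack(q: np.ndarray, rho_layers: np.ndarray, fronting: float) -> np.ndarray:
    """kz in every medium: kz_j = sqrt((q/2)² − 4π(ρ_j − ρ_fronting))."""
    k0sq = (np.asarray(q, dtype=float) / 2.0) ** 2
    delta = 4.0 * np.pi * (np.asarray(rho_layers) - fronting)
    return np.sqrt(k0sq[None, :].astype(complex) - delta[:, None])


def _trim_constant_ends(rho: np.ndarray, fronting: float, backing: float) -> np.ndarray:
    """Drop leading/trailing slabs indistinguishable from the bulk media."""
    scale = max(np.max(np.abs(rho), initial=0.0), abs(fronting), abs(backing), 1e-30)
    tol = 1e-12 * scale
    keep = np.ones(len(rho), dtype=bool)
    i = 0
    while i < len(rho) and abs(rho[i] - fronting) < tol:
        keep[i] = False
        i += 1
    i = len(rho) - 1
    while i >= 0 and abs(rho[i] - backing) < tol:
        keep[i] = False
        i -= 1
    return rho[keep]


def reflectivity(sld: SLDProfile, q: np.ndarray, *, trim: bool = True) -> ReflectivityCurve:
    """Specular reflectivity |r(q)|² of an SLD profile.

    Each grid bin becomes a uniform slab of thickness Δz between semi-infinite
    fronting and backing media.  Leading/trailing slabs equal to the bulk
    values are trimmed (they cannot scatter) unless ``trim=False``.
    """
    q = np.asarray(q, dtype=float)
    if len(sld.z) == 0:
        raise ValueError("empty SLD profile")
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    rho = sld.rho
    if trim:
        rho = _trim_constant_ends(rho, sld.fronting, sld.backing)
    layers = np.concatenate([[sld.fronting], rho, [sld.backing]])
    kz = _kz_stack(q, layers, sld.fronting)
    R = _parratt(kz, sld.dz if len(rho) else 0.0)
    R = np.clip(R.real, 0.0, 1.0)
    return ReflectivityCurve(q, R)


def batched_reflectivity(
    profiles: list[SLDProfile], q: np.ndarray
) -> list[np.ndarray]:
    """R(q) for several profiles sharing grid spacing and slab count.

    Stacks the contrasts into one Parratt recursion so the layer loop runs
    once; used by the fitting likelihood where seven contrasts share a grid.
    Falls back to per-profile evaluation when shapes differ.
    """
    q = np.asarray(q, dtype=float)
    n = len(profiles)
    if n == 0:
        return []
    same = all(
        len(p.z) == len(profiles[0].z) and abs(p.dz - profiles[0].dz) < 1e-12
        for p in profiles
    )
    if not same:
        return [reflectivity(p, q).R for p in profiles]
    nq = len(q)
    kz_cols = []
    for p in profiles:
        layers = np.concatenate([[p.fronting], p.rho, [p.backing]])
        kz_cols.append(_kz_stack(q, layers, p.fronting))
    kz = np.concatenate(kz_cols, axis=1)  # (n_media, n*nq)
    R = _parratt(kz, profiles[0].dz)
    R = np.clip(R.real, 0.0, 1.0)
    return [R[i * nq:(i + 1) * nq] for i in range(n)]


def apply_scale_background(
    curve: ReflectivityCurve, scale: float, background: float
) -> ReflectivityCurve:
    """R_model = scale·R + background, pointwise.

    The scale factor absorbs direct-beam attenuation relative to the
    reflected measurement; the constant background models incoherent
    scattering from the bulk and is therefore added after scaling.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if background < 0:
        raise ValueError("background must be non-negative")
    return replace(curve, R=scale * curve.R + background)


def smear_resolution(curve: ReflectivityCurve, dq_over_q: float, n_points: int = 17) -> ReflectivityCurve:
    """Optional constant-Δq/q Gaussian resolution smearing (off by default).

    Instrument resolution is not part of the standard model here; this hook
    exists for data carrying a known Δq/q.
    """
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be non-negative")
    if dq_over_q == 0:
        return replace(curve, R=curve.R.copy())
    x = np.linspace(-3.0, 3.0, n_points)
    w = np.exp(-0.5 * x**2)
    w /= w.sum()
    R_sm = np.zeros_like(curve.R)
    for xi, wi in zip(x, w):
        q_shift = curve.q * (1.0 + xi * dq_over_q)
        R_sm += wi * np.interp(q_shift, curve.q, curve.R)
    return replace(curve, R=R_sm)
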