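"""Structural and dynamic observables from monolayer trajectories.

These quantities feed the downstream biophysical interpretation once the
best-fitting area per lipid is known: the deuterium order parameter |S_CD|
of the acyl chains, the chain tilt relative to the interface normal, and the
lateral (x–y) self-diffusion coefficient of the lipids.

Atom bookkeeping: the frame format carries no bond topology, so C–H pairs
and chain ends are resolved from atom names following the convention the
synthetic generator emits — tail carbons ``C<k><chain>`` (k the carbon
number, chain a letter) with attached hydrogens ``H<k><chain><a|b|c>``.
Explicit index pairs may be passed instead for other naming schemes.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict

import numpy as np

from .frames import Frame

_CARBON_RE = re.compile(r"^C(\d+)([A-Z])$")
_HYDROGEN_RE = re.compile(r"^H(\d+)([A-Z])[a-z]?$")


def _resolve_ch_pairs(frame: Frame, carbons: range) -> list[tuple[int, int]]:
    """Pair tail carbons in ``carbons`` with their hydrogens by atom name."""
    if frame.names is None:
        raise ValueError("frame carries no atom names; pass ch_pairs explicitly")
    tail = frame.groups == "tail"
    carbon_index: dict[tuple[int, int, str], int] = {}
    for i in np.nonzero(tail & (frame.elements == "C"))[0]:
        m = _CARBON_RE.match(str(frame.names[i]))
        if m and int(m.group(1)) in carbons:
            carbon_index[(frame.mol_index[i], int(m.group(1)), m.group(2))] = i
    pairs = []
    for i in np.nonzero(tail & (frame.elements == "H"))[0]:
        m = _HYDROGEN_RE.match(str(frame.names[i]))
        if not m:
            continue
        key = (frame.mol_index[i], int(m.group(1)), m.group(2))
        if key in carbon_index:
            pairs.append((carbon_index[key], i))
    if not pairs:
        raise ValueError("no C–H pairs resolved for the requested carbon range")
    return pairs


def order_parameter_scd(
    frames,
    carbons: range = range(4, 17),
    ch_pairs: list[tuple[int, int]] | None = None,
) -> float:
    """Mean |S_CD| over the selected acyl carbons, chains, lipids and frames.

    S_CD = ⟨(3cos²θ − 1)/2⟩ with θ the angle between each C–H bond and the
    interface normal (z).  The default carbon window C4–C16 excludes the
    perturbed chain ends.  Reported as the absolute value, the convention
    for deuterium NMR order parameters.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    total, count = 0.0, 0
    for frame in frames:
        pairs = ch_pairs if ch_pairs is not None else _resolve_ch_pairs(frame, carbons)
        idx = np.asarray(pairs, dtype=int)
        vec = frame.positions[idx[:, 1]] - frame.positions[idx[:, 0]]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise ValueError("zero-length C–H vector")
        cos2 = (vec[:, 2] / norm) ** 2
        total += float(np.sum(1.5 * cos2 - 0.5))
        count += len(idx)
    return abs(total / count)


def _chain_ends(frame: Frame) -> list[tuple[int, int]]:
    """(first, last) carbon index per chain, from C<k><chain> names."""
    if frame.names is None:
        raise ValueError("frame carries no atom names; pass chain_ends explicitly")
    chains: dict[tuple[int, str], dict[int, int]] = defaultdict(dict)
    tail_c = (frame.groups == "tail") & (frame.elements == "C")
    for i in np.nonzero(tail_c)[0]:
        m = _CARBON_RE.match(str(frame.names[i]))
        if m:
            chains[(frame.mol_index[i], m.group(2))][int(m.group(1))] = i
    ends = []
    for mapping in chains.values():
        ks = sorted(mapping)
        if len(ks) >= 2:
            ends.append((mapping[ks[0]], mapping[ks[-1]]))
    if not ends:
        raise ValueError("no chains resolved from atom names")
    return ends


def tail_tilt(frames, chain_ends: list[tuple[int, int]] | None = None) -> float:
    """Mean tilt angle (degrees) of the chain end-to-end vector from z.

    The tilt of each chain is the angle between its first→last carbon vector
    and the interface normal, folded into [0°, 90°] so the two leaflets
    (chains pointing +z and −z) average consistently.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    total, count = 0.0, 0
    for frame in frames:
        ends = chain_ends if chain_ends is not None else _chain_ends(frame)
        idx = np.asarray(ends, dtype=int)
        vec = frame.positions[idx[:, 1]] - frame.positions[idx[:, 0]]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise ValueError("degenerate (zero-length) chain vector")
        cos = np.abs(vec[:, 2]) / norm
        total += float(np.sum(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))))
        count += len(idx)
    return total / count


def _unwrap_xy(coms: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Undo periodic jumps in lipid centre-of-mass x–y tracks."""
    out = coms.copy()
    for ax in range(2):
        L = boxes[:, ax]
        delta = np.diff(out[:, :, ax], axis=0)
        jumps = np.round(delta / L[1:, None])
        out[1:, :, ax] -= np.cumsum(jumps * L[1:, None], axis=0)
    return out


def lateral_diffusion(
    frames,
    dt: float,
    lag_window: tuple[float, float] = (0.1, 0.5),
    drift_tolerance: float = 0.25,
) -> float:
    """Lateral self-diffusion coefficient D = slope(MSD_xy)/4.

    ``dt`` is the frame spacing in ns; positions are in Å, so D comes out in
    Å²·ns⁻¹, numerically equal to 10⁻⁷ cm²·s⁻¹.  The MSD is computed per
    lipid centre of mass (x–y, periodic jumps unwrapped) and averaged over
    lipids and time origins; the slope is a least-squares fit over the lag
    window given as fractions of the trajectory span (default 10–50%,
    avoiding both ballistic/rattling short lags and noise-dominated long
    ones).

    A strongly super-linear MSD (uniform drift, quadratic growth) triggers a
    diagnostic warning, since a straight-line fit is then meaningless.
    """
    frames = list(frames)
    n_frames = len(frames)
    if n_frames < 4:
        raise ValueError("need at least 4 frames for an MSD fit")
    if dt <= 0:
        raise ValueError("frame spacing must be positive")

    lipid = frames[0].groups != "water"
    mols, inverse = np.unique(frames[0].mol_index[lipid], return_inverse=True)
    counts = np.bincount(inverse).astype(float)
    coms = np.empty((n_frames, len(mols), 2))
    boxes = np.empty((n_frames, 2))
    for t, frame in enumerate(frames):
        boxes[t] = frame.box[:2]
        pos = frame.positions[lipid]
        for ax in range(2):
            coms[t, :, ax] = np.bincount(inverse, weights=pos[:, ax]) / counts
    coms = _unwrap_xy(coms, boxes)

    max_lag = n_frames - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, lag in enumerate(lags):
        disp = coms[lag:] - coms[:-lag]
        msd[k] = float(np.mean(np.sum(disp**2, axis=2)))

    lo = max(1, int(np.floor(lag_window[0] * max_lag)))
    hi = max(lo + 2, int(np.ceil(lag_window[1] * max_lag)))
    if hi > max_lag:
        raise ValueError("lag window exceeds trajectory span")
    t_fit = lags[lo - 1:hi] * dt
    m_fit = msd[lo - 1:hi]

    slope, _ = np.polyfit(t_fit, m_fit, 1)
    # drift diagnostic: log–log slope α of the MSD is 1 for diffusion and 2
    # for uniform drift; a clearly super-linear window is flagged
    if np.all(m_fit > 0):
        alpha = np.polyfit(np.log(t_fit), np.log(m_fit), 1)[0]
        if alpha > 1.0 + drift_tolerance:
            warnings.warn(
                "MSD grows super-linearly (log–log slope "
                f"{alpha:.2f}); drift suspected, the linear diffusion fit is "
                "unreliable",
                stacklevel=2,
            )
    return float(max(slope, 0.0) / 4.0)
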