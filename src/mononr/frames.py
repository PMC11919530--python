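"""Trajectory frames and atom classification.

A :class:`Frame` is the minimal in-memory representation of one snapshot of a
monolayer simulation cell: positions, box lengths, and per-atom labels
(element, head/tail/water group, hydrogen class).  Hydrogen classes exist
because isotopic contrast variation substitutes deuterium for hydrogen on the
head or tails only, never on the glycerol backbone; each hydrogen must
therefore be assigned to one of the substitution pools up front.

Coordinate files (GRO/PDB) are read through MDAnalysis; the mapping from
(residue name, atom name) to (element, group, hydrogen class) is supplied by a
:class:`ClassificationMap`, a plain whitespace-delimited text table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

GROUPS = ("head", "tail", "water")
HCLASSES = ("H_head", "H_tail", "H_backbone", "H_water", "none")

#: species channels a density profile carries (water handled separately)
LIPID_SPECIES = ("C", "N", "O", "P", "H_head", "H_tail", "H_backbone")


@dataclass
class Frame:
    """One snapshot: positions in Å plus per-atom labels and box lengths.

    ``hclass`` is "none" for every non-hydrogen atom and one of
    ``H_head``/``H_tail``/``H_backbone``/``H_water`` for every hydrogen.
    """

    positions: np.ndarray          # (n_atoms, 3) float, Å
    elements: np.ndarray           # (n_atoms,) str, e.g. "C", "H"
    groups: np.ndarray             # (n_atoms,) str in GROUPS
    hclass: np.ndarray             # (n_atoms,) str in HCLASSES
    mol_index: np.ndarray          # (n_atoms,) int molecule id
    box: np.ndarray                # (3,) float, L_x, L_y, L_z in Å
    names: np.ndarray | None = None      # optional atom names
    resnames: np.ndarray | None = None   # optional residue names

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        for arr_name in ("elements", "groups", "hclass"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name)))
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        for arr_name in ("elements", "groups", "hclass", "mol_index"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != n_atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box lengths must be three positive values")
        bad = ~np.isin(self.groups, GROUPS)
        if bad.any():
            raise ValueError(f"unknown group tags: {sorted(set(self.groups[bad]))}")
        bad = ~np.isin(self.hclass, HCLASSES)
        if bad.any():
            raise ValueError(f"unknown hydrogen classes: {sorted(set(self.hclass[bad]))}")
        is_h = self.elements == "H"
        if np.any(is_h & (self.hclass == "none")):
            raise ValueError("hydrogen atom without a hydrogen-class tag")
        if np.any(~is_h & (self.hclass != "none")):
            raise ValueError("non-hydrogen atom carries a hydrogen-class tag")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def area(self) -> float:
        """Interface area L_x · L_y in Å²."""
        return float(self.box[0] * self.box[1])


class ClassificationMap:
    """(residue name, atom name) → (element, group, hydrogen class).

    Stored as an explicit dictionary; unknown atoms raise rather than being
    silently dropped, since a dropped atom would bias every density profile
    downstream.
    """

    def __init__(self, rows: dict[tuple[str, str], tuple[str, str, str]]):
        for (res, name), (elem, group, hcl) in rows.items():
            if group not in GROUPS:
                raise ValueError(f"{res}/{name}: unknown group {group!r}")
            if hcl not in HCLASSES:
                raise ValueError(f"{res}/{name}: unknown hydrogen class {hcl!r}")
            if (elem == "H") != (hcl != "none"):
                raise ValueError(f"{res}/{name}: hydrogen class inconsistent with element {elem!r}")
        self._rows = dict(rows)

    def __len__(self) -> int:
        return len(self._rows)

    def lookup(self, resname: str, atomname: str) -> tuple[str, str, str]:
        try:
            return self._rows[(resname, atomname)]
        except KeyError:
            raise KeyError(
                f"atom {resname}/{atomname} not in classification map; "
                "every atom must resolve to exactly one row"
            ) from None

    @classmethod
    def from_text(cls, text: str) -> "ClassificationMap":
        """Parse the 5-column text format: residue atom element group h-class."""
        rows = {}
        for lineno, line in enumerate(io.StringIO(text), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            res, name, elem, group, hcl = parts
            key = (res, name)
            if key in rows:
                raise ValueError(f"line {lineno}: duplicate entry for {res}/{name}")
            rows[key] = (elem, group, hcl)
        return cls(rows)

    @classmethod
    def read(cls, path) -> "ClassificationMap":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# residue atom element group h-class\n")
            for (res, name), (elem, group, hcl) in sorted(self._rows.items()):
                fh.write(f"{res} {name} {elem} {group} {hcl}\n")


def classify_universe(universe, cmap: ClassificationMap) -> list[Frame]:
    """Convert every frame of an MDAnalysis Universe into :class:`Frame` objects."""
    atoms = universe.atoms
    resnames = atoms.resnames
    names = atoms.names
    labels = [cmap.lookup(r, n) for r, n in zip(resnames, names)]
    elements = np.array([lab[0] for lab in labels])
    groups = np.array([lab[1] for lab in labels])
    hclass = np.array([lab[2] for lab in labels])
    mol_index = atoms.resindices.copy()
    frames = []
    for _ in universe.trajectory:
        box = universe.dimensions[:3].astype(float)
        frames.append(
            Frame(
                positions=atoms.positions.astype(float),
                elements=elements,
                groups=groups,
                hclass=hclass,
                mol_index=mol_index,
                box=box,
                names=names.copy(),
                resnames=resnames.copy(),
            )
        )
    return frames


def read_frames(path, cmap: ClassificationMap, topology=None) -> list[Frame]:
    """Read GRO or PDB coordinates (optionally multi-model) into frames.

    ``path`` is the coordinate/trajectory file; ``topology`` an optional
    separate topology readable by MDAnalysis.
    """
    import MDAnalysis as mda

    if topology is None:
        universe = mda.Universe(str(path))
    else:
        universe = mda.Universe(str(topology), str(path))
    return classify_universe(universe, cmap)
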