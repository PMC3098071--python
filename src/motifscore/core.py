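"""Core containers shared across the package.

A *typed complex* is the package's central in-memory object: the heavy atoms
of one protein-ligand complex, each carrying its 3-code atom type (see
:mod:`motifscore.atom_typing`), split into a protein side and a ligand side.
All geometry is in Angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

PROTEIN = "protein"
LIGAND = "ligand"

#: code used for heavy atoms whose element falls outside the 23-type alphabet
UNK = "UNK"


@dataclass(frozen=True)
class TypedAtom:
    """One heavy atom with coordinates, identity, and an atom-type code.

    ``resnum`` keeps author numbering plus any insertion code as a single
    string, so residue identity round-trips through PDB text unchanged.
    """

    origin: str  # PROTEIN or LIGAND
    name: str  # PDB atom name
    element: str
    xyz: tuple[float, float, float]
    code: str = UNK
    chain: str = ""
    residue: str = ""
    resnum: str = ""

    def __post_init__(self) -> None:
        if self.origin not in (PROTEIN, LIGAND):
            raise ValueError(f"origin must be protein|ligand, got {self.origin!r}")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")

    def moved(self, xyz: Iterable[float]) -> "TypedAtom":
        x, y, z = (float(c) for c in xyz)
        return replace(self, xyz=(x, y, z))

    @property
    def residue_id(self) -> tuple[str, str, str]:
        return (self.chain, self.residue, self.resnum)


@dataclass
class TypedComplex:
    """Heavy atoms of one protein-ligand complex, both sides typed."""

    name: str
    protein: list[TypedAtom] = field(default_factory=list)
    ligand: list[TypedAtom] = field(default_factory=list)

    def protein_coords(self) -> np.ndarray:
        return _coords(self.protein)

    def ligand_coords(self) -> np.ndarray:
        return _coords(self.ligand)

    def with_ligand_coords(self, coords: np.ndarray, name: str | None = None) -> "TypedComplex":
        """Copy of the complex with the ligand moved to ``coords`` (same order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.ligand), 3):
            raise ValueError("coordinate array shape does not match ligand atom count")
        moved = [a.moved(c) for a, c in zip(self.ligand, coords)]
        return TypedComplex(name or self.name, list(self.protein), moved)


def _coords(atoms: list[TypedAtom]) -> np.ndarray:
    if not atoms:
        return np.zeros((0, 3))
    return np.asarray([a.xyz for a in atoms], dtype=float)
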