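"""Reading protein-ligand complexes and ligand bond dictionaries.

Coordinates come from PDB-format files (protein as ATOM records, the ligand
as a HETATM component).  Ligand chemistry (bonds, bond orders, aromaticity,
formal charges) comes from a chemical-component-dictionary-style mmCIF file
or a MOL/SDF file, since PDB coordinate records carry no bonding information.

Loading already applies the normalizations every downstream stage assumes:
hydrogens are dropped, alternate locations are collapsed to a single copy,
waters and common crystallization additives are removed, and metal ions
coordinated by the protein are moved to the protein side of the complex.
The corpus eligibility filters used to build contact statistics (X-ray only,
single ligand, no nucleic acids, no covalently bound ligand, no heme) are a
separate, explicit step so that scoring arbitrary poses stays possible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RawAtom",
    "ComplexMetadata",
    "RawComplex",
    "LigandBondGraph",
    "EligibilityVerdict",
    "read_complex",
    "read_ligand_dictionary",
    "corpus_eligibility",
    "write_complex_pdb",
    "write_complex_tsv",
    "excluded_components",
    "METAL_ELEMENTS",
    "HEME_COMPONENTS",
]

#: metal ions that may be re-assigned to the protein side when coordinated
METAL_ELEMENTS = {"ZN", "CA", "MG", "MN", "FE", "NI", "CU", "CO", "CD"}

#: heme-group component ids; complexes containing any of them are ineligible
HEME_COMPONENTS = {"HEM", "HEC", "HEA", "HEB", "DHE"}

#: distance below which a ligand-protein heavy-atom pair is taken as covalent
COVALENT_CUTOFF = 1.9

#: metal counts as protein-coordinated within this distance of protein N/O/S
METAL_COORDINATION_CUTOFF = 3.0

_NUCLEIC_RESIDUES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}


def excluded_components() -> frozenset[str]:
    """Component ids (waters, buffer ions, cryoprotectants) dropped on load."""
    text = resources.files("motifscore.data").joinpath("excluded_components.txt").read_text()
    ids = {line.strip().upper() for line in text.splitlines()
           if line.strip() and not line.startswith("#")}
    return frozenset(ids)


@dataclass(frozen=True)
class RawAtom:
    """One heavy atom as read from a coordinate file (pre-typing)."""

    element: str
    residue: str
    resnum: str  # author number + insertion code
    chain: str
    name: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class ComplexMetadata:
    experimental_method: str = "X-RAY DIFFRACTION"
    ligand_component_id: str = ""
    n_ligand_copies: int = 1
    has_nucleic_acid: bool = False
    het_components: tuple[str, ...] = ()


@dataclass
class RawComplex:
    """Protein and ligand heavy atoms of one complex, plus header metadata."""

    name: str
    protein_atoms: list[RawAtom] = field(default_factory=list)
    ligand_atoms: list[RawAtom] = field(default_factory=list)
    metadata: ComplexMetadata = field(default_factory=ComplexMetadata)

    def min_interface_distance(self) -> float:
        if not self.protein_atoms or not self.ligand_atoms:
            return math.inf
        p = np.asarray([a.xyz for a in self.protein_atoms])
        l = np.asarray([a.xyz for a in self.ligand_atoms])
        return float(cdist(l, p).min())


@dataclass
class LigandBondGraph:
    """Bond graph of one ligand component, hydrogens contracted to counts."""

    component_id: str
    atoms: list[tuple[str, str, int]]  # (atom_name, element, formal_charge)
    bonds: list[tuple[str, str, float, bool]]  # (name1, name2, order, aromatic)
    hydrogen_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = {a[0] for a in self.atoms}
        for a1, a2, _, _ in self.bonds:
            if a1 not in declared or a2 not in declared:
                raise ValueError(
                    f"{self.component_id}: bond endpoint {a1 if a1 not in declared else a2!r}"
                    " names an undeclared atom")

    def atom_names(self) -> set[str]:
        return {a[0] for a in self.atoms}

    def element(self, name: str) -> str:
        for n, el, _ in self.atoms:
            if n == name:
                return el
        raise KeyError(name)

    def formal_charge(self, name: str) -> int:
        for n, _, q in self.atoms:
            if n == name:
                return q
        raise KeyError(name)

    def neighbors(self, name: str) -> list[tuple[str, float, bool]]:
        out = []
        for a1, a2, order, arom in self.bonds:
            if a1 == name:
                out.append((a2, order, arom))
            elif a2 == name:
                out.append((a1, order, arom))
        return out

    def h_count(self, name: str) -> int:
        return self.hydrogen_counts.get(name, 0)

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        names = self.atom_names()
        seen = {next(iter(names))}
        frontier = list(seen)
        while frontier:
            cur = frontier.pop()
            for nbr, _, _ in self.neighbors(cur):
                if nbr not in seen:
                    seen.add(nbr)
                    frontier.append(nbr)
        return seen == names


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reason: str | None = None  # method|nucleic_acid|heme|multiple_ligands|covalent


# ---------------------------------------------------------------------------
# coordinate reading


def read_complex(path: str | Path, ligand_id: str = "auto", *,
                 exclusions: frozenset[str] | None = None) -> RawComplex:
    """Read a PDB-format complex, returning normalized heavy-atom lists.

    ``ligand_id`` selects the HETATM component treated as the ligand; with
    ``"auto"`` there must be exactly one candidate component after waters,
    buffer ions and metals are set aside.
    """
    path = Path(path)
    if exclusions is None:
        exclusions = excluded_components()
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    method = _experimental_method(path) or "X-RAY DIFFRACTION"
    if not st or len(st) == 0:
        raise ValueError(f"{path}: no model found")
    model = st[0]

    protein: list[RawAtom] = []
    het_groups: dict[str, list[list[RawAtom]]] = {}  # resname -> residue copies
    metal_atoms: list[RawAtom] = []
    has_nucleic = False
    het_components: list[str] = []

    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            atoms = _dedup_altlocs(res)
            heavy = [a for a in atoms if a.element.name not in ("H", "D")]
            if not heavy:
                continue
            raw = [RawAtom(element=a.element.name.upper(), residue=resname,
                           resnum=_resnum(res), chain=chain.name, name=a.name,
                           xyz=(a.pos.x, a.pos.y, a.pos.z),
                           occupancy=a.occ, altloc=a.altloc.replace("\x00", ""))
                   for a in heavy]
            if res.het_flag != "H":
                if resname in _NUCLEIC_RESIDUES:
                    has_nucleic = True
                    continue
                protein.extend(raw)
                continue
            # HETATM side
            if resname not in het_components:
                het_components.append(resname)
            if resname.upper() == str(ligand_id).upper() and ligand_id != "auto":
                het_groups.setdefault(resname, []).append(raw)
                continue
            if resname in exclusions:
                continue
            if len(raw) == 1 and raw[0].element in METAL_ELEMENTS:
                metal_atoms.append(raw[0])
                continue
            het_groups.setdefault(resname, []).append(raw)

    if ligand_id == "auto":
        candidates = sorted(het_groups)
        if not candidates:
            raise ValueError(f"{path}: no ligand entity among HETATM records")
        if len(candidates) > 1:
            raise ValueError(
                f"{path}: ambiguous ligand with ligand_id=auto: {candidates}")
        chosen = candidates[0]
    else:
        chosen = str(ligand_id).upper()
        if chosen not in het_groups:
            raise ValueError(f"{path}: no HETATM component {chosen!r}")

    copies = het_groups[chosen]
    ligand = copies[0]

    # metals coordinated by protein N/O/S join the protein side
    protein = protein + [m for m in metal_atoms if _is_coordinated(m, protein)]

    meta = ComplexMetadata(
        experimental_method=method,
        ligand_component_id=chosen,
        n_ligand_copies=len(copies),
        has_nucleic_acid=has_nucleic,
        het_components=tuple(het_components),
    )
    return RawComplex(name=path.stem, protein_atoms=protein,
                      ligand_atoms=list(ligand), metadata=meta)


def _resnum(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def _dedup_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties -> altloc 'A'/first."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_rank(atom: gemmi.Atom) -> int:
    return 1 if atom.altloc in ("", "A", "\x00") else 0


def _is_coordinated(metal: RawAtom, protein: list[RawAtom]) -> bool:
    donors = [a for a in protein if a.element in ("N", "O", "S")]
    if not donors:
        return False
    d = cdist([metal.xyz], [a.xyz for a in donors])
    return bool(d.min() <= METAL_COORDINATION_CUTOFF)


def _experimental_method(path: Path) -> str | None:
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("EXPDTA"):
                    return line[6:].strip().upper()
                if line.startswith(("ATOM", "HETATM")):
                    break
    except OSError:
        return None
    return None


# ---------------------------------------------------------------------------
# ligand dictionaries


def read_ligand_dictionary(path: str | Path) -> dict[str, LigandBondGraph]:
    """Read ligand bond graphs keyed by component id.

    Accepts a chemical-component-dictionary-style mmCIF (``chem_comp_atom`` /
    ``chem_comp_bond`` categories) or a MOL/SDF file.  Aromaticity flags are
    taken from the file when present and otherwise perceived with RDKit from
    elements, bond orders and formal charges.
    """
    path = Path(path)
    text = path.read_text()
    if "_chem_comp_atom" in text:
        return _read_chem_comp_cif(path)
    return _read_sdf(path)


_ORDER_MAP = {"SING": 1.0, "DOUB": 2.0, "TRIP": 3.0, "AROM": 1.5,
              "1": 1.0, "2": 2.0, "3": 3.0, "4": 1.5}


def _read_chem_comp_cif(path: Path) -> dict[str, LigandBondGraph]:
    doc = gemmi.cif.read(str(path))
    out: dict[str, LigandBondGraph] = {}
    for block in doc:
        atoms_tab = block.find("_chem_comp_atom.",
                               ["comp_id", "atom_id", "type_symbol", "?charge"])
        if len(atoms_tab) == 0:
            continue
        comp_atoms: dict[str, list[tuple[str, str, int]]] = {}
        for row in atoms_tab:
            comp = row[0]
            name = gemmi.cif.as_string(row[1])
            el = gemmi.cif.as_string(row[2]).upper()
            q = 0
            if row.has(3) and row[3] not in (".", "?"):
                q = int(float(row[3]))
            comp_atoms.setdefault(comp, []).append((name, el, q))
        bonds_tab = block.find("_chem_comp_bond.",
                               ["comp_id", "atom_id_1", "atom_id_2",
                                "value_order", "?pdbx_aromatic_flag"])
        comp_bonds: dict[str, list[tuple[str, str, float, bool]]] = {}
        have_flags = False
        for row in bonds_tab:
            comp = row[0]
            a1 = gemmi.cif.as_string(row[1])
            a2 = gemmi.cif.as_string(row[2])
            order_s = gemmi.cif.as_string(row[3]).upper()
            order = _ORDER_MAP.get(order_s, 1.0)
            arom = False
            if row.has(4) and row[4] not in (".", "?"):
                have_flags = True
                arom = gemmi.cif.as_string(row[4]).upper() == "Y"
            comp_bonds.setdefault(comp, []).append((a1, a2, order, arom))
        for comp, atoms in comp_atoms.items():
            if atoms and comp not in comp_bonds and len(atoms) > 1:
                raise ValueError(f"{path}: component {comp!r} has no bonds block")
            graph = _contract_hydrogens(comp, atoms, comp_bonds.get(comp, []))
            if not have_flags or not any(b[3] for b in graph.bonds):
                graph = _perceive_aromaticity(graph)
            out[comp] = graph
    if not out:
        raise ValueError(f"{path}: no chem_comp components found")
    return out


def _read_sdf(path: Path) -> dict[str, LigandBondGraph]:
    from rdkit import Chem

    out: dict[str, LigandBondGraph] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable MOL/SDF record #{i}")
        comp = (mol.GetProp("_Name").strip() or f"LIG{i}") if mol.HasProp("_Name") else f"LIG{i}"
        atoms: list[tuple[str, str, int]] = []
        names: dict[int, str] = {}
        counters: dict[str, int] = {}
        hcounts: dict[str, int] = {}
        for atom in mol.GetAtoms():
            el = atom.GetSymbol().upper()
            if el == "H":
                continue
            counters[el] = counters.get(el, 0) + 1
            info = atom.GetMonomerInfo()
            name = info.GetName().strip() if info is not None else f"{el}{counters[el]}"
            names[atom.GetIdx()] = name
            atoms.append((name, el, atom.GetFormalCharge()))
            hcounts[name] = atom.GetTotalNumHs(includeNeighbors=True)
        bonds: list[tuple[str, str, float, bool]] = []
        for bond in mol.GetBonds():
            i1, i2 = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i1 not in names or i2 not in names:
                continue  # bond to hydrogen
            bonds.append((names[i1], names[i2], float(bond.GetBondTypeAsDouble()),
                          bond.GetIsAromatic()))
        out[comp] = LigandBondGraph(comp, atoms, bonds, hcounts)
    if not out:
        raise ValueError(f"{path}: no molecules in MOL/SDF file")
    return out


def _contract_hydrogens(comp: str, atoms: list[tuple[str, str, int]],
                        bonds: list[tuple[str, str, float, bool]]) -> LigandBondGraph:
    h_names = {n for n, el, _ in atoms if el in ("H", "D")}
    heavy = [a for a in atoms if a[0] not in h_names]
    hcounts: dict[str, int] = {a[0]: 0 for a in heavy}
    heavy_bonds = []
    for a1, a2, order, arom in bonds:
        if a1 in h_names or a2 in h_names:
            partner = a2 if a1 in h_names else a1
            if partner in hcounts:
                hcounts[partner] += 1
            continue
        heavy_bonds.append((a1, a2, order, arom))
    return LigandBondGraph(comp, heavy, heavy_bonds, hcounts)


def _perceive_aromaticity(graph: LigandBondGraph) -> LigandBondGraph:
    """Perceive aromatic bonds with RDKit when the file carries no flags."""
    from rdkit import Chem

    mol = Chem.RWMol()
    idx: dict[str, int] = {}
    for name, el, q in graph.atoms:
        a = Chem.Atom(el.capitalize())
        a.SetFormalCharge(q)
        if name in graph.hydrogen_counts:
            a.SetNumExplicitHs(graph.hydrogen_counts[name])
            a.SetNoImplicit(True)
        idx[name] = mol.AddAtom(a)
    btype = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
             3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for a1, a2, order, _ in graph.bonds:
        mol.AddBond(idx[a1], idx[a2], btype.get(order, Chem.BondType.SINGLE))
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        warnings.warn(f"{graph.component_id}: aromaticity perception failed; "
                      "keeping file bond orders")
        return graph
    rev = {v: k for k, v in idx.items()}
    arom_pairs = {frozenset((rev[b.GetBeginAtomIdx()], rev[b.GetEndAtomIdx()]))
                  for b in mol.GetBonds() if b.GetIsAromatic()}
    new_bonds = [(a1, a2, order, frozenset((a1, a2)) in arom_pairs)
                 for a1, a2, order, _ in graph.bonds]
    return LigandBondGraph(graph.component_id, list(graph.atoms), new_bonds,
                           dict(graph.hydrogen_counts))


# ---------------------------------------------------------------------------
# corpus eligibility


def corpus_eligibility(cx: RawComplex, *,
                       covalent_cutoff: float = COVALENT_CUTOFF) -> EligibilityVerdict:
    """Decide whether a complex may enter the contact-statistics corpus."""
    method = cx.metadata.experimental_method.upper()
    if "X-RAY" not in method:
        return EligibilityVerdict(False, "method")
    if cx.metadata.has_nucleic_acid:
        return EligibilityVerdict(False, "nucleic_acid")
    if any(c in HEME_COMPONENTS for c in cx.metadata.het_components):
        return EligibilityVerdict(False, "heme")
    if cx.metadata.n_ligand_copies > 1:
        return EligibilityVerdict(False, "multiple_ligands")
    if cx.min_interface_distance() < covalent_cutoff:
        return EligibilityVerdict(False, "covalent")
    return EligibilityVerdict(True, None)


# ---------------------------------------------------------------------------
# writing


def write_complex_pdb(cx: RawComplex, path: str | Path) -> None:
    """Write the normalized complex back out as PDB text."""
    lines = []
    serial = 1
    for record, atoms in (("ATOM", cx.protein_atoms), ("HETATM", cx.ligand_atoms)):
        for a in atoms:
            lines.append(_pdb_line(record, serial, a))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(record: str, serial: int, a: RawAtom) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    num = a.resnum
    icode = " "
    if num and not num[-1].isdigit():
        num, icode = num[:-1], num[-1]
    return (f"{record:<6s}{serial:>5d} {name:<4s}{a.altloc or ' '}"
            f"{a.residue:>3s} {a.chain[:1] or 'A'}{int(num or 0):>4d}{icode}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{a.occupancy:6.2f}"
            f"{0.0:6.2f}          {a.element:>2s}")


def write_complex_tsv(cx: RawComplex, path: str | Path) -> None:
    """Normalized listing: origin, chain, resname, resnum, atom, element, xyz."""
    rows = ["origin\tchain\tresname\tresnum\tatomname\telement\tx\ty\tz"]
    for origin, atoms in (("protein", cx.protein_atoms), ("ligand", cx.ligand_atoms)):
        for a in atoms:
            rows.append(f"{origin}\t{a.chain}\t{a.residue}\t{a.resnum}\t{a.name}"
                        f"\t{a.element}\t{a.xyz[0]:.3f}\t{a.xyz[1]:.3f}\t{a.xyz[2]:.3f}")
    Path(path).write_text("\n".join(rows) + "\n")
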