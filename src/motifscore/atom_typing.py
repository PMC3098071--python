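"""Assignment of the 23-code heavy-atom type alphabet.

Each heavy atom gets a 3-character code: element (C/N/O/S), environment
(2 = sp2, 3 = sp3, R = aromatic ring, L = aliphatic) and chemical role
(P polar, N non-polar, A hydrogen-bond acceptor, D donor, B both,
E either-donor-or-acceptor, C charged).  Rare elements keep single-purpose
codes: PHO (phosphorus), MET (metal), HAL (halogen).  Protein atoms are
typed from a fixed residue/atom-name lookup shipped with the package;
ligand atoms are typed from their bond graph (element, bond orders,
aromaticity, hydrogen counts, formal charges).

Elements outside the alphabet (boron, selenium, ...) are typed ``UNK``;
they still take part in interaction networks through the default distance
rule but never define motif identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

from .complex_io import LigandBondGraph, RawAtom, RawComplex, METAL_ELEMENTS
from .core import LIGAND, PROTEIN, UNK, TypedAtom, TypedComplex

__all__ = [
    "AtomTypeCode",
    "ATOM_TYPES",
    "PROTEIN_TYPES",
    "LIGAND_TYPES",
    "protein_lookup",
    "assign_protein_atom_types",
    "assign_ligand_atom_types",
    "type_complex",
]

HALOGENS = {"F", "CL", "BR", "I"}


@dataclass(frozen=True)
class AtomTypeCode:
    code: str
    description: str
    protein_capable: bool
    ligand_capable: bool


def _t(code, desc, prot, lig):
    return AtomTypeCode(code, desc, prot, lig)


#: The closed 23-code alphabet.  The capability flags follow the published
#: availability columns (14 protein-capable, 20 ligand-capable) and define
#: the 280-pair threshold universe; the assignment rules below may place a
#: code on the other side as well (e.g. NLC on lysine/arginine nitrogens,
#: OLC on a ligand carboxylate) — such pairs fall back to the default rule.
ATOM_TYPES: dict[str, AtomTypeCode] = {t.code: t for t in [
    _t("C2N", "C, sp2, non-polar", False, True),
    _t("C2P", "C, sp2, polar", True, True),
    _t("C3N", "C, sp3, non-polar", True, True),
    _t("C3P", "C, sp3, polar", True, True),
    _t("CRN", "C, aromatic, non-polar", True, True),
    _t("CRP", "C, aromatic, polar", True, True),
    _t("O2A", "O, sp2, H-bond acceptor", True, True),
    _t("O3A", "O, sp3, H-bond acceptor", False, True),
    _t("O3B", "O, sp3, donor and acceptor", True, True),
    _t("OLC", "O, aliphatic, charged", True, False),
    _t("ORA", "O, aromatic, H-bond acceptor", False, True),
    _t("NLA", "N, aliphatic, H-bond acceptor", True, True),
    _t("NLB", "N, aliphatic, H-bond donor", True, True),
    _t("NLC", "N, aliphatic, charged", False, True),
    _t("NRA", "N, aromatic, H-bond acceptor", False, True),
    _t("NRD", "N, aromatic, H-bond donor", True, True),
    _t("NRE", "N, aromatic, donor or acceptor", True, False),
    _t("S3N", "S, sp3, non-polar", True, True),
    _t("SRA", "S, aromatic, H-bond acceptor", False, True),
    _t("SLC", "S, aliphatic, charged", False, True),
    _t("PHO", "phosphorus", False, True),
    _t("MET", "metal", True, False),
    _t("HAL", "halogen (F, Cl, Br, I)", False, True),
]}

PROTEIN_TYPES: tuple[str, ...] = tuple(c for c, t in ATOM_TYPES.items() if t.protein_capable)
LIGAND_TYPES: tuple[str, ...] = tuple(c for c, t in ATOM_TYPES.items() if t.ligand_capable)


# ---------------------------------------------------------------------------
# protein side: residue/atom-name lookup


_lookup_cache: dict[tuple[str, str], str] | None = None


def protein_lookup() -> dict[tuple[str, str], str]:
    """(residue, atom_name) -> code table; '*' rows match any residue."""
    global _lookup_cache
    if _lookup_cache is None:
        table: dict[tuple[str, str], str] = {}
        text = resources.files("motifscore.data").joinpath("protein_atom_types.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            residue, atom, code = line.split("\t")
            if code not in ATOM_TYPES:
                raise ValueError(f"lookup table uses unknown code {code!r}")
            table[(residue, atom)] = code
        _lookup_cache = table
    return _lookup_cache


def _protein_code(atom: RawAtom, table: dict[tuple[str, str], str]) -> str | None:
    exact = table.get((atom.residue, atom.name))
    if exact is not None:
        return exact
    if atom.element in METAL_ELEMENTS:
        return "MET"
    return table.get(("*", atom.name))


def assign_protein_atom_types(cx: RawComplex) -> list[TypedAtom]:
    """Type every protein heavy atom of the 20 standard residues plus metals.

    Atoms of unknown residues (or unknown atom names) are left untyped and
    dropped from the result, with a warning — they would otherwise distort
    the corpus atom-type occurrence statistics.
    """
    table = protein_lookup()
    typed: list[TypedAtom] = []
    skipped: set[tuple[str, str]] = set()
    for atom in cx.protein_atoms:
        code = _protein_code(atom, table)
        if code is None:
            skipped.add((atom.residue, atom.name))
            continue
        typed.append(TypedAtom(PROTEIN, atom.name, atom.element, atom.xyz,
                               code=code, chain=atom.chain,
                               residue=atom.residue, resnum=atom.resnum))
    if skipped:
        warnings.warn(f"{cx.name}: untyped protein atoms excluded: {sorted(skipped)}")
    return typed


# ---------------------------------------------------------------------------
# ligand side: bond-graph perception


def _is_charged_oxygen(name: str, graph: LigandBondGraph) -> bool:
    """Carboxylate / sulfate / phosphate style oxygen -> OLC.

    True for a terminal oxygen whose parent bears at least two terminal
    oxygens, when the parent is S or P, or the group carries a formal
    negative charge, or the parent is a carbon with exactly two terminal
    oxygens (a carboxylate, protonated or not).
    """
    nbrs = graph.neighbors(name)
    if len(nbrs) != 1:
        return False
    parent = nbrs[0][0]
    parent_el = graph.element(parent)
    terminal_os = [n for n, _, _ in graph.neighbors(parent)
                   if graph.element(n) == "O" and len(graph.neighbors(n)) == 1]
    if len(terminal_os) < 2:
        return False
    if parent_el in ("S", "P"):
        return True
    if graph.formal_charge(parent) < 0 or any(graph.formal_charge(o) < 0 for o in terminal_os):
        return True
    return parent_el == "C" and len(terminal_os) == 2


def _ligand_code(name: str, graph: LigandBondGraph) -> str:
    el = graph.element(name)
    if el in HALOGENS:
        return "HAL"
    if el == "P":
        return "PHO"
    if el in METAL_ELEMENTS:
        return "MET"
    if el not in ("C", "N", "O", "S"):
        return UNK

    nbrs = graph.neighbors(name)
    aromatic = any(arom for _, _, arom in nbrs)
    max_order = max((order for _, order, _ in nbrs), default=1.0)
    polar = any(graph.element(n) in {"N", "O", "S"} | HALOGENS for n, _, _ in nbrs)
    h = graph.h_count(name)
    q = graph.formal_charge(name)

    if el == "C":
        if aromatic:
            return "CRP" if polar else "CRN"
        if max_order >= 2:
            return "C2P" if polar else "C2N"
        return "C3P" if polar else "C3N"
    if el == "O":
        if aromatic:
            return "ORA"
        if _is_charged_oxygen(name, graph) or q < 0:
            return "OLC"
        if max_order >= 2:
            return "O2A"
        if len(nbrs) >= 2:
            return "O3A"  # ether/ester oxygen: acceptor only
        return "O3B"  # hydroxyl: donor and acceptor
    if el == "N":
        if aromatic:
            return "NRD" if (h > 0 or q > 0) else "NRA"
        if q > 0 or h >= 3:
            return "NLC"
        return "NLB" if h > 0 else "NLA"
    # sulfur
    if aromatic:
        return "SRA"
    terminal_os = [n for n, _, _ in nbrs
                   if graph.element(n) == "O" and len(graph.neighbors(n)) == 1]
    if q < 0 or len(terminal_os) >= 2:
        return "SLC"
    return "S3N"


def assign_ligand_atom_types(cx: RawComplex, graph: LigandBondGraph) -> list[TypedAtom]:
    """Type ligand heavy atoms from the component's bond graph."""
    known = graph.atom_names()
    typed: list[TypedAtom] = []
    for atom in cx.ligand_atoms:
        if atom.name not in known:
            raise KeyError(
                f"{cx.name}: ligand atom {atom.name!r} missing from bond graph of "
                f"{graph.component_id!r}")
        typed.append(TypedAtom(LIGAND, atom.name, atom.element, atom.xyz,
                               code=_ligand_code(atom.name, graph),
                               chain=atom.chain, residue=atom.residue,
                               resnum=atom.resnum))
    return typed


def type_complex(cx: RawComplex, graph: LigandBondGraph) -> TypedComplex:
    """Convenience: type both sides and return a :class:`TypedComplex`."""
    return TypedComplex(cx.name,
                        assign_protein_atom_types(cx),
                        assign_ligand_atom_types(cx, graph))
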