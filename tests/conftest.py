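"""Shared fixtures: a default threshold table, tiny PDB/dictionary texts,
random bipartite networks, and an exhaustive motif-enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from motifscore.atom_typing import LIGAND_TYPES, PROTEIN_TYPES
from motifscore.core import LIGAND, PROTEIN, UNK, TypedAtom, TypedComplex
from motifscore.motif_engine import canonical_key, classify_topology
from motifscore.network import InteractionNetwork
from motifscore.thresholds import ThresholdTable


@pytest.fixture
def default_table() -> ThresholdTable:
    """Empty table: every pair resolves to the category-4 2-4 A window."""
    return ThresholdTable()


def random_network(rng: np.random.Generator, max_ligand: int = 8,
                   max_protein: int = 15, p_edge: float = 0.25) -> InteractionNetwork:
    """Random bipartite network with random atom types (geometry-free)."""
    n_l = int(rng.integers(2, max_ligand + 1))
    n_p = int(rng.integers(3, max_protein + 1))
    lig = [TypedAtom(LIGAND, f"L{i}", "C", (float(i), 0.0, 0.0),
                     code=LIGAND_TYPES[rng.integers(len(LIGAND_TYPES))])
           for i in range(n_l)]
    prot = [TypedAtom(PROTEIN, f"P{i}", "C", (float(i), 5.0, 0.0),
                      code=PROTEIN_TYPES[rng.integers(len(PROTEIN_TYPES))])
            for i in range(n_p)]
    net = InteractionNetwork(TypedComplex("rand", prot, lig))
    for li in range(n_l):
        for pi in range(n_p):
            if rng.random() < p_edge:
                net.edges.append((li, pi, 3.0))
    return net


def exhaustive_motifs(net: InteractionNetwork):
    """Oracle: test the induced subgraph of every C(L,2) x C(P,3) selection."""
    cx = net.complex
    edge_set = net.edge_set()
    out = []
    for l1, l2 in itertools.combinations(range(len(cx.ligand)), 2):
        for triple in itertools.combinations(range(len(cx.protein)), 3):
            induced = frozenset(
                (a, b)
                for a, li in enumerate((l1, l2))
                for b, pi in enumerate(triple)
                if (li, pi) in edge_set)
            if classify_topology(induced) is None:
                continue
            ltypes = (cx.ligand[l1].code, cx.ligand[l2].code)
            ptypes = tuple(cx.protein[p].code for p in triple)
            if UNK in ltypes or UNK in ptypes:
                continue
            out.append((canonical_key(ltypes, ptypes, induced), (l1, l2), triple))
    return sorted(out, key=lambda t: (t[1], t[2]))


SMALL_PDB = """\
HEADER    SYNTHETIC TEST COMPLEX
EXPDTA    X-RAY DIFFRACTION
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  CB AALA A   1      12.000  11.300  10.000  0.60  0.00           C
ATOM      4  CB BALA A   1      12.100  11.400  10.100  0.40  0.00           C
ATOM      5  C   ALA A   1      12.000   8.800  10.000  1.00  0.00           C
ATOM      6  O   ALA A   1      11.400   7.700  10.000  1.00  0.00           O
ATOM      7  HA  ALA A   1      11.500   9.000  11.000  1.00  0.00           H
HETATM    8 ZN    ZN A  90      10.000   8.200  10.000  1.00  0.00          ZN
HETATM    9  O   HOH A  99       5.000   5.000   5.000  1.00  0.00           O
HETATM   10  C1  BZA L 201      14.000  10.500  12.500  1.00  0.00           C
HETATM   11  O1  BZA L 201      14.800  11.400  12.600  1.00  0.00           O
HETATM   12  O2  BZA L 201      14.100   9.500  13.300  1.00  0.00           O
END
"""

BZA_DICT = """\
data_BZA
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
BZA C1 C 0
BZA O1 O 0
BZA O2 O -1
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
BZA C1 O1 DOUB
BZA C1 O2 SING
"""


@pytest.fixture
def small_pdb(tmp_path):
    p = tmp_path / "small.pdb"
    p.write_text(SMALL_PDB)
    return p


@pytest.fixture
def bza_dict(tmp_path):
    p = tmp_path / "bza.cif"
    p.write_text(BZA_DICT)
    return p
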