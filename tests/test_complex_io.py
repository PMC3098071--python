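"""Complex loading, ligand dictionaries, and corpus eligibility filters."""

import math

import numpy as np
import pytest

from motifscore.complex_io import (
    ComplexMetadata, LigandBondGraph, RawAtom, RawComplex,
    corpus_eligibility, read_complex, read_ligand_dictionary,
    write_complex_pdb, write_complex_tsv)

FURAN_DICT = """\
data_FUR
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
FUR O1 O 0
FUR C2 C 0
FUR C3 C 0
FUR C4 C 0
FUR C5 C 0
FUR H2 H 0
FUR H3 H 0
FUR H4 H 0
FUR H5 H 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
FUR O1 C2 SING
FUR C2 C3 DOUB
FUR C3 C4 SING
FUR C4 C5 DOUB
FUR C5 O1 SING
FUR C2 H2 SING
FUR C3 H3 SING
FUR C4 H4 SING
FUR C5 H5 SING
"""

BENZENE_SDF = """\
BNZ
  synthetic

 12 12  0  0  0  0  0  0  0  0999 V2000
    0.0000    1.3960    0.0000 C   0  0
    1.2090    0.6980    0.0000 C   0  0
    1.2090   -0.6980    0.0000 C   0  0
    0.0000   -1.3960    0.0000 C   0  0
   -1.2090   -0.6980    0.0000 C   0  0
   -1.2090    0.6980    0.0000 C   0  0
    0.0000    2.4760    0.0000 H   0  0
    2.1450    1.2380    0.0000 H   0  0
    2.1450   -1.2380    0.0000 H   0  0
    0.0000   -2.4760    0.0000 H   0  0
   -2.1450   -1.2380    0.0000 H   0  0
   -2.1450    1.2380    0.0000 H   0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  1  7  1  0
  2  8  1  0
  3  9  1  0
  4 10  1  0
  5 11  1  0
  6 12  1  0
M  END
$$$$
"""


class TestReadComplex:
    def test_filters_and_sides(self, small_pdb):
        """Hydrogens, waters and altloc duplicates are removed; the
        coordinated zinc joins the protein side."""
        cx = read_complex(small_pdb)
        names = [a.name for a in cx.protein_atoms]
        assert names == ["N", "CA", "CB", "C", "O", "ZN"]
        assert [a.name for a in cx.ligand_atoms] == ["C1", "O1", "O2"]
        assert all(a.element != "H" for a in cx.protein_atoms + cx.ligand_atoms)
        # altloc A kept (higher occupancy)
        cb = next(a for a in cx.protein_atoms if a.name == "CB")
        assert cb.altloc == "A" and cb.occupancy == pytest.approx(0.6)
        assert cx.metadata.ligand_component_id == "BZA"
        assert cx.metadata.n_ligand_copies == 1

    def test_no_ligand_is_an_error(self, tmp_path):
        p = tmp_path / "apo.pdb"
        p.write_text("ATOM      1  N   ALA A   1      10.000  10.000  10.000"
                     "  1.00  0.00           N\nEND\n")
        with pytest.raises(ValueError, match="no ligand entity"):
            read_complex(p)

    def test_ambiguous_ligand_is_an_error(self, tmp_path, small_pdb):
        text = small_pdb.read_text().replace(
            "END\n",
            "HETATM   13  C1  XYZ L 301      20.000  20.000  20.000  1.00  0.00"
            "           C\nEND\n")
        p = tmp_path / "two.pdb"
        p.write_text(text)
        with pytest.raises(ValueError, match="ambiguous"):
            read_complex(p)
        assert read_complex(p, ligand_id="BZA").metadata.ligand_component_id == "BZA"

    def test_water_count_fixture(self, tmp_path):
        """5 protein heavy atoms + 1 water + 3 ligand atoms -> 5 + 3."""
        lines = ["EXPDTA    X-RAY DIFFRACTION"]
        for i, name in enumerate(["N", "CA", "C", "O", "CB"]):
            lines.append(f"ATOM  {i + 1:>5d}  {name:<3s} ALA A   1    "
                         f"{10 + i:8.3f}{10.0:8.3f}{10.0:8.3f}  1.00  0.00"
                         f"           {name[0]}")
        lines.append("HETATM    6  O   HOH A  99       2.000   2.000   2.000"
                     "  1.00  0.00           O")
        for i, name in enumerate(["C1", "C2", "O1"]):
            lines.append(f"HETATM{7 + i:>5d}  {name:<3s} LIG L 201    "
                         f"{20 + i:8.3f}{10.0:8.3f}{10.0:8.3f}  1.00  0.00"
                         f"           {name[0]}")
        p = tmp_path / "counts.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        cx = read_complex(p)
        assert len(cx.protein_atoms) == 5
        assert len(cx.ligand_atoms) == 3

    def test_roundtrip_through_pdb_text(self, small_pdb, tmp_path):
        cx = read_complex(small_pdb)
        out = tmp_path / "rt.pdb"
        write_complex_pdb(cx, out)
        cx2 = read_complex(out, ligand_id="BZA")
        assert [a.name for a in cx2.protein_atoms] == [a.name for a in cx.protein_atoms]
        np.testing.assert_allclose(
            [a.xyz for a in cx2.protein_atoms + cx2.ligand_atoms],
            [a.xyz for a in cx.protein_atoms + cx.ligand_atoms], atol=1e-3)

    def test_tsv_export(self, small_pdb, tmp_path):
        cx = read_complex(small_pdb)
        out = tmp_path / "listing.tsv"
        write_complex_tsv(cx, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("origin\tchain")
        assert len(lines) == 1 + len(cx.protein_atoms) + len(cx.ligand_atoms)


class TestLigandDictionary:
    def test_benzene_sdf(self, tmp_path):
        p = tmp_path / "bnz.sdf"
        p.write_text(BENZENE_SDF)
        graph = read_ligand_dictionary(p)["BNZ"]
        assert len(graph.atoms) == 6
        assert len(graph.bonds) == 6
        assert all(arom for *_, arom in graph.bonds)
        assert all(graph.h_count(n) == 1 for n in graph.atom_names())

    def test_furan_ring_oxygen_is_aromatic(self, tmp_path):
        p = tmp_path / "fur.cif"
        p.write_text(FURAN_DICT)
        graph = read_ligand_dictionary(p)["FUR"]
        assert any(arom for n, _, arom in graph.neighbors("O1"))
        assert graph.h_count("O1") == 0

    def test_dangling_bond_endpoint_is_an_error(self):
        with pytest.raises(ValueError, match="undeclared"):
            LigandBondGraph("BAD", [("C1", "C", 0)], [("C1", "C9", 1.0, False)])

    def test_charges_and_hydrogen_counts(self, bza_dict):
        graph = read_ligand_dictionary(bza_dict)["BZA"]
        assert graph.formal_charge("O2") == -1
        assert graph.is_connected()


def _fixture_raw(min_dist: float, method: str = "X-RAY DIFFRACTION",
                 het: tuple[str, ...] = ("LIG",), copies: int = 1,
                 nucleic: bool = False) -> RawComplex:
    prot = [RawAtom("S", "CYS", "1", "A", "SG", (0.0, 0.0, 0.0))]
    lig = [RawAtom("C", "LIG", "1", "L", "C1", (min_dist, 0.0, 0.0))]
    meta = ComplexMetadata(experimental_method=method, ligand_component_id="LIG",
                           n_ligand_copies=copies, has_nucleic_acid=nucleic,
                           het_components=het)
    return RawComplex("fix", prot, lig, meta)


class TestEligibility:
    def test_eligible_xray_single_ligand(self):
        verdict = corpus_eligibility(_fixture_raw(3.5))
        assert verdict.eligible and verdict.reason is None

    @pytest.mark.parametrize("cx,reason", [
        (_fixture_raw(3.5, method="SOLUTION NMR"), "method"),
        (_fixture_raw(3.5, nucleic=True), "nucleic_acid"),
        (_fixture_raw(3.5, het=("HEM", "LIG")), "heme"),
        (_fixture_raw(3.5, copies=2), "multiple_ligands"),
        (_fixture_raw(1.4), "covalent"),  # 1.4 A to a cysteine sulfur
    ])
    def test_exclusion_reasons(self, cx, reason):
        verdict = corpus_eligibility(cx)
        assert not verdict.eligible
        assert verdict.reason == reason

    def test_filter_is_idempotent(self, small_pdb):
        cx1 = read_complex(small_pdb)
        cx2 = read_complex(small_pdb)
        assert corpus_eligibility(cx1) == corpus_eligibility(cx2)
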