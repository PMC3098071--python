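"""Motif topologies, canonical keys, enumeration, and significance grades."""

import math
from itertools import permutations

import numpy as np
import pytest

from conftest import exhaustive_motifs, random_network
from motifscore.core import LIGAND, PROTEIN, TypedAtom, TypedComplex
from motifscore.motif_engine import (
    CANONICAL_EDGES, MotifKey, MotifTopology, accumulate_statistics,
    canonical_key, classify_topology, enumerate_motifs, significance_grade)
from motifscore.network import InteractionNetwork, build_network
from motifscore.thresholds import ThresholdTable


class TestTopologyClassification:
    def test_reference_edge_sets_classify_to_themselves(self):
        for topo, edges in CANONICAL_EDGES.items():
            assert classify_topology(edges) is topo

    def test_inadmissible_edge_sets(self):
        # an isolated protein node
        assert classify_topology(frozenset({(0, 0), (0, 1), (1, 0), (1, 1)})) is None
        # an isolated ligand node
        assert classify_topology(frozenset({(0, 0), (0, 1), (0, 2)})) is None
        # 3 edges only
        assert classify_topology(frozenset({(0, 0), (1, 1), (0, 2)})) is None

    def test_edge_counts(self):
        assert len(CANONICAL_EDGES[MotifTopology.FULL]) == 6
        assert len(CANONICAL_EDGES[MotifTopology.FIVE]) == 5
        assert len(CANONICAL_EDGES[MotifTopology.FOUR_2P2]) == 4
        assert len(CANONICAL_EDGES[MotifTopology.FOUR_3P1]) == 4


class TestCanonicalKey:
    @pytest.mark.parametrize("topo", list(MotifTopology))
    def test_permutation_invariance(self, topo):
        """All 12 relabelings of an instance map to one canonical key."""
        ltypes = ("CRN", "ORA")
        ptypes = ("NRE", "S3N", "O3B")
        edges = CANONICAL_EDGES[topo]
        keys = set()
        for lp in permutations(range(2)):
            for pp in permutations(range(3)):
                perm_edges = frozenset((lp[l], pp[p]) for l, p in edges)
                perm_lt = tuple(ltypes[lp.index(i)] for i in range(2))
                perm_pt = tuple(ptypes[pp.index(i)] for i in range(3))
                keys.add(canonical_key(perm_lt, perm_pt, perm_edges))
        assert len(keys) == 1

    def test_swapping_equal_ligand_atoms_is_identity(self):
        edges = CANONICAL_EDGES[MotifTopology.FULL]
        a = canonical_key(("CRN", "ORA"), ("CRN", "CRN", "CRN"), edges)
        b = canonical_key(("ORA", "CRN"), ("CRN", "CRN", "CRN"), edges)
        assert a == b

    def test_idempotence(self):
        edges = CANONICAL_EDGES[MotifTopology.FIVE]
        key = canonical_key(("C2N", "HAL"), ("NRE", "CRP", "S3N"), edges)
        again = canonical_key(key.ligand_types, key.protein_types, edges)
        assert key == again

    def test_rejects_inadmissible_graphs(self):
        with pytest.raises(ValueError, match="not an admissible"):
            canonical_key(("C2N", "HAL"), ("NRE", "CRP", "S3N"),
                          frozenset({(0, 0), (0, 1), (0, 2)}))


class TestEnumeration:
    def test_complete_k23_is_one_full_motif(self):
        lig = [TypedAtom(LIGAND, f"L{i}", "C", (float(i), 0, 0), code="CRN")
               for i in range(2)]
        prot = [TypedAtom(PROTEIN, f"P{i}", "C", (float(i), 5, 0), code="CRN")
                for i in range(3)]
        net = InteractionNetwork(TypedComplex("k23", prot, lig),
                                 [(l, p, 3.0) for l in range(2) for p in range(3)])
        inst = enumerate_motifs(net)
        assert len(inst) == 1
        assert inst[0].key.topology is MotifTopology.FULL

    def test_single_ligand_atom_yields_nothing(self):
        lig = [TypedAtom(LIGAND, "L0", "C", (0, 0, 0), code="CRN")]
        prot = [TypedAtom(PROTEIN, f"P{i}", "C", (float(i), 5, 0), code="CRN")
                for i in range(3)]
        net = InteractionNetwork(TypedComplex("s", prot, lig),
                                 [(0, p, 3.0) for p in range(3)])
        assert enumerate_motifs(net) == []

    def test_unk_atoms_never_enter_motifs(self):
        lig = [TypedAtom(LIGAND, "L0", "C", (0, 0, 0), code="CRN"),
               TypedAtom(LIGAND, "L1", "X", (1, 0, 0), code="UNK")]
        prot = [TypedAtom(PROTEIN, f"P{i}", "C", (float(i), 5, 0), code="CRN")
                for i in range(3)]
        net = InteractionNetwork(TypedComplex("u", prot, lig),
                                 [(l, p, 3.0) for l in range(2) for p in range(3)])
        assert enumerate_motifs(net) == []

    def test_matches_exhaustive_oracle_on_random_networks(self):
        """Enumerator vs brute-force over every 5-node selection."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            net = random_network(rng)
            ours = sorted(((i.key, i.ligand_indices, i.protein_indices)
                           for i in enumerate_motifs(net)),
                          key=lambda t: (t[1], t[2]))
            assert ours == exhaustive_motifs(net)


def _network_of_key(key: MotifKey, name="nk") -> InteractionNetwork:
    from motifscore.fixtures import make_motif_complex
    cx = make_motif_complex([key], name=name)
    return build_network(cx, ThresholdTable())


class TestStatistics:
    def test_single_full_instance_counts(self):
        key = MotifKey(MotifTopology.FULL, ("CRN", "ORA"), ("CRN", "CRN", "CRN"))
        stats = accumulate_statistics([_network_of_key(key)])
        assert stats.OM[key] == 1
        assert stats.topology_totals[MotifTopology.FULL] == 1
        assert stats.M_l == 2 and stats.M_p == 3

    def test_duplicated_corpus_doubles_counts(self):
        key = MotifKey(MotifTopology.FIVE, ("C2N", "ORA"), ("NRE", "S3N", "S3N"))
        nets = [_network_of_key(key)]
        one = accumulate_statistics(nets)
        two = accumulate_statistics(nets * 2)
        assert two.OM[key] == 2 * one.OM[key]
        assert two.M_l == 2 * one.M_l and two.M_p == 2 * one.M_p

    def test_three_network_corpus_matches_hand_count(self):
        k1 = MotifKey(MotifTopology.FULL, ("CRN", "ORA"), ("CRN", "CRN", "CRN"))
        k2 = MotifKey(MotifTopology.FOUR_2P2, ("HAL", "HAL"), ("S3N", "S3N", "S3N"))
        nets = [_network_of_key(k1, "a"), _network_of_key(k1, "b"),
                _network_of_key(k2, "c")]
        stats = accumulate_statistics(nets)
        assert stats.OM[k1] == 2 and stats.OM[k2] == 1
        assert stats.topology_totals[MotifTopology.FULL] == 2
        assert stats.topology_totals[MotifTopology.FOUR_2P2] == 1
        assert sum(stats.OM.values()) == sum(stats.topology_totals.values())

    def test_conservation_across_random_corpora(self):
        rng = np.random.default_rng(5)
        nets = [random_network(rng, 5, 8) for _ in range(10)]
        stats = accumulate_statistics(nets)
        for topo in MotifTopology:
            per_topo = sum(c for k, c in stats.OM.items() if k.topology is topo)
            assert per_topo == stats.topology_totals[topo]

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        stats = accumulate_statistics([random_network(rng, 5, 8) for _ in range(5)])
        path = tmp_path / "stats.tsv"
        stats.save(path)
        again = type(stats).load(path)
        assert again.OM == stats.OM
        assert again.topology_totals == stats.topology_totals
        assert (again.M_l, again.M_p) == (stats.M_l, stats.M_p)
        assert again.OA_ligand == stats.OA_ligand


class TestSignificanceGrade:
    def test_uniform_single_type_corpus_grades_zero(self):
        """One observed key, every atom the same type: OM/N = 1 and each
        OA/M = 1, so the log-ratio vanishes."""
        key = MotifKey(MotifTopology.FULL, ("C3N", "C3N"), ("C3N", "C3N", "C3N"))
        stats = accumulate_statistics([_network_of_key(key)])
        assert significance_grade(stats, key) == pytest.approx(0.0)

    def test_duplication_leaves_every_grade_unchanged(self):
        from motifscore.fixtures import make_toy_corpus
        table = ThresholdTable()
        corpus = make_toy_corpus(6, seed=9)
        nets = [build_network(c, table) for c in corpus]
        s1 = accumulate_statistics(nets)
        s2 = accumulate_statistics(nets * 3)
        for k in s1.OM:
            assert significance_grade(s2, k) == pytest.approx(
                significance_grade(s1, k))

    def test_hand_built_two_complex_corpus(self):
        """SG matches a spreadsheet-style evaluation of the formula."""
        k1 = MotifKey(MotifTopology.FULL, ("CRN", "ORA"), ("CRN", "CRN", "CRN"))
        k2 = MotifKey(MotifTopology.FULL, ("HAL", "HAL"), ("S3N", "S3N", "S3N"))
        stats = accumulate_statistics([_network_of_key(k1), _network_of_key(k2)])
        # corpus: M_l = 4 (CRN, ORA, HAL, HAL), M_p = 6 (3 CRN, 3 S3N)
        # k1: OM/N = 1/2; OA: CRN_l 1/4, ORA 1/4, CRN_p (3/6)^3
        expected = math.log((1 / 2) / ((1 / 4) * (1 / 4) * (3 / 6) ** 3))
        assert significance_grade(stats, k1) == pytest.approx(expected)
        # k2: OM/N = 1/2; HAL 2/4 twice, S3N (3/6)^3
        expected2 = math.log((1 / 2) / ((2 / 4) ** 2 * (3 / 6) ** 3))
        assert significance_grade(stats, k2) == pytest.approx(expected2)

    def test_unseen_key_raises(self):
        key = MotifKey(MotifTopology.FULL, ("C3N", "C3N"), ("C3N", "C3N", "C3N"))
        stats = accumulate_statistics([_network_of_key(key)])
        other = MotifKey(MotifTopology.FULL, ("HAL", "HAL"), ("S3N", "S3N", "S3N"))
        with pytest.raises(KeyError, match="unseen"):
            significance_grade(stats, other)

    def test_keys_stay_inside_the_alphabet(self):
        from motifscore.atom_typing import ATOM_TYPES
        rng = np.random.default_rng(13)
        stats = accumulate_statistics([random_network(rng) for _ in range(20)])
        for key in stats.OM:
            assert set(key.ligand_types) <= set(ATOM_TYPES)
            assert set(key.protein_types) <= set(ATOM_TYPES)
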