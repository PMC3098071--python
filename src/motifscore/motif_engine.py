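"""Enumeration, canonicalization and corpus statistics of 2x3 motifs.

A motif is the induced bipartite subgraph on 2 ligand atoms and 3 protein
atoms of an interaction network, restricted to four admissible topologies
(6, 5, or 4 edges; with 4 edges either both ligand atoms have degree 2 and
share a middle protein atom, or the ligand degrees are 3+1).  A motif's
identity is its topology plus the atom-type codes of its five atoms, up to
any relabeling of atoms that preserves the topology; identities are
canonicalized by explicit minimization over the 2! x 3! node permutations.

Each observed motif gets a significance grade

    SG = ln[ (OM_i / N_i) / prod_j (OA_j / M_side(j)) ]

where OM_i is the motif's occurrence count across the corpus, N_i the total
instance count of its topology, OA_j the corpus occurrence of constituent
atom type j, and M_side the total ligand or protein atom count.  The grade
compares the motif's frequency within its topology with the expectation
under independent atom-type draws, so duplicating the corpus leaves every
SG unchanged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations, permutations
from pathlib import Path

from .core import LIGAND, PROTEIN, UNK
from .network import InteractionNetwork

__all__ = [
    "MotifTopology",
    "MotifKey",
    "MotifInstance",
    "MotifStatistics",
    "CANONICAL_EDGES",
    "classify_topology",
    "canonical_key",
    "enumerate_motifs",
    "accumulate_statistics",
    "significance_grade",
]


class MotifTopology(Enum):
    FULL = "full"  # 6 edges
    FIVE = "five"  # 5 edges
    FOUR_2P2 = "four_2p2"  # 4 edges, ligand degrees 2+2, shared middle
    FOUR_3P1 = "four_3p1"  # 4 edges, ligand degrees 3+1


LocalEdge = tuple[int, int]  # (ligand position 0..1, protein position 0..2)

#: reference edge set of each topology over local node positions
CANONICAL_EDGES: dict[MotifTopology, frozenset[LocalEdge]] = {
    MotifTopology.FULL: frozenset((l, p) for l in (0, 1) for p in (0, 1, 2)),
    MotifTopology.FIVE: frozenset({(0, 0), (0, 1), (0, 2), (1, 0), (1, 1)}),
    MotifTopology.FOUR_2P2: frozenset({(0, 0), (0, 1), (1, 1), (1, 2)}),
    MotifTopology.FOUR_3P1: frozenset({(0, 0), (0, 1), (0, 2), (1, 0)}),
}


def classify_topology(edges: frozenset[LocalEdge]) -> MotifTopology | None:
    """Topology of an induced 2x3 edge set, or None if inadmissible."""
    ldeg = [sum(1 for l, _ in edges if l == i) for i in (0, 1)]
    pdeg = [sum(1 for _, p in edges if p == i) for i in (0, 1, 2)]
    if min(ldeg) == 0 or min(pdeg) == 0:
        return None
    n = len(edges)
    if n == 6:
        return MotifTopology.FULL
    if n == 5:
        return MotifTopology.FIVE
    if n == 4:
        return MotifTopology.FOUR_2P2 if sorted(ldeg) == [2, 2] else MotifTopology.FOUR_3P1
    return None


@dataclass(frozen=True)
class MotifKey:
    """Canonical identity of a motif: topology + per-position atom types."""

    topology: MotifTopology
    ligand_types: tuple[str, str]
    protein_types: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.ligand_types) != 2 or len(self.protein_types) != 3:
            raise ValueError("a motif has exactly 2 ligand and 3 protein atoms")

    @property
    def atom_types(self) -> tuple[tuple[str, str], ...]:
        """(code, side) for all five constituent atoms."""
        return tuple((t, LIGAND) for t in self.ligand_types) + \
            tuple((t, PROTEIN) for t in self.protein_types)

    def __lt__(self, other: "MotifKey") -> bool:  # stable ordering for reports
        return (self.topology.value, self.ligand_types, self.protein_types) < \
            (other.topology.value, other.ligand_types, other.protein_types)


def canonical_key(ligand_types: tuple[str, str], protein_types: tuple[str, str, str],
                  edges: frozenset[LocalEdge]) -> MotifKey:
    """Canonicalize by brute force over all side-preserving permutations.

    Among the <= 12 relabelings that map ``edges`` onto the topology's
    reference edge set, the lexicographically smallest
    (ligand_types, protein_types) assignment is the canonical one.
    """
    topology = classify_topology(edges)
    if topology is None:
        raise ValueError(f"edge set {sorted(edges)} is not an admissible 2x3 motif")
    target = CANONICAL_EDGES[topology]
    best: tuple[tuple[str, str], tuple[str, str, str]] | None = None
    for lp in permutations(range(2)):
        for pp in permutations(range(3)):
            mapped = frozenset((lp[l], pp[p]) for l, p in edges)
            if mapped != target:
                continue
            # lp[l] is the canonical position of input ligand node l
            lt = tuple(ligand_types[lp.index(i)] for i in range(2))
            pt = tuple(protein_types[pp.index(i)] for i in range(3))
            cand = (lt, pt)
            if best is None or cand < best:
                best = cand
    assert best is not None  # classify_topology guarantees >= 1 match
    return MotifKey(topology, best[0], best[1])


@dataclass(frozen=True)
class MotifInstance:
    """One concrete motif occurrence inside a network."""

    key: MotifKey
    ligand_indices: tuple[int, int]
    protein_indices: tuple[int, int, int]
    source: str = ""


def enumerate_motifs(net: InteractionNetwork) -> list[MotifInstance]:
    """All admissible 2x3 induced subgraphs of a network.

    Every unordered ligand pair / protein triple among networked nodes is
    tested; the induced edge set either equals one of the four topologies
    (at most one instance per 5-node selection) or yields nothing.
    Instances containing UNK-typed atoms are dropped: the motif universe is
    defined on the 23-code alphabet only.
    """
    adjacency: dict[int, set[int]] = {}
    for li, pi, _ in net.edges:
        adjacency.setdefault(li, set()).add(pi)
    out: list[MotifInstance] = []
    lig_nodes = sorted(adjacency)
    cx = net.complex
    for l1, l2 in combinations(lig_nodes, 2):
        candidates = sorted(adjacency[l1] | adjacency[l2])
        ltypes = (cx.ligand[l1].code, cx.ligand[l2].code)
        if UNK in ltypes:
            continue
        for triple in combinations(candidates, 3):
            induced = frozenset(
                (lpos, ppos)
                for lpos, li in enumerate((l1, l2))
                for ppos, pi in enumerate(triple)
                if pi in adjacency[li])
            topology = classify_topology(induced)
            if topology is None:
                continue
            ptypes = tuple(cx.protein[pi].code for pi in triple)
            if UNK in ptypes:
                continue
            key = canonical_key(ltypes, ptypes, induced)
            out.append(MotifInstance(key, (l1, l2), triple, source=cx.name))
    return out


# ---------------------------------------------------------------------------
# corpus statistics


@dataclass
class MotifStatistics:
    """Corpus-level motif and atom-type occurrence counts."""

    OM: Counter = field(default_factory=Counter)  # MotifKey -> occurrences
    topology_totals: Counter = field(default_factory=Counter)  # MotifTopology -> N_i
    OA_ligand: Counter = field(default_factory=Counter)  # code -> occurrences
    OA_protein: Counter = field(default_factory=Counter)
    M_l: int = 0
    M_p: int = 0
    corpus_size: int = 0

    def grade(self, key: MotifKey) -> float:
        return significance_grade(self, key)

    def observed_keys(self) -> list[MotifKey]:
        return sorted(self.OM)

    def all_grades(self) -> dict[MotifKey, float]:
        return {k: significance_grade(self, k) for k in self.OM}

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        lines = ["#motifscore-statistics\tv1",
                 f"#corpus_size\t{self.corpus_size}",
                 f"#M_l\t{self.M_l}", f"#M_p\t{self.M_p}"]
        for topo in MotifTopology:
            lines.append(f"#topology_total\t{topo.value}\t{self.topology_totals[topo]}")
        for side, oa in (("ligand", self.OA_ligand), ("protein", self.OA_protein)):
            for code, count in sorted(oa.items()):
                lines.append(f"#OA\t{side}\t{code}\t{count}")
        lines.append("topology\tlig1\tlig2\tprot1\tprot2\tprot3\tOM\tSG")
        for key in self.observed_keys():
            sg = significance_grade(self, key)
            lines.append("\t".join([key.topology.value, *key.ligand_types,
                                    *key.protein_types, str(self.OM[key]),
                                    f"{sg:.6f}"]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MotifStatistics":
        stats = cls()
        topo_by_value = {t.value: t for t in MotifTopology}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            cells = line.split("\t")
            if line.startswith("#"):
                tag = cells[0][1:]
                if tag == "corpus_size":
                    stats.corpus_size = int(cells[1])
                elif tag == "M_l":
                    stats.M_l = int(cells[1])
                elif tag == "M_p":
                    stats.M_p = int(cells[1])
                elif tag == "topology_total":
                    stats.topology_totals[topo_by_value[cells[1]]] = int(cells[2])
                elif tag == "OA":
                    oa = stats.OA_ligand if cells[1] == "ligand" else stats.OA_protein
                    oa[cells[2]] = int(cells[3])
                continue
            if cells[0] == "topology":
                continue
            key = MotifKey(topo_by_value[cells[0]], (cells[1], cells[2]),
                           (cells[3], cells[4], cells[5]))
            stats.OM[key] = int(cells[6])
        return stats


def accumulate_statistics(networks: list[InteractionNetwork]) -> MotifStatistics:
    """Aggregate motif and atom-type occurrences over a corpus of networks.

    Atom-type occurrences OA_j (and the totals M_l, M_p) count every typed
    atom of the underlying complexes, not only networked atoms; UNK atoms
    are outside the alphabet and excluded from both numerator and totals.
    """
    if not networks:
        raise ValueError("corpus is empty")
    stats = MotifStatistics(corpus_size=len(networks))
    for net in networks:
        for inst in enumerate_motifs(net):
            stats.OM[inst.key] += 1
            stats.topology_totals[inst.key.topology] += 1
        for atom in net.complex.ligand:
            if atom.code != UNK:
                stats.OA_ligand[atom.code] += 1
                stats.M_l += 1
        for atom in net.complex.protein:
            if atom.code != UNK:
                stats.OA_protein[atom.code] += 1
                stats.M_p += 1
    return stats


def significance_grade(stats: MotifStatistics, key: MotifKey) -> float:
    """Log-ratio of a motif's observed frequency to its independence expectation."""
    om = stats.OM.get(key, 0)
    if om == 0:
        raise KeyError(f"motif {key} unseen in corpus; SG undefined")
    n_topo = stats.topology_totals[key.topology]
    expectation = 1.0
    for code, side in key.atom_types:
        oa = (stats.OA_ligand if side == LIGAND else stats.OA_protein).get(code, 0)
        m = stats.M_l if side == LIGAND else stats.M_p
        if oa == 0 or m == 0:
            raise ValueError(f"atom type {code!r} ({side}) absent from corpus")
        expectation *= oa / m
    return math.log((om / n_topo) / expectation)
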