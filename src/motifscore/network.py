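"""Bipartite protein-ligand interaction networks and clash counting.

An edge connects a ligand atom and a protein atom whose distance lies inside
the window of their atom-type pair rule.  Intra-protein and intra-ligand
contacts are never edges.  Two different lower bounds are in play: edges
used for motif gain are built with the lower cutoff raised by a configurable
factor (default 10%), while clashes are counted against the unraised lower
cutoff of every pair, whatever its category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import UNK, TypedAtom, TypedComplex
from .thresholds import ThresholdTable

__all__ = ["InteractionNetwork", "build_network", "count_clashes"]

GAIN_LOWER_FACTOR = 1.10


@dataclass
class InteractionNetwork:
    """Edges between ligand and protein atoms of one conformation.

    Edges are stored as (ligand index, protein index, distance) with indices
    into the owning complex's atom lists, keeping the structure strictly
    bipartite by construction.
    """

    complex: TypedComplex
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def ligand_nodes(self) -> list[int]:
        """Indices of ligand atoms with at least one edge."""
        return sorted({li for li, _, _ in self.edges})

    @property
    def protein_nodes(self) -> list[int]:
        return sorted({pi for _, pi, _ in self.edges})

    def ligand_atom(self, li: int) -> TypedAtom:
        return self.complex.ligand[li]

    def protein_atom(self, pi: int) -> TypedAtom:
        return self.complex.protein[pi]

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((li, pi) for li, pi, _ in self.edges)

    def to_tsv(self) -> str:
        """Edge-list export: one row per established interaction."""
        rows = ["ligand_atom\tligand_type\tprotein_chain\tprotein_res"
                "\tprotein_atom\tprotein_type\tdistance_A"]
        for li, pi, d in self.edges:
            la, pa = self.complex.ligand[li], self.complex.protein[pi]
            rows.append(f"{la.name}\t{la.code}\t{pa.chain}\t{pa.residue}{pa.resnum}"
                        f"\t{pa.name}\t{pa.code}\t{d:.3f}")
        return "\n".join(rows) + "\n"


def build_network(cx: TypedComplex, table: ThresholdTable, *,
                  gain_lower_factor: float = 1.0) -> InteractionNetwork:
    """Connect ligand-protein atom pairs whose distance meets their rule.

    A pair of types contributes an edge iff its rule has an upper cutoff
    (category 3 pairs never connect) and
    ``gain_lower_factor * lower <= d <= upper``.  UNK-typed atoms resolve to
    the default rule.  Corpus statistics use factor 1.0; scoring raises the
    lower bound (default factor 1.10).
    """
    if gain_lower_factor < 1.0:
        raise ValueError("gain_lower_factor must be >= 1")
    net = InteractionNetwork(cx)
    if not cx.ligand or not cx.protein:
        return net
    d = cdist(cx.ligand_coords(), cx.protein_coords())
    for li, la in enumerate(cx.ligand):
        for pi, pa in enumerate(cx.protein):
            rule = table.rule(pa.code, la.code)
            if rule.upper is None:
                continue
            if gain_lower_factor * rule.lower <= d[li, pi] <= rule.upper:
                net.edges.append((li, pi, float(d[li, pi])))
    return net


def count_clashes(cx: TypedComplex, table: ThresholdTable) -> int:
    """Number of ligand-protein atom pairs closer than their lower cutoff.

    Every pair of types has a lower cutoff (category 3 included; missing
    pairs use the default rule), and the unraised value is used here.
    """
    if not cx.ligand or not cx.protein:
        return 0
    d = cdist(cx.ligand_coords(), cx.protein_coords())
    nc = 0
    for li, la in enumerate(cx.ligand):
        for pi, pa in enumerate(cx.protein):
            if d[li, pi] < table.rule(pa.code, la.code).lower:
                nc += 1
    return nc
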