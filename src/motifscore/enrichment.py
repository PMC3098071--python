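"""Binding-site enrichment of protein atom-type triangles.

Every 2x3 interaction motif carries three protein atoms — a *protein
triangle*, identified by the unordered multiset of its three atom-type
codes.  Comparing how often a triangle appears in ligand-binding interaction
networks against how often it appears anywhere in the protein gives a
binding-site enrichment factor

    F_b = (n_s / n) / (N_s / N)

with n_s, N_s the per-triangle counts in sites and whole proteins and n, N
the corresponding totals (a relative-frequency ratio in the style of
gene-set over-representation statistics).  Whole-protein triangles are
restricted geometrically: all three sides longer than 2 A, the two shortest
under 10 A and the longest under 13 A — a filter that captures nearly all
triangles actually seen in motifs.

Counting unit: within one complex a distinct atom triple counts once, no
matter how many motifs contain it; the same triangle in different complexes
counts once per complex.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .core import TypedAtom
from .motif_engine import enumerate_motifs
from .network import InteractionNetwork

__all__ = [
    "TriangleKey",
    "EnrichmentTable",
    "triangle_key",
    "count_site_triangles",
    "count_protein_triangles",
    "build_enrichment_table",
    "enrichment_factor",
    "triangle_alphabet_size",
]

TriangleKey = tuple[str, str, str]  # sorted atom-type codes

#: geometric filter for whole-protein triangles, in A
MIN_SIDE = 2.0
MID_MAX = 10.0
LONG_MAX = 13.0


def triangle_key(codes: tuple[str, str, str]) -> TriangleKey:
    a, b, c = sorted(codes)
    return (a, b, c)


def count_site_triangles(networks: list[InteractionNetwork]) -> Counter:
    """Triangle occurrences inside interaction networks (binding sites).

    Per complex, each distinct unordered protein-atom triple appearing in at
    least one motif instance contributes one count to its type key.
    """
    counts: Counter = Counter()
    for net in networks:
        triples = {inst.protein_indices for inst in enumerate_motifs(net)}
        for triple in triples:
            codes = tuple(net.complex.protein[i].code for i in triple)
            counts[triangle_key(codes)] += 1
    return counts


def count_protein_triangles(atoms: list[TypedAtom]) -> Counter:
    """Triangle occurrences over a whole protein, geometrically filtered.

    Counts every unordered atom triple whose sorted side lengths (s1, s2, s3)
    satisfy s1 > 2 A, s2 < 10 A, s3 < 13 A.
    """
    counts: Counter = Counter()
    if len(atoms) < 3:
        return counts
    coords = np.asarray([a.xyz for a in atoms])
    d = cdist(coords, coords)
    # precompute per-atom neighbor lists under the longest cutoff to avoid
    # scanning all C(n,3) triples of distant atoms
    n = len(atoms)
    near = [set(np.nonzero(d[i] < LONG_MAX)[0]) for i in range(n)]
    for i in range(n):
        cand = sorted(j for j in near[i] if j > i)
        for j, k in combinations(cand, 2):
            if k not in near[j]:
                continue
            sides = sorted((d[i, j], d[i, k], d[j, k]))
            if sides[0] > MIN_SIDE and sides[1] < MID_MAX and sides[2] < LONG_MAX:
                codes = (atoms[i].code, atoms[j].code, atoms[k].code)
                counts[triangle_key(codes)] += 1
    return counts


@dataclass
class EnrichmentTable:
    """Per-triangle site and whole-protein counts with F_b values."""

    site_counts: Counter = field(default_factory=Counter)
    protein_counts: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return sum(self.site_counts.values())

    @property
    def N(self) -> int:
        return sum(self.protein_counts.values())

    def f_b(self, key: TriangleKey) -> float:
        return enrichment_factor(self, key)

    def keys(self) -> list[TriangleKey]:
        return sorted(set(self.site_counts) | set(self.protein_counts))

    def undefined_keys(self) -> list[TriangleKey]:
        """Triangles seen in sites but never in whole proteins: F_b undefined."""
        return sorted(k for k in self.site_counts
                      if self.site_counts[k] > 0 and self.protein_counts[k] == 0)

    def ranked(self, exclude_metals: bool = True) -> list[tuple[TriangleKey, float]]:
        """Triangles sorted by descending F_b.

        Metal-containing triangles are dropped by default: metals are rare
        and almost always ligand-coordinating, which makes their F_b
        uninformatively large.
        """
        rows = []
        for key in self.keys():
            if exclude_metals and "MET" in key:
                continue
            if self.protein_counts[key] == 0:
                continue
            rows.append((key, self.f_b(key)))
        rows.sort(key=lambda kv: (-kv[1], kv[0]))
        return rows

    def to_tsv(self, exclude_metals: bool = True) -> str:
        rows = ["triangle\tn_s\tN_s\tF_b\trank"]
        for rank, (key, fb) in enumerate(self.ranked(exclude_metals), start=1):
            rows.append(f"{'-'.join(key)}\t{self.site_counts[key]}"
                        f"\t{self.protein_counts[key]}\t{fb:.4f}\t{rank}")
        return "\n".join(rows) + "\n"


def build_enrichment_table(networks: list[InteractionNetwork]) -> EnrichmentTable:
    """Count site triangles from motifs and whole-protein triangles per complex."""
    table = EnrichmentTable(site_counts=count_site_triangles(networks))
    for net in networks:
        table.protein_counts.update(count_protein_triangles(net.complex.protein))
    return table


def enrichment_factor(table: EnrichmentTable, key: TriangleKey) -> float:
    """F_b = relative site frequency over relative whole-protein frequency."""
    n_s = table.site_counts.get(key, 0)
    if n_s == 0:
        return 0.0
    N_s = table.protein_counts.get(key, 0)
    if N_s == 0:
        raise ValueError(f"triangle {key}: seen in sites but not in whole "
                         "proteins; F_b undefined")
    n, N = table.n, table.N
    if n == 0 or N == 0:
        raise ValueError("empty enrichment table")
    return (n_s / n) / (N_s / N)


def triangle_alphabet_size(protein_types: int, exclude_metals: bool = False) -> int:
    """Number of distinct atom-type triangles: multisets of size 3 over t types."""
    if protein_types < 1:
        raise ValueError("need at least one type")
    t = protein_types - (1 if exclude_metals else 0)
    if t < 1:
        raise ValueError("no types left after excluding metals")
    return math.comb(t + 2, 3)
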