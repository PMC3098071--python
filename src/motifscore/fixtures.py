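"""Synthetic typed complexes, decoy sets and corpora for controlled testing.

Real contact statistics need thousands of crystal structures; these
generators instead build geometric toy complexes whose interaction networks
are known by construction.  The basic unit is a *cluster*: 2 ligand atoms
1.4 A apart plus 3 protein atoms placed so that exactly the edge pattern of
a chosen motif topology is realized under the default 2-4 A distance window
(connected pairs sit at 3.0 A; non-connected pairs at >= 4.1 A).  Clusters
are spaced far apart, so a complex's network is the disjoint union of its
clusters' edges, and padding atoms far from everything supply realistic
atom-type denominators for the significance-grade statistics.

Everything is deterministic under a fixed seed.  What these fixtures do not
emulate: real packing densities, chain connectivity, or chemically
consistent ligand geometry — they exercise the counting and scoring
machinery, not structural realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atom_typing import LIGAND_TYPES, PROTEIN_TYPES
from .core import LIGAND, PROTEIN, TypedAtom, TypedComplex
from .motif_engine import CANONICAL_EDGES, MotifKey, MotifTopology
from .thresholds import ThresholdTable

__all__ = [
    "FixtureSpec",
    "Decoy",
    "make_toy_complex",
    "expected_edges",
    "make_cluster",
    "make_motif_complex",
    "make_decoy_set",
    "make_toy_corpus",
    "make_docking_case",
]

#: separation of the two ligand atoms in a cluster
_LIG_SEP = 1.4
#: contact distance for connected ligand-protein pairs
_CONTACT = 3.0

# protein-atom templates: radial placements realizing each connectivity.
# "both" sits on the mid-plane circle (3.0 A from both ligand atoms);
# "only-L0"/"only-L1" sit 3.0 A from one ligand atom and ~4.14 A from the
# other, outside the default 4 A window.
_R_BOTH = math.sqrt(_CONTACT ** 2 - (_LIG_SEP / 2) ** 2)
_X_ONLY = 2.2
_R_ONLY = math.sqrt(_CONTACT ** 2 - _X_ONLY ** 2)


@dataclass(frozen=True)
class FixtureSpec:
    """Explicit atom placements for a hand-built toy complex."""

    ligand_atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    protein_atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    seed: int = 0
    noise_sigma: float = 0.0


@dataclass(frozen=True)
class Decoy:
    id: str
    complex: TypedComplex
    rmsd: float


def make_toy_complex(spec: FixtureSpec, name: str = "toy") -> TypedComplex:
    """Typed complex with atoms exactly at (or jittered around) spec positions."""
    rng = np.random.default_rng(spec.seed)

    def jitter(xyz):
        if spec.noise_sigma <= 0:
            return tuple(float(c) for c in xyz)
        return tuple(float(c + rng.normal(0, spec.noise_sigma)) for c in xyz)

    ligand = [TypedAtom(LIGAND, f"L{i + 1}", _element_for(code), jitter(xyz),
                        code=code, chain="L", residue="LIG", resnum="1")
              for i, (code, xyz) in enumerate(spec.ligand_atoms)]
    protein = [TypedAtom(PROTEIN, f"P{i + 1}", _element_for(code), jitter(xyz),
                         code=code, chain="A", residue="UNX", resnum=str(i + 1))
               for i, (code, xyz) in enumerate(spec.protein_atoms)]
    return TypedComplex(name, protein, ligand)


def _element_for(code: str) -> str:
    return {"PHO": "P", "HAL": "CL", "MET": "ZN", "UNK": "X"}.get(code, code[0])


def expected_edges(cx: TypedComplex, table: ThresholdTable, *,
                   gain_lower_factor: float = 1.0) -> set[tuple[int, int]]:
    """Edge list by direct per-pair arithmetic (oracle for network building)."""
    out = set()
    for li, la in enumerate(cx.ligand):
        for pi, pa in enumerate(cx.protein):
            rule = table.rule(pa.code, la.code)
            if rule.upper is None:
                continue
            d = math.dist(la.xyz, pa.xyz)
            if gain_lower_factor * rule.lower <= d <= rule.upper:
                out.add((li, pi))
    return out


# ---------------------------------------------------------------------------
# motif clusters


def make_cluster(key: MotifKey, origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 ) -> tuple[list[tuple[str, tuple[float, float, float]]],
                            list[tuple[str, tuple[float, float, float]]]]:
    """Atom placements realizing exactly ``key``'s topology at ``origin``.

    Returns (ligand_atom_specs, protein_atom_specs) in canonical position
    order, so enumerating the resulting network yields ``key`` itself.
    """
    ox, oy, oz = origin
    ligand = [(key.ligand_types[0], (ox, oy, oz)),
              (key.ligand_types[1], (ox + _LIG_SEP, oy, oz))]
    edges = CANONICAL_EDGES[key.topology]
    protein = []
    for p in range(3):
        connected = {l for l, pp in edges if pp == p}
        phi = 2 * math.pi * p / 3 + 0.4
        if connected == {0, 1}:
            pos = (ox + _LIG_SEP / 2,
                   oy + _R_BOTH * math.cos(phi), oz + _R_BOTH * math.sin(phi))
        elif connected == {0}:
            pos = (ox - _X_ONLY,
                   oy + _R_ONLY * math.cos(phi), oz + _R_ONLY * math.sin(phi))
        else:  # only L1
            pos = (ox + _LIG_SEP + _X_ONLY,
                   oy + _R_ONLY * math.cos(phi), oz + _R_ONLY * math.sin(phi))
        protein.append((key.protein_types[p], pos))
    return ligand, protein


def make_motif_complex(keys: list[MotifKey], name: str = "motifs", *,
                       padding: tuple[int, int] = (0, 0),
                       rng: np.random.Generator | None = None,
                       ligand_frequencies: dict[str, float] | None = None,
                       protein_frequencies: dict[str, float] | None = None,
                       extra_protein_triangles: int = 0,
                       noise_sigma: float = 0.0, seed: int = 0) -> TypedComplex:
    """Complex whose network is the disjoint union of one cluster per key.

    ``padding`` adds (ligand, protein) atoms far from every cluster, typed
    by the given frequency distributions, contributing to atom-type totals
    without forming edges.  ``extra_protein_triangles`` adds isolated
    equilateral protein triples (side 5 A) away from the ligand — they pass
    the whole-protein triangle filter without touching any binding site.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lig_specs: list[tuple[str, tuple[float, float, float]]] = []
    prot_specs: list[tuple[str, tuple[float, float, float]]] = []
    for i, key in enumerate(keys):
        l, p = make_cluster(key, origin=(30.0 * i, 0.0, 0.0))
        lig_specs.extend(l)
        prot_specs.extend(p)
    n_lig_pad, n_prot_pad = padding
    for i in range(n_lig_pad):
        code = _sample_code(rng, ligand_frequencies, LIGAND_TYPES)
        lig_specs.append((code, (8.0 * i, 80.0, 0.0)))
    for i in range(n_prot_pad):
        code = _sample_code(rng, protein_frequencies, PROTEIN_TYPES)
        prot_specs.append((code, (8.0 * i, -80.0, 0.0)))
    for i in range(extra_protein_triangles):
        ox, oy = 30.0 * i, -160.0
        side = 5.0
        corners = [(ox, oy, 0.0), (ox + side, oy, 0.0),
                   (ox + side / 2, oy + side * math.sqrt(3) / 2, 0.0)]
        for c in corners:
            prot_specs.append((_sample_code(rng, protein_frequencies, PROTEIN_TYPES), c))
    spec = FixtureSpec(tuple(lig_specs), tuple(prot_specs),
                       seed=int(rng.integers(2 ** 31)), noise_sigma=noise_sigma)
    return make_toy_complex(spec, name=name)


def _sample_code(rng: np.random.Generator, freqs: dict[str, float] | None,
                 default_codes: tuple[str, ...]) -> str:
    if freqs is None:
        return str(rng.choice(list(default_codes)))
    codes = sorted(freqs)
    p = np.array([freqs[c] for c in codes], dtype=float)
    if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("type frequencies must sum to 1")
    return str(rng.choice(codes, p=p / p.sum()))


def _random_key(rng: np.random.Generator,
                ligand_frequencies: dict[str, float] | None,
                protein_frequencies: dict[str, float] | None) -> MotifKey:
    from .motif_engine import canonical_key

    topology = list(MotifTopology)[int(rng.integers(4))]
    lt = tuple(_sample_code(rng, ligand_frequencies, LIGAND_TYPES) for _ in range(2))
    pt = tuple(_sample_code(rng, protein_frequencies, PROTEIN_TYPES) for _ in range(3))
    return canonical_key(lt, pt, CANONICAL_EDGES[topology])


# ---------------------------------------------------------------------------
# corpora


def make_toy_corpus(n_complexes: int, *,
                    ligand_frequencies: dict[str, float] | None = None,
                    protein_frequencies: dict[str, float] | None = None,
                    motif_plant: MotifKey | None = None,
                    plant_rate: float = 0.0,
                    background_clusters: int = 2,
                    padding: tuple[int, int] = (6, 12),
                    noise_sigma: float = 0.0,
                    seed: int = 0) -> list[TypedComplex]:
    """Corpus of typed complexes with controlled type and motif content.

    Each complex holds ``background_clusters`` randomly typed clusters plus,
    when ``motif_plant`` is set, planted clusters of that key at an expected
    rate of ``plant_rate`` per complex; padding atoms shape the atom-type
    marginals toward the requested frequencies.
    """
    if motif_plant is not None and plant_rate > 0:
        for code, side_types, freqs in [
                *[(c, LIGAND_TYPES, ligand_frequencies) for c in motif_plant.ligand_types],
                *[(c, PROTEIN_TYPES, protein_frequencies) for c in motif_plant.protein_types]]:
            available = set(freqs) if freqs is not None else set(side_types)
            if freqs is not None and freqs.get(code, 0.0) <= 0.0:
                raise ValueError(f"planted key uses zero-probability type {code!r}")
            if code not in available:
                raise ValueError(f"planted key type {code!r} not in frequency support")
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n_complexes):
        keys = [_random_key(rng, ligand_frequencies, protein_frequencies)
                for _ in range(background_clusters)]
        if motif_plant is not None and plant_rate > 0:
            n_plant = int(plant_rate) + (1 if rng.random() < plant_rate % 1 else 0)
            keys.extend([motif_plant] * n_plant)
        corpus.append(make_motif_complex(
            keys, name=f"toy{i}", padding=padding, rng=rng,
            ligand_frequencies=ligand_frequencies,
            protein_frequencies=protein_frequencies,
            noise_sigma=noise_sigma))
    return corpus


# ---------------------------------------------------------------------------
# decoys


def make_decoy_set(native: TypedComplex, n: int, *, sigma: float = 0.2,
                   max_shift: float = 5.0, max_angle_deg: float = 25.0,
                   seed: int = 0, ensure_near: bool = True) -> list[Decoy]:
    """Rigid-body perturbations of the native ligand with recorded true rmsd.

    Each decoy applies a random rotation about the ligand centroid, a random
    translation of length up to ``max_shift`` and per-atom jitter of scale
    ``sigma``.  With ``ensure_near`` the first decoy is a sub-Angstrom
    perturbation, guaranteeing one near-native pose in the set.
    """
    from scipy.spatial.transform import Rotation

    if n < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(seed)
    coords0 = native.ligand_coords()
    centroid = coords0.mean(axis=0)
    decoys = []
    for i in range(n):
        near = ensure_near and i == 0
        angle = math.radians(rng.uniform(0, 2.0 if near else max_angle_deg))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * rng.uniform(0, 0.2 if near else max_shift)
        jit = rng.normal(0, (0.05 if near else sigma), size=coords0.shape)
        coords = rot.apply(coords0 - centroid) + centroid + shift + jit
        rmsd = float(np.sqrt(np.mean(np.sum((coords - coords0) ** 2, axis=1))))
        decoys.append(Decoy(f"decoy{i}", native.with_ligand_coords(coords, f"{native.name}/d{i}"),
                            rmsd))
    return decoys


# ---------------------------------------------------------------------------
# end-to-end docking demonstration


#: pocket motifs used by the demonstration docking case; drawn from
#: combinations of aromatic/polar types typical of real binding sites
_POCKET_KEYS = [
    MotifKey(MotifTopology.FULL, ("CRN", "ORA"), ("CRN", "CRN", "CRN")),
    MotifKey(MotifTopology.FULL, ("NRA", "NRA"), ("CRN", "CRN", "NRE")),
    MotifKey(MotifTopology.FULL, ("CRN", "NLC"), ("CRN", "CRN", "CRN")),
]


def make_docking_stats(seed: int = 0, *, n_corpus: int = 30):
    """Motif statistics for the demonstration pocket, from a seeded corpus."""
    from .motif_engine import accumulate_statistics
    from .network import build_network

    table = ThresholdTable()  # every pair on the default 2-4 A window
    corpus = []
    rng = np.random.default_rng(seed)
    for i in range(n_corpus):
        keys = list(_POCKET_KEYS) + [_random_key(rng, None, None) for _ in range(2)]
        corpus.append(make_motif_complex(keys, name=f"corpus{i}", padding=(6, 12),
                                         rng=rng))
    nets = [build_network(cx, table) for cx in corpus]
    return accumulate_statistics(nets), table


def make_docking_case(seed: int = 0, *, n_decoys: int = 100, n_corpus: int = 30,
                      stats=None, table=None):
    """Self-contained docking benchmark: native pose, decoys, statistics, table.

    The native pose holds three motif-rich pocket clusters; the statistics
    corpus contains the same motif keys (so they carry positive grades)
    plus random background, and the decoy set perturbs the native ligand
    rigidly.  Returns ``(native, decoys, stats, table)``.  Pass precomputed
    ``stats``/``table`` to share one corpus across replicates.
    """
    if stats is None or table is None:
        stats, table = make_docking_stats(seed, n_corpus=n_corpus)

    native = make_motif_complex(list(_POCKET_KEYS), name="native",
                                rng=np.random.default_rng(seed + 1))
    # a repulsive wall under each cluster: no edges at 4.5 A, but poses pushed
    # toward it start to clash
    wall = [TypedAtom(PROTEIN, f"W{i + 1}", "C", (30.0 * i + 0.7, 0.0, -4.5),
                      code="C3N", chain="A", residue="UNX", resnum=str(100 + i))
            for i in range(len(_POCKET_KEYS))]
    native = TypedComplex(native.name, native.protein + wall, native.ligand)
    decoys = make_decoy_set(native, n_decoys, sigma=0.15, max_shift=5.0,
                            seed=seed + 2)
    return native, decoys, stats, table
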