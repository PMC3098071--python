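"""Per-atom-type-pair interaction distance thresholds.

For each (protein type, ligand type) pair a lower and (usually) an upper
distance cutoff define when two heavy atoms are connected in the bipartite
interaction network.  The cutoffs are derived from shell-volume-normalized
distance distributions over a corpus of complexes, in the spirit of a radial
distribution function: per distance bin, the pair count is divided by
(r_out^3 - r_in^3), which is proportional to the shell volume, and by the
corpus-wide occurrence of the ligand-side atom type.

Pairs fall into four categories: (1) a sharp early peak — specific contacts
such as hydrogen bonds; (2) a fast rise to a plateau — weak or less defined
contacts; (3) a slow monotone rise — pairs that avoid each other, which get
a lower cutoff (for clash counting) but no upper cutoff and hence no edges;
(4) too little data — an arbitrary default window of 2-4 A.  The category
heuristic is advisory and can be overridden per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core import TypedComplex

__all__ = [
    "DistanceDistribution",
    "PairRule",
    "ThresholdTable",
    "DEFAULT_RULE",
    "radial_profile",
    "classify_profile",
    "derive_thresholds",
    "derive_table",
    "validate_table",
]

Pair = tuple[str, str]  # (protein code, ligand code)

#: ranges the corpus-derived thresholds are expected to stay inside
UPPER_RANGE = (3.0, 5.6)
LOWER_RANGE = (1.2, 4.0)


@dataclass
class DistanceDistribution:
    """Shell-volume- and occurrence-normalized distance histogram of a pair."""

    pair: Pair
    bin_edges: np.ndarray  # length nbins+1, strictly increasing, in A
    density: np.ndarray  # length nbins, >= 0
    raw_counts: np.ndarray | None = None  # unnormalized per-bin pair counts

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def max_r(self) -> float:
        return float(self.bin_edges[-1])


@dataclass(frozen=True)
class PairRule:
    pair: Pair
    category: int  # 1..4
    lower: float
    upper: float | None  # None for category 3: no edges, clash cutoff only


DEFAULT_RULE_PARAMS = (2.0, 4.0)  # category-4 lower/upper in A


def DEFAULT_RULE(pair: Pair = ("*", "*")) -> PairRule:
    return PairRule(pair, 4, *DEFAULT_RULE_PARAMS)


@dataclass
class ThresholdTable:
    """Rules for all pairs; anything missing resolves to the category-4 default."""

    rules: dict[Pair, PairRule] = field(default_factory=dict)

    def rule(self, protein_code: str, ligand_code: str) -> PairRule:
        pair = (protein_code, ligand_code)
        got = self.rules.get(pair)
        return got if got is not None else DEFAULT_RULE(pair)

    def set_rule(self, rule: PairRule) -> None:
        self.rules[rule.pair] = rule

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        lines = ["protein_type\tligand_type\tcategory\tlower_A\tupper_A"]
        for (p, l), r in sorted(self.rules.items()):
            upper = "" if r.upper is None else repr(r.upper)
            lines.append(f"{p}\t{l}\t{r.category}\t{r.lower!r}\t{upper}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdTable":
        table = cls()
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            p, l, cat, lower, upper = line.split("\t")
            table.set_rule(PairRule((p, l), int(cat), float(lower),
                                    float(upper) if upper else None))
        return table


# ---------------------------------------------------------------------------
# derivation pipeline


def radial_profile(corpus: list[TypedComplex], pair: Pair, *,
                   bin_width: float = 0.1, max_r: float = 8.0) -> DistanceDistribution:
    """Normalized occurrence-vs-distance profile for one atom-type pair.

    Per bin [r_in, r_out): (number of protein-ligand pairs of these two types
    at that distance) / (r_out^3 - r_in^3) / (corpus-wide occurrence of the
    ligand-side atom type).
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    prot_code, lig_code = pair
    edges = np.arange(0.0, max_r + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    lig_total = 0
    for cx in corpus:
        lig_total += sum(1 for a in cx.ligand if a.code == lig_code)
        p = [a for a in cx.protein if a.code == prot_code]
        l = [a for a in cx.ligand if a.code == lig_code]
        if not p or not l:
            continue
        d = cdist([a.xyz for a in l], [a.xyz for a in p]).ravel()
        hist, _ = np.histogram(d[d < edges[-1]], bins=edges)
        counts += hist
    if lig_total == 0:
        import warnings
        warnings.warn(f"atom type {lig_code!r} absent from corpus; zero profile")
        density = np.zeros_like(counts)
    else:
        shell = edges[1:] ** 3 - edges[:-1] ** 3
        density = counts / shell / lig_total
    return DistanceDistribution(pair, edges, density, raw_counts=counts)


def classify_profile(dist: DistanceDistribution, *,
                     min_counts: int = 20) -> int:
    """Advisory four-way classification of a pair's distance profile.

    Category 1: sharp early peak then decline (specific contact).
    Category 2: fast rise then plateau (weak/non-specific but bounded).
    Category 3: slow monotone rise (the pair avoids short contact).
    Category 4: too little data to tell.
    """
    if dist.max_r < 8.0:
        raise ValueError("profile must extend to at least 8 A")
    density = dist.density
    peak = float(density.max(initial=0.0))
    if peak == 0.0:
        return 4
    if dist.raw_counts is not None and dist.raw_counts.sum() < min_counts:
        return 4
    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
    # mean density over the final 2 A, relative to the peak
    tail = float(density[centers >= dist.max_r - 2.0].mean())
    if tail < 0.3 * peak:
        return 1
    # fraction of the range at which density first reaches half its peak
    r50 = float(centers[np.argmax(density >= 0.5 * peak)]) / dist.max_r
    return 2 if r50 <= 0.35 else 3


def derive_thresholds(dist: DistanceDistribution, category: int, *,
                      peak_fraction: float = 0.1) -> PairRule:
    """Extract the lower/upper cutoffs of a pair from its profile.

    The lower cutoff is the left edge of the first populated bin — the
    largest distance below which the pair is never observed.  For categories
    1 and 2 the upper cutoff is where the density first falls below
    ``peak_fraction`` of its maximum after the peak; category 3 has no
    upper cutoff; category 4 uses the fixed 2-4 A window.
    """
    if category == 4:
        return PairRule(dist.pair, 4, *DEFAULT_RULE_PARAMS)
    nz = np.nonzero(dist.density)[0]
    if nz.size == 0:
        return PairRule(dist.pair, 4, *DEFAULT_RULE_PARAMS)
    lower = float(dist.bin_edges[nz[0]])
    if category == 3:
        return PairRule(dist.pair, 3, lower, None)
    peak_idx = int(np.argmax(dist.density))
    peak = dist.density[peak_idx]
    upper = dist.max_r
    for i in range(peak_idx + 1, len(dist.density)):
        if dist.density[i] < peak_fraction * peak:
            upper = float(dist.bin_edges[i])
            break
    return PairRule(dist.pair, category, lower, upper)


def derive_table(corpus: list[TypedComplex], pairs: list[Pair], *,
                 bin_width: float = 0.1, max_r: float = 8.0,
                 peak_fraction: float = 0.1,
                 category_overrides: dict[Pair, int] | None = None) -> ThresholdTable:
    """Run the full profile -> classify -> cutoff pipeline over ``pairs``."""
    overrides = category_overrides or {}
    table = ThresholdTable()
    for pair in pairs:
        dist = radial_profile(corpus, pair, bin_width=bin_width, max_r=max_r)
        category = overrides.get(pair, classify_profile(dist))
        table.set_rule(derive_thresholds(dist, category, peak_fraction=peak_fraction))
    return table


def validate_table(table: ThresholdTable) -> list[str]:
    """Warnings for cutoffs outside the empirically expected ranges.

    A lower cutoff at or above its upper cutoff is a structural error and
    reported with an ``ERROR:`` prefix.
    """
    issues: list[str] = []
    for (p, l), r in sorted(table.rules.items()):
        tag = f"{p}-{l}"
        if r.upper is not None and r.lower >= r.upper:
            issues.append(f"ERROR: {tag}: lower {r.lower} >= upper {r.upper}")
            continue
        if r.category == 4:
            continue  # the fixed default window is exempt by construction
        if not LOWER_RANGE[0] <= r.lower <= LOWER_RANGE[1]:
            issues.append(f"{tag}: lower {r.lower} outside {LOWER_RANGE}")
        if r.upper is not None and not UPPER_RANGE[0] <= r.upper <= UPPER_RANGE[1]:
            issues.append(f"{tag}: upper {r.upper} outside {UPPER_RANGE}")
    return issues
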