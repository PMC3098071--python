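"""Gain, Penalty and the composite MotifScore; decoy ranking and evaluation.

For one docking pose the score has two opposing parts.  *Gain* is the sum of
significance grades over all motifs found in the pose's interaction network
(built with the lower cutoffs raised by 10% so that barely-above-threshold
contacts do not inflate the motif count).  *Penalty* grows with the clash
count NC — ligand-protein pairs closer than their unraised lower cutoff —
offset by a weight W (default 10, insensitive over a wide range):

    MotifScore = Gain / (NC + W)

The ratio is well defined for clash-free poses and strictly decreasing in
NC at fixed Gain.  Alternative composites (difference form, 1 + W*NC ratio)
are selectable for sensitivity studies.

Pose quality is judged by distance rmsd between corresponding ligand heavy
atoms of a decoy and the crystallographic pose, computed in the protein
frame without superposition; ranking succeeds at cutoff c when the
top-scored decoy has rmsd <= c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import TypedAtom, TypedComplex
from .motif_engine import MotifStatistics, enumerate_motifs
from .network import build_network, count_clashes
from .thresholds import ThresholdTable

__all__ = [
    "ScoringConfig",
    "ScoreBreakdown",
    "DecoyEvaluation",
    "gain",
    "composite",
    "motif_score",
    "ligand_rmsd",
    "rank_and_evaluate",
]


@dataclass(frozen=True)
class ScoringConfig:
    W: float = 10.0
    gain_lower_factor: float = 1.10
    unseen_motif_policy: str = "skip"  # skip | pseudocount
    unseen_floor: float = 0.0  # grade used under the pseudocount policy
    composite: str = "ratio_offset"  # ratio_offset | difference | ratio_one_plus
    include_native: bool = False  # add the native pose to the candidate pool

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("W must be positive")
        if self.gain_lower_factor < 1.0:
            raise ValueError("gain_lower_factor must be >= 1")
        if self.unseen_motif_policy not in ("skip", "pseudocount"):
            raise ValueError(f"unknown policy {self.unseen_motif_policy!r}")
        if self.composite not in ("ratio_offset", "difference", "ratio_one_plus"):
            raise ValueError(f"unknown composite {self.composite!r}")


@dataclass
class ScoreBreakdown:
    gain: float
    motif_count: int
    skipped_unseen: int
    nc: int
    penalty: float
    score: float


def gain(net, stats: MotifStatistics,
         config: ScoringConfig = ScoringConfig()) -> tuple[float, int, int]:
    """Sum of significance grades over the motifs of one network.

    Returns (gain, motif_count, skipped): instances whose key never occurred
    in the corpus carry no grade and are skipped (or, under the pseudocount
    policy, contribute a configured floor grade).
    """
    total = 0.0
    count = 0
    skipped = 0
    for inst in enumerate_motifs(net):
        count += 1
        if inst.key in stats.OM:
            total += stats.grade(inst.key)
        elif config.unseen_motif_policy == "pseudocount":
            total += config.unseen_floor
        else:
            skipped += 1
    return total, count, skipped


def composite(g: float, nc: int, config: ScoringConfig = ScoringConfig()) -> tuple[float, float]:
    """(penalty, score) for a given gain and clash count under the config."""
    if config.composite == "ratio_offset":
        penalty = nc + config.W
        return penalty, g / penalty
    if config.composite == "difference":
        penalty = config.W * nc
        return penalty, g - penalty
    penalty = 1.0 + config.W * nc
    return penalty, g / penalty


def motif_score(cx: TypedComplex, stats: MotifStatistics, table: ThresholdTable,
                config: ScoringConfig = ScoringConfig()) -> ScoreBreakdown:
    """Score one pose: gain network with raised lowers, clashes with unraised."""
    net = build_network(cx, table, gain_lower_factor=config.gain_lower_factor)
    g, count, skipped = gain(net, stats, config)
    nc = count_clashes(cx, table)
    penalty, score = composite(g, nc, config)
    if not math.isfinite(score):
        raise ValueError("non-finite score")
    return ScoreBreakdown(g, count, skipped, nc, penalty, score)


def ligand_rmsd(decoy_ligand: list[TypedAtom], native_ligand: list[TypedAtom]) -> float:
    """Distance rmsd over corresponding heavy atoms, matched by atom name.

    No superposition: decoy and native are compared in the docking frame.
    """
    native_by_name = {a.name: a for a in native_ligand}
    if len(native_by_name) != len(native_ligand):
        raise ValueError("duplicate atom names in native ligand")
    if {a.name for a in decoy_ligand} != set(native_by_name):
        raise ValueError("decoy and native ligand atom names do not match")
    sq = 0.0
    for atom in decoy_ligand:
        ref = native_by_name[atom.name]
        sq += sum((a - b) ** 2 for a, b in zip(atom.xyz, ref.xyz))
    return math.sqrt(sq / len(decoy_ligand))


@dataclass
class DecoyEvaluation:
    """Scored, ranked decoy set with rmsd-based success flags."""

    ids: list[str]
    rmsds: list[float]
    breakdowns: list[ScoreBreakdown]
    ranking: list[int]  # decoy indices, best score first (stable)
    top_index: int
    top_rmsd: float
    tied: bool
    success: dict[float, bool] = field(default_factory=dict)

    @property
    def scores(self) -> list[float]:
        return [b.score for b in self.breakdowns]

    def report_tsv(self) -> str:
        rows = ["decoy_id\trmsd_A\tgain\tNC\tscore\trank"]
        rank_of = {idx: r + 1 for r, idx in enumerate(self.ranking)}
        for i, (did, rmsd, b) in enumerate(zip(self.ids, self.rmsds, self.breakdowns)):
            rows.append(f"{did}\t{rmsd:.3f}\t{b.gain:.4f}\t{b.nc}\t{b.score:.4f}"
                        f"\t{rank_of[i]}")
        return "\n".join(rows) + "\n"


def rank_and_evaluate(decoys: list[TypedComplex], native: TypedComplex,
                      stats: MotifStatistics, table: ThresholdTable,
                      config: ScoringConfig = ScoringConfig(),
                      cutoffs: tuple[float, ...] = (1.0, 2.0, 3.0),
                      ids: list[str] | None = None) -> DecoyEvaluation:
    """Score every decoy against the native reference and flag rmsd success.

    The top-scored decoy decides success at each cutoff.  Exact score ties
    at the top are flagged and the lowest rmsd among the tied poses is
    reported.  The native pose itself joins the candidate pool only when
    ``config.include_native`` is set.
    """
    if not decoys:
        raise ValueError("empty decoy list")
    pool = list(decoys)
    pool_ids = list(ids) if ids is not None else [f"decoy{i}" for i in range(len(decoys))]
    if len(pool_ids) != len(pool):
        raise ValueError("ids length does not match decoy count")
    if config.include_native:
        pool.append(native)
        pool_ids.append("native")

    breakdowns = [motif_score(cx, stats, table, config) for cx in pool]
    rmsds = [ligand_rmsd(cx.ligand, native.ligand) for cx in pool]
    scores = np.array([b.score for b in breakdowns])
    ranking = list(np.argsort(-scores, kind="stable"))
    top = int(ranking[0])
    tied_idx = [i for i in ranking if scores[i] == scores[top]]
    tied = len(tied_idx) > 1
    top_rmsd = min(rmsds[i] for i in tied_idx)
    success = {c: top_rmsd <= c for c in cutoffs}
    return DecoyEvaluation(pool_ids, rmsds, breakdowns, ranking,
                           top, top_rmsd, tied, success)
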