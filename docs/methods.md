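# Methods

This note documents the models and procedures implemented in `motifscore`,
the parameters that matter, the synthetic data used for validation, and the
design choices made where the method leaves room for interpretation.

## Atom typing

Heavy atoms are described by a closed alphabet of 23 three-character codes:
element (C/N/O/S), environment (`2` sp2, `3` sp3, `R` aromatic ring, `L`
aliphatic chain), and role (`P` polar, `N` non-polar, `A` acceptor, `D`
donor, `B` both, `E` either-donor-or-acceptor, `C` charged), plus the
single-purpose codes `PHO` (phosphorus), `MET` (metal), `HAL` (halogen).
Hydrogens are never considered; protonation states are inferred only from
bond graphs (no pKa model).

* **Protein atoms** are typed by a fixed (residue, atom-name) lookup shipped
  as an editable TSV.  Choices worth noting: both His imidazole nitrogens
  and the Trp indole nitrogen are `NRE` (donor *or* acceptor); Lys NZ and
  Arg NE/NH1/NH2 are `NLC`; Asp/Glu carboxylate oxygens and terminal OXT are
  `OLC`; Ser/Thr/Tyr hydroxyl oxygens are `O3B`; Cys SG and Met SD are `S3N`
  (sulfur is treated as sp3 throughout, including thiols and thioethers).
  Pro's backbone nitrogen is a tertiary amide with no donor hydrogen, so it
  is typed `NLA` rather than the generic backbone `NLB`.  Atoms of
  non-standard residues are left untyped and excluded with a warning.
* **Ligand atoms** are typed from the component's bond graph (chemical-
  component-dictionary mmCIF or MOL/SDF; aromaticity taken from the file or
  perceived with RDKit).  A carbon is "polar" iff bonded to N, O, S or a
  halogen.  Oxygen: aromatic ring → `ORA`; carboxylate/sulfate/phosphate
  oxygens (terminal O whose parent bears ≥ 2 terminal oxygens, with S/P
  parent or a formal negative charge, or a C parent with exactly two
  terminal oxygens) → `OLC`; double-bonded → `O2A`; ether → `O3A`;
  hydroxyl → `O3B`.  Aromatic nitrogen is `NRD` when protonated (explicit or
  implied hydrogen) and `NRA` otherwise; aliphatic nitrogen is `NLC` when
  formally positive (or carrying three hydrogens), `NLB` with a donor
  hydrogen, `NLA` otherwise.  Elements outside the alphabet (boron,
  selenium, …) are typed `UNK`.
* The protein/ligand **capability flags** (14 protein-capable, 20
  ligand-capable codes) define the 280-pair threshold universe.  The
  assignment rules deliberately allow two codes to cross sides — `NLC`
  appears on Lys/Arg side chains and `OLC` on ligand carboxylates — because
  the side-chain chemistry demands it; pairs outside the 280-pair table
  simply resolve to the default distance rule, so no special casing is
  needed downstream.

## Distance thresholds

For each (protein type, ligand type) pair, a distance profile is built over
a corpus: per bin `[r_in, r_out)`, the pair count is divided by
`r_out³ − r_in³` (proportional to the shell volume, e.g. 3³ − 2³ = 19 for
the 2–3 Å shell) and by the corpus-wide occurrence of the ligand-side type.
This normalization makes the profile invariant under corpus duplication.
Profiles fall into four categories — (1) sharp early peak, (2) fast rise to
a plateau, (3) slow monotone rise, (4) insufficient data — mirrored here by
a transparent heuristic (tail-to-peak ratio < 0.3 → 1; half-peak reached in
the first 35 % of the range → 2; otherwise 3; empty or sparse → 4).  The
original assignments were made by manual inspection, so the classifier is
advisory and overridable per pair.

Cutoffs: the lower threshold is the left edge of the first populated bin;
for categories 1–2 the upper threshold is where density first drops below a
`peak_fraction` (default 0.1) of the maximum past the peak; category 3
keeps its lower cutoff (for clash counting) but gets **no upper cutoff and
hence no edges**; category 4 uses the fixed 2–4 Å window, which also serves
as the default for unlisted pairs and for `UNK` atoms.  Defaults: bin width
0.1 Å, profile range 8 Å.  Empirically derived uppers are expected in
[3, 5.6] Å and lowers in [1.2, 4.0] Å; `validate_table` warns outside these
ranges and flags lower ≥ upper as an error.  A user-supplied table in the
same TSV format can replace the derivation entirely.

## Networks, motifs, grades

Edges connect ligand–protein atom pairs only (never intra-molecular), with
`factor · lower ≤ d ≤ upper`.  Two lower bounds coexist by design: **gain
networks** raise the lower cutoffs by 10 % (`gain_lower_factor = 1.10`),
because a contact barely above the statistical lower bound is rarely seen
in crystal structures yet would otherwise count fully toward the score;
**clash counting** uses the unraised lower cutoffs of all pairs, category 3
included.  Corpus statistics are accumulated with factor 1.0 — the raise is
a scoring-time device, not a property of the observed distance statistics.

Motifs are induced subgraphs on 2 ligand + 3 protein nodes restricted to
four topologies: 6 edges (complete), 5 edges, and two 4-edge forms (ligand
degrees 2+2 with a shared middle protein atom, or 3+1).  Induced-subgraph
semantics means a complete selection counts once as the 6-edge motif, never
additionally as its sparser subgraphs — this avoids systematic double
counting.  Motif identity is canonicalized by explicit minimization over
the 2!·3! side-preserving node permutations; with ≤ 12 candidates, brute
force is both trivially correct and cheap, and the enumerator is verified
against an exhaustive `C(L,2)·C(P,3)` oracle in the tests.  `UNK` atoms may
form edges but never motifs: the motif universe is defined on the 23-code
alphabet.

The significance grade of an observed motif is
`SG = ln[(OM/N) / Π(OA_j/M_side)]`.  `N` is the total instance count of the
motif's topology (not the number of distinct keys) — this reading follows
from normalizing "by the total occurrence of each motif type" and makes
ΣOM over a topology equal `N` by construction.  `OA_j` counts all typed
atoms of the corpus complexes, not only networked atoms (configurable in
principle; all-atoms is the default because the denominator should describe
the composition of the structures, not of the contact layer).  Both choices
leave SG exactly invariant under corpus duplication.  Motifs absent from
the corpus have undefined SG and are skipped when scoring (a pseudocount
floor is available as a config option).

## Scoring and evaluation

`MotifScore = Gain / (NC + W)` with `W = 10`.  The additive offset form was
chosen over a multiplicative penalty because the composite is stated to be
a ratio, a pure product `W·NC` would leave clash-free poses undefined, and
an offset reproduces the reported insensitivity to W (ranking on the
planted-pocket fixture is unchanged for W anywhere in [5, 20]).  The
alternatives `Gain − W·NC` and `Gain/(1 + W·NC)` remain selectable for
sensitivity studies.  Pose quality is distance rmsd over corresponding
ligand heavy atoms, matched by atom name, **without superposition**
(docking-frame rmsd) and without symmetry correction — symmetric ligands
would need a graph-automorphism-aware rmsd, which is out of scope.  Decoy
ranking takes the top-scored pose (stable sort; exact ties are flagged and
the lowest rmsd among the tied poses is reported) and succeeds at cutoff c
when its rmsd ≤ c; the native pose is excluded from the pool by default.

## Triangle enrichment

Every motif's 3 protein atoms form a "protein triangle" keyed by the sorted
multiset of its atom types (560 keys over 14 types; 455 excluding metals).
`F_b = (n_s/n)/(N_s/N)` compares a triangle's relative frequency in
interaction networks with its relative frequency in whole proteins, where
whole-protein triangles are the unordered atom triples with all sides
> 2 Å, the two shortest < 10 Å and the longest < 13 Å.  Counting unit: a
distinct atom triple counts once per complex however many motifs contain
it; the same choice applies on the whole-protein side, so the two
frequencies are commensurable.  Metal-containing triangles are computed but
excluded from ranked output by default — metals are rare and almost always
ligand-coordinating, which makes their F_b uninformatively large.

## Corpus eligibility

Statistics corpora admit only X-ray structures with a single ligand copy,
no nucleic-acid chains, no heme component (a heme behaves as part of the
protein, not as a ligand), and no covalent protein–ligand bond.  Covalency
is operationalized as any ligand–protein heavy-atom distance below 1.9 Å (a
typical single-bond upper bound; configurable).  Waters and common
crystallization additives (editable list shipped with the package) are
dropped on loading; entries with multiple copies of the ligand component
are excluded rather than arbitrated.  Metal ions within 3.0 Å of a protein
N/O/S atom are re-assigned to the protein side and participate in networks
there; uncoordinated metals are treated as crystallization ions.  Altloc
duplicates keep the highest-occupancy copy (ties → altloc A).

## Synthetic fixtures: what they do and do not show

The generators build *clusters*: 2 ligand atoms 1.4 Å apart plus 3 protein
atoms placed so that exactly one chosen motif topology is realized under
the default 2–4 Å window — connected pairs at 3.0 Å (inside the window even
after the 10 % raise), non-connected pairs at ≥ 4.1 Å.  Clusters sit 30 Å
apart, so a complex's network is the disjoint union of its clusters, and
far-away padding atoms shape the atom-type denominators without forming
edges.  Decoy sets apply rigid rotations (≤ 25°), translations (≤ 5 Å) and
per-atom jitter (σ = 0.2 Å) to the ligand, recording the true rmsd; one
guaranteed near-native decoy anchors each set.  The demonstration docking
case adds a repulsive "wall" of protein atoms 4.5 Å beneath each cluster so
that inward-pushed poses accumulate clashes.

These fixtures validate the counting, grading and ranking machinery under
known ground truth.  They do **not** emulate real packing densities, chain
connectivity, solvation, conformational strain, or chemically consistent
ligand geometry; passing the planted self-docking benchmark shows the
scoring pipeline is internally sound, not that it reaches any particular
success rate on real decoy benchmarks, which require external structure
sets.  Problem sizes used by the test suite and the acceptance script —
corpora of 8–60 complexes, 100 random networks against the exhaustive
oracle, 100 seeded corpora for planted-grade recovery, 20 docking
replicates of 100 decoys — were chosen to make each property statistically
meaningful at interactive runtimes.

## Numerical notes and limitations

* All geometry is in Å on heavy-atom centers; no periodic images.
* Distance comparisons are plain floating-point inequalities; thresholds
  are exact table values, so edges at exactly the cutoff are included.
* Fixture coordinates use closed-form placements; determinism under a seed
  holds across platforms (NumPy Generator with explicit seeds throughout).
* The derivation pipeline cannot reproduce the manually curated threshold
  table of the original corpus; it ships the reproducible equivalent plus a
  loader for any externally supplied table.
* 2×2, 1×3 and 1×n motif families are deliberately not scored: the 1×n
  census is dominated by the middle of its combinatorial range, and the
  small families add no discriminative signal.
* Ligand bond graphs must cover every ligand heavy atom; mismatched atom
  names between coordinates and dictionary are an error, not a guess.
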