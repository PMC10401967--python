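# Methods

## The active-state model

A catalytically competent kinase domain must bind ATP, two Mg²⁺ ions and a
substrate peptide at once.  The package encodes this as five geometric
criteria on one chain, all on heavy atoms, all evaluated from author-curated
anchor residues.  A chain is **Active** iff

    DFGin ∧ BLAminus ∧ saltbridge ∈ {in, skipped}
          ∧ ActLoopNT = in ∧ ActLoopCT ∈ {in, skipped}

with these observables and defaults (packaged in `data/cutoffs.json`):

| observable | atoms | in-state | default cutoff |
| --- | --- | --- | --- |
| DFG anchor distances | DFG-Phe Cζ ↔ β3-Lys Cα, ↔ Glu4 Cα | DFGin: Glu4 ≤ 11 Å ∧ Lys ≥ 11 Å | 11.0 Å |
| salt bridge | Lys Nζ ↔ min(Glu Oε1, Oε2) | < cutoff | 3.6 Å |
| ActLoopNT | min of N(DFG6)–O(XHRD), O(DFG6)–N(XHRD) | < cutoff | 3.6 Å |
| ActLoopCT | APE9 Cα ↔ HRD-Arg O | < cutoff | 6.0 Å (8.0 Å for TYR) |
| spine 1–3 | closest side-chain heavy-atom pairs | intact: max < cutoff | 5.0 Å (reported only) |

Boundary semantics: every "in" test is strict (<); the spatial rule uses
≤/≥ at 11 Å with the DFGin branch tested first, so the measure-zero case of
exact equality on both distances resolves to DFGin deterministically.
DFGout is the mirrored condition; anything else is DFGinter.

The spine is reported but never gates the verdict: structures passing the
five criteria essentially always have an intact spine, and the rare
exceptions (C-helix distortions) do not touch ATP or substrate contacts.

### Unevaluable, not failed

A missing atom or residue (disordered loops, truncated side chains) makes
only the dependent observable absent; its criterion becomes *unevaluable*
and forces the Active verdict to unevaluable rather than false.  This
mirrors how curated structure tables mark disordered anchors with "–".

### Family exceptions

`data/family_exceptions.tsv` (user-extendable) lists genes with skipped
criteria: WNK1–4 (no β3 lysine) and MAP3K12/13 (Asp in place of the C-helix
Glu, bent C-helix) skip the salt bridge; HASPIN, TP53RK and PKDCC (no APE
motif, divergent C-terminal loop) skip ActLoopCT.

### Anchors and offsets

All derived positions are **ordinal** (sequence-position) offsets, never
author-number arithmetic, so insertion codes and numbering gaps cannot
corrupt them: DFG6 = DFG-Asp + 5, APE9 = APE-Glu − 8, Glu4 = C-helix
Glu + 4, HPN7 = HPN-His + 6, XHRD = HRD-His − 1, XDFG = DFG-Asp − 1.  The
activation loop spans DFG-Asp through APE-Glu inclusive; a config switch
(`loop_includes_motifs`) trims the motif residues for users who prefer the
interior definition, and kinases lacking APE give the loop end explicitly.
Anchor-by-pattern search (degenerate tripeptides [HYLF]RD / D[FLYWMV]G /
[ASP]PE, ordered, DFG→APE separation 15–45 residues) is a convenience that
refuses ambiguous placements; explicit configs are the canonical input.

### Dihedral labels

Ramachandran basins use a rectangular, total partition (packaged in
`data/rama_regions.json`, overridable): for φ < 0, ψ ∈ [−120, 50) is A and
the rest is B; for φ ≥ 0, ψ ∈ [−50, 100) is L and the rest is E.  χ1 bins
are the staggered wells with edges at −120/0/120° (gauche−, gauche+,
trans).  Half-open intervals make every angle pair land in exactly one bin.
This partition is coarser than the reference Kincore labelling scheme; the
B/L/A basins agree where it matters for the BLAminus test, but users
replicating Kincore *inactive-state sublabels* should substitute its exact
boundaries via the config.  Torsions follow the standard IUPAC sign
convention (cis = 0, right-handed positive), wrapped to (−180, 180].

For non-Phe residues at the DFG-Phe position (Leu/Tyr/Trp/Met/Val occur),
the Cζ anchor is replaced by the present side-chain atom with the greatest
bond-path distance from Cβ (ties by name order: Leu → CD1, Met → CE,
Trp → CH2, Val → CG1); Cζ itself is used whenever present.  The table is
overridable per residue type.

## Model assessment

Per-residue pLDDT is read from the Cα B-factor (predicted models write one
value to all atoms of a residue).  The ranking statistic is the **minimum**
loop pLDDT: one doubtful residue is enough to doubt the loop.  Ties break
by mean pLDDT, then model id, making the order total and
permutation-invariant.  Operations that interpret B-factors as pLDDT refuse
structures not flagged as models.

Benchmarking is fit-then-measure: residues are paired by global sequence
alignment (near-identical sequences only, ≥ 90 % identity — this is a
same-protein protocol, not a homology aligner), the C-terminal domains are
superposed by Kabsch (SVD with determinant correction; reflections
excluded) on Cα pairs, and the loop backbone RMSD (N, Cα, C, O) is read off
in that frame without refitting.  The "C-terminal domain" is defined
sequence-wise as everything after the activation loop plus the
catalytic-loop block from HRD-His − 10 through XHRD, with the loop itself
always excluded from the fit; an explicit residue list can override this.
RMSD is computed over the intersection of loop positions with complete
backbones, and the pair count is reported so callers can require
completeness.  When several reference conformations exist, the tool reports
an RMSD against each; it does not pick one.

## The synthetic generator

Real kinase coordinates cannot be bundled, so ground truth is manufactured:

* `build_backbone` grows N/Cα/C/O from per-residue (φ, ψ, ω) with ideal
  bond geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å; angles
  111.2/116.2/121.7/120.8°); recomputing torsions from the output
  reproduces the inputs to 1e-6°.
* `make_kinase_fixture` lays a 100-residue chain with motifs at fixed
  ordinals (activation loop of 23 residues), a helical block keeping the
  two DFG anchor Cα atoms mutually reachable, and places the criterion
  atoms analytically: Nζ/Oε on a ray (salt bridge), Cζ by two-sphere
  intersection (anchor distances; triangle-inequality violations raise a
  construction error naming the pair), repositioned carbonyl O atoms
  (ActLoopNT/CT — these two oxygens are knowingly non-stereochemical), χ1
  atoms by torsion placement, and spine pseudo-atoms along directions with
  non-positive projection onto competing atoms so the *minimum* pair
  distance equals the target.  Every requested observable is verified
  against `measure_geometry` to 1e-6 Å at construction time.
* `perturb_loop` adds seeded isotropic Gaussian noise (std σ per
  coordinate) to loop atoms only, so E[RMSD] ≈ σ√3.
* `make_model_ensemble` uses a geometric ladder of σ from 0.2 to 2.0 Å
  (shuffled per seed) so per-model error levels are well separated, and
  sets the loop pLDDT to 95 − 20σ plus Gaussian noise of std
  30·(1 − coupling).  At coupling 1 the pLDDT order is exactly the inverse
  error order; at coupling 0 it is uninformative.

What fixtures do *not* emulate: real fold topology, rotameric side chains,
crystallographic artefacts, missolved carbonyls, or correlated loop
motions.  Passing tests therefore demonstrate that the measurement and
decision logic is correct, not that the cutoffs discriminate on real
structures — the cutoffs themselves are taken as given.

## Curation rules

Hit filtering keeps identity > 0.50, coverage > 0.90, gap fraction < 0.10,
all strict.  Clustering is greedy longest-first (ties by input order): a
sequence joins the representative set unless its identity to an existing
representative exceeds 0.90, guaranteeing no representative pair above the
threshold.  Identity is matches / alignment columns of a global pairwise
alignment with affine gaps (match 2, mismatch −1, open −10, extend −0.5);
word-based estimators differ slightly, so the threshold and metric are
configurable.  Template selection sorts by (ordered loop residues desc,
resolution asc, entry, chain) and takes up to two per kinase from distinct
PDB entries, after removing the target's own entry.  MSA truncation keeps
the query plus the first depth − 1 rows; depths of a handful of sequences
are the regime in which template-driven predictors actually follow their
templates.

## Numerical choices and problem sizes

* Alt-loc reduction: highest occupancy, ties to the alphabetically first
  alt-loc id.  Only model 1 of multi-model files is read.  Hydrogens are
  dropped on input.
* Kabsch requires ≥ 3 non-collinear pairs; degenerate configurations raise
  rather than silently reflecting.
* The acceptance script runs 200 regime fixtures, 100 oracle clouds, 100
  rigid transforms, 50 ranking trials and a 25-kinase synthetic benchmark
  with 6-model ensembles — sizes chosen to give stable percentages in
  seconds on one CPU; all randomness derives from `--seed`.

## Known limitations

* The verdict quality on experimental structures is bounded by the anchor
  annotation supplied; no HMM-based automatic annotation is included.
* Non-{A,B,L} basins are all labelled E, so inactive-state sublabels can
  disagree with finer reference taxonomies; the Active verdict is
  unaffected.
* ATP-presence reporting (when used) is by chain-associated HETATM code
  only; no geometric "in the active site" test is applied.
* Relaxed vs. unrelaxed model coordinates are classified as given; no
  reconciliation between the two is attempted.
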