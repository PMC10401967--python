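"""Sequence and template curation rules for building active-model inputs.

Operates purely on tabular/sequence data — the products of a sequence
search and of structure classification — without any network access:

* ortholog-hit filtering (identity > 50%, coverage > 90%, gaps < 10%,
  all strict);
* greedy identity clustering at 90% to de-redundify ortholog sets
  (CD-HIT-style: longest first, a sequence joins the first representative
  it exceeds the threshold against);
* active-template selection: per kinase, up to two structures from
  distinct PDB entries, preferring complete activation loops and then
  higher resolution;
* MSA depth truncation (query always kept first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from Bio import Align

__all__ = [
    "SequenceHit",
    "TemplateCandidate",
    "filter_hits",
    "hit_from_alignment",
    "pairwise_identity",
    "greedy_identity_cluster",
    "select_active_templates",
    "truncate_msa",
]


@dataclass
class SequenceHit:
    """One sequence-search hit with its alignment statistics as fractions."""

    query_id: str
    subject_id: str
    identity_fraction: float
    coverage_fraction: float
    gap_fraction: float
    aligned_subject_sequence: str = ""

    def __post_init__(self) -> None:
        for name in ("identity_fraction", "coverage_fraction", "gap_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class TemplateCandidate:
    """One candidate template chain for a kinase."""

    kinase_id: str
    pdb_entry: str
    chain: str
    n_ordered_al: int
    resolution: Optional[float] = None
    is_active: bool = True

    def __post_init__(self) -> None:
        if self.n_ordered_al < 0:
            raise ValueError("n_ordered_al must be >= 0")


def filter_hits(
    hits: Sequence[SequenceHit],
    id_min: float = 0.50,
    cov_min: float = 0.90,
    gap_max: float = 0.10,
) -> list[SequenceHit]:
    """Keep hits with identity > id_min, coverage > cov_min and gap
    fraction < gap_max — all three comparisons strict."""
    return [
        h for h in hits
        if h.identity_fraction > id_min
        and h.coverage_fraction > cov_min
        and h.gap_fraction < gap_max
    ]


def hit_from_alignment(
    query_id: str,
    subject_id: str,
    query_aln: str,
    subject_aln: str,
    query_length: int,
) -> SequenceHit:
    """Derive hit statistics from a pair of aligned (gapped) sequences.

    Identity is matches over alignment columns with both residues present;
    coverage is the fraction of the full query covered by aligned columns;
    the gap fraction counts gap columns over the alignment length.
    """
    if len(query_aln) != len(subject_aln):
        raise ValueError("aligned sequences differ in length")
    columns = len(query_aln)
    matches = aligned = gaps = 0
    for q, s in zip(query_aln, subject_aln):
        if q == "-" or s == "-":
            gaps += 1
            continue
        aligned += 1
        if q == s:
            matches += 1
    return SequenceHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_fraction=matches / max(1, aligned),
        coverage_fraction=aligned / max(1, query_length),
        gap_fraction=gaps / max(1, columns),
        aligned_subject_sequence=subject_aln,
    )


_ALIGNER: Optional[Align.PairwiseAligner] = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = Align.PairwiseAligner(
            mode="global",
            match_score=2.0,
            mismatch_score=-1.0,
            open_gap_score=-10.0,
            extend_gap_score=-0.5,
        )
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps count
    as columns).  This is the clustering metric; it differs slightly from
    word-based estimators, which is why the threshold is configurable."""
    if not seq_a or not seq_b:
        return 0.0
    alignment = _aligner().align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / max(1, len(a))


SeqItem = Union[str, tuple[str, str]]


def _seq_of(item: SeqItem) -> str:
    return item[1] if isinstance(item, tuple) else item


def greedy_identity_cluster(
    sequences: Sequence[SeqItem],
    threshold: float = 0.90,
) -> list[SeqItem]:
    """Greedy redundancy reduction: no two representatives more than
    ``threshold`` identical.

    Sequences are processed longest-first (ties keep input order); each
    becomes a new representative unless its identity to an existing one
    exceeds the threshold.  Representatives are returned in processing
    order.  Accepts plain strings or (name, sequence) tuples.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(
        range(len(sequences)), key=lambda i: (-len(_seq_of(sequences[i])), i)
    )
    representatives: list[SeqItem] = []
    for i in order:
        seq = _seq_of(sequences[i])
        if all(
            pairwise_identity(seq, _seq_of(rep)) <= threshold
            for rep in representatives
        ):
            representatives.append(sequences[i])
    return representatives


def select_active_templates(
    candidates: Sequence[TemplateCandidate],
    per_kinase: int = 2,
    exclude_entry: Optional[str] = None,
) -> dict[str, list[TemplateCandidate]]:
    """Choose up to ``per_kinase`` active templates per kinase.

    Ranking: most ordered activation-loop residues first, then best
    (lowest) resolution, then entry and chain id for determinism; chosen
    templates must come from distinct PDB entries.  ``exclude_entry``
    removes the target's own entry (self-template exclusion); inactive
    candidates are ignored.
    """
    exclude = exclude_entry.lower() if exclude_entry else None
    by_kinase: dict[str, list[TemplateCandidate]] = {}
    for cand in candidates:
        if not cand.is_active:
            continue
        if exclude and cand.pdb_entry.lower() == exclude:
            continue
        by_kinase.setdefault(cand.kinase_id, []).append(cand)

    selections: dict[str, list[TemplateCandidate]] = {}
    for kinase, pool in by_kinase.items():
        pool.sort(
            key=lambda c: (
                -c.n_ordered_al,
                c.resolution if c.resolution is not None else float("inf"),
                c.pdb_entry.lower(),
                c.chain,
            )
        )
        chosen: list[TemplateCandidate] = []
        used_entries: set[str] = set()
        for cand in pool:
            if len(chosen) >= per_kinase:
                break
            if cand.pdb_entry.lower() in used_entries:
                continue
            chosen.append(cand)
            used_entries.add(cand.pdb_entry.lower())
        selections[kinase] = chosen
    return selections


def truncate_msa(msa: Sequence[SeqItem], depth: int) -> list[SeqItem]:
    """Query (first row) plus the first ``depth`` − 1 further rows, order
    preserved.  Shallow alignments (depth down to 1 = query only) are the
    lever that makes a template-driven predictor follow its templates."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not msa:
        raise ValueError("empty MSA")
    return list(msa[:depth])
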