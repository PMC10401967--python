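"""Rank predicted kinase models by activation-loop pLDDT and benchmark
them against reference structures.

The ranking statistic is the *minimum* per-residue pLDDT over the
activation loop: a single low-confidence loop residue is enough to doubt
the loop conformation, and across kinases the highest-min-pLDDT model is
the one (or nearly the one) closest to the substrate-bound reference.

Benchmarking follows a fit-then-measure protocol: the C-terminal domains
are superposed (Kabsch on Cα pairs), the transform is applied to the
model, and the activation-loop backbone RMSD (N, CA, C, O) is read off
without refitting on the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .annotation import KinaseAnnotation
from .classify import ConformationLabel
from .geometry import GeometryError, kabsch_superpose, rmsd_no_fit
from .structure import ResidueRecord, StructureModel, get_atom

logger = logging.getLogger(__name__)

__all__ = [
    "ModelScore",
    "CorrespondenceMap",
    "BenchmarkSummary",
    "min_plddt_activation_loop",
    "rank_models",
    "build_correspondence",
    "activation_loop_rmsd",
    "benchmark_summary",
]

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class ModelScore:
    """Per-model assessment record."""

    model_id: str
    min_plddt_al: float
    mean_plddt_al: float
    rmsd_al: Optional[float] = None
    n_al_residues: int = 0
    active_label: Optional[ConformationLabel] = None

    def __post_init__(self) -> None:
        # 1e-9 absorbs accumulation error when all loop values are equal
        if not (0.0 <= self.min_plddt_al <= self.mean_plddt_al + 1e-9
                and self.mean_plddt_al <= 100.0):
            raise ValueError(
                "need 0 <= min_plddt_al <= mean_plddt_al <= 100"
            )
        if self.rmsd_al is not None and self.rmsd_al < 0:
            raise ValueError("rmsd_al must be >= 0")


@dataclass
class CorrespondenceMap:
    """One-to-one residue pairings (model ordinal, reference ordinal) for
    the C-terminal-domain fit set and the activation-loop measure set."""

    ctd_pairs: list[tuple[int, int]] = field(default_factory=list)
    loop_pairs: list[tuple[int, int]] = field(default_factory=list)
    identity: float = 1.0


def _polymer(chain: Sequence[ResidueRecord]) -> list[ResidueRecord]:
    return [r for r in chain if not r.is_hetero]


def min_plddt_activation_loop(
    model: StructureModel,
    annotation: KinaseAnnotation,
    chain_id: Optional[str] = None,
) -> tuple[float, float]:
    """(min, mean) Cα B-factor pLDDT over the activation-loop residues.

    Refuses experimental structures: B-factors are only a confidence in
    predicted models.  Predicted models write one pLDDT to every atom of a
    residue; the Cα value is taken as canonical.
    """
    if not model.is_model:
        raise ValueError(
            f"{model.entry_id}: experimental structure; B-factors are not "
            "pLDDT values (pass a model-flagged structure)"
        )
    chain_id = chain_id or model.chain_ids[0]
    polymer = _polymer(model.chains[chain_id])
    values = []
    for i in annotation.loop_ordinals():
        if 0 <= i < len(polymer):
            ca = get_atom(polymer[i], "CA")
            if ca is not None:
                values.append(ca.b_factor)
    if not values:
        raise ValueError("activation loop span has no Cα atoms")
    return float(min(values)), float(np.mean(values))


def rank_models(
    scores: Sequence[ModelScore], require_active: bool = False
) -> list[ModelScore]:
    """Order models best-first: descending min loop pLDDT, ties by mean,
    then model_id.  With ``require_active``, models whose classification is
    not Active are excluded before ranking."""
    if not scores:
        raise ValueError("no models to rank")
    pool = list(scores)
    if require_active:
        pool = [
            s for s in pool
            if s.active_label is not None and s.active_label.active is True
        ]
        if not pool:
            logger.warning("all models excluded by the Active requirement")
            return []
    return sorted(
        pool, key=lambda s: (-s.min_plddt_al, -s.mean_plddt_al, s.model_id)
    )


def _global_alignment_pairs(seq_a: str, seq_b: str
                            ) -> tuple[list[tuple[int, int]], float]:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-5.0,
        extend_gap_score=-0.5,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                matches += 1
    identity = matches / max(1, len(pairs))
    return pairs, identity


def _ctd_ordinals(annotation: KinaseAnnotation, n_res: int) -> set[int]:
    """C-terminal-domain fit set: everything after the activation loop plus
    the catalytic-loop block (HRD-His − 10 … XHRD); the loop itself is
    always excluded from the fit."""
    loop_end = annotation.activation_loop[1]
    ordinals = set(range(loop_end + 1, n_res))
    ordinals |= set(range(max(0, annotation.hrd_h - 10), annotation.xhrd + 1))
    ordinals -= set(annotation.loop_ordinals())
    return ordinals


def build_correspondence(
    model_chain: Sequence[ResidueRecord],
    reference_chain: Sequence[ResidueRecord],
    annotation_model: KinaseAnnotation,
    annotation_ref: KinaseAnnotation,
    identity_min: float = 0.90,
) -> CorrespondenceMap:
    """Pair model and reference residues by global sequence alignment.

    The sequences must be near-identical (>= ``identity_min`` over the
    aligned positions) — this is a same-protein benchmark pairing, not a
    homology aligner.  Loop pairs are restricted to positions where both
    partners have a complete N/CA/C/O backbone.
    """
    model_poly = _polymer(model_chain)
    ref_poly = _polymer(reference_chain)
    seq_m = "".join(r.aa1 for r in model_poly)
    seq_r = "".join(r.aa1 for r in ref_poly)
    pairs, identity = _global_alignment_pairs(seq_m, seq_r)
    if identity < identity_min:
        raise ValueError(
            f"sequence identity {identity:.2f} below {identity_min:.2f}; "
            "supply an explicit correspondence map"
        )

    ctd_m = _ctd_ordinals(annotation_model, len(model_poly))
    ctd_r = _ctd_ordinals(annotation_ref, len(ref_poly))
    loop_m = set(annotation_model.loop_ordinals())
    loop_r = set(annotation_ref.loop_ordinals())

    cmap = CorrespondenceMap(identity=identity)
    for i, j in pairs:
        if i in ctd_m and j in ctd_r:
            cmap.ctd_pairs.append((i, j))
        if i in loop_m and j in loop_r:
            if _has_backbone(model_poly[i]) and _has_backbone(ref_poly[j]):
                cmap.loop_pairs.append((i, j))
    return cmap


def _has_backbone(residue: ResidueRecord) -> bool:
    return all(get_atom(residue, name) is not None for name in BACKBONE)


def activation_loop_rmsd(
    model_chain: Sequence[ResidueRecord],
    reference_chain: Sequence[ResidueRecord],
    cmap: CorrespondenceMap,
) -> tuple[float, float]:
    """(loop backbone RMSD, fitted CTD Cα RMSD) after CTD superposition.

    The Kabsch fit uses only C-terminal-domain Cα pairs; the returned loop
    RMSD is measured over N/CA/C/O of the loop pairs in that frame, with no
    refitting on the loop.
    """
    model_poly = _polymer(model_chain)
    ref_poly = _polymer(reference_chain)

    ctd_mobile, ctd_ref = [], []
    for i, j in cmap.ctd_pairs:
        ca_m = get_atom(model_poly[i], "CA")
        ca_r = get_atom(ref_poly[j], "CA")
        if ca_m is not None and ca_r is not None:
            ctd_mobile.append(ca_m.position)
            ctd_ref.append(ca_r.position)
    if len(ctd_mobile) < 3:
        raise GeometryError("fewer than 3 CTD Cα pairs for superposition")
    if not cmap.loop_pairs:
        raise GeometryError("no complete activation-loop residue pairs")

    transform, rmsd_ctd = kabsch_superpose(
        np.asarray(ctd_mobile), np.asarray(ctd_ref)
    )

    loop_mobile, loop_ref = [], []
    for i, j in cmap.loop_pairs:
        for name in BACKBONE:
            loop_mobile.append(get_atom(model_poly[i], name).position)
            loop_ref.append(get_atom(ref_poly[j], name).position)
    moved = transform.apply(np.asarray(loop_mobile))
    rmsd_al = rmsd_no_fit(moved, np.asarray(loop_ref))
    return rmsd_al, rmsd_ctd


@dataclass
class BenchmarkSummary:
    """Fractions of kinases whose best model is under the RMSD thresholds."""

    n: int
    n_below_1: int
    n_below_2: int
    fraction_below_1: float
    fraction_below_2: float
    histogram: list[tuple[float, float, int]]  # (lo, hi, count)


def benchmark_summary(
    records: Sequence[tuple[str, float]],
    bin_width: float = 0.5,
    max_bin: float = 5.0,
) -> BenchmarkSummary:
    """Summarise (kinase, best loop RMSD) records: counts and fractions
    below 1.0 and 2.0 Å plus a fixed-width histogram (last bin open)."""
    if not records:
        raise ValueError("no benchmark records")
    rmsds = np.asarray([r[1] for r in records], float)
    n = len(rmsds)
    edges = list(np.arange(0.0, max_bin + bin_width / 2, bin_width))
    histogram = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        histogram.append((lo, hi, int(np.sum((rmsds >= lo) & (rmsds < hi)))))
    histogram.append((edges[-1], float("inf"), int(np.sum(rmsds >= edges[-1]))))
    n1 = int(np.sum(rmsds < 1.0))
    n2 = int(np.sum(rmsds < 2.0))
    return BenchmarkSummary(
        n=n, n_below_1=n1, n_below_2=n2,
        fraction_below_1=n1 / n, fraction_below_2=n2 / n,
        histogram=histogram,
    )
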