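"""Resolve anchor-residue positions of a kinase domain chain.

Every geometric criterion is anchored on a handful of conserved motifs: the
β3 lysine, the C-helix glutamate, the HPN motif in the C-helix/β4 loop, the
catalytic-loop HRD motif, the DFG motif opening the activation loop and the
APE motif closing it.  Derived positions (DFG6, APE9, Glu4, HPN7, XHRD,
XDFG) are pure *ordinal* offsets — residues are counted along the chain, so
author-numbering gaps and insertion codes cannot corrupt them:

* DFG6 is activation-loop residue 6 counting DFG-Asp as 1 (DFGxxX);
* APE9 is residue 9 from the loop end counting APE-Glu as 1 (XxxxxxAPE);
* Glu4 is four residues after the salt-bridge Glu;
* HPN7 is the seventh residue counting HPN-His as 1 (HPNxxxX);
* XHRD / XDFG are the residues immediately before HRD-His / DFG-Asp.

Anchors come from an explicit per-kinase config (author numbering, the way
structural literature reports them) or from a degenerate tripeptide search.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .structure import ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "AnnotationError",
    "AmbiguousAnchorError",
    "AnnotationConfig",
    "KinaseAnnotation",
    "annotate_from_config",
    "annotate_by_anchor_search",
    "apply_family_exceptions",
    "load_exception_registry",
    "DEFAULT_MOTIF_PATTERNS",
]

FAMILIES = ("AGC", "CAMK", "CK1", "CMGC", "NEK", "OTHER", "STE", "TKL", "TYR")


class AnnotationError(ValueError):
    """An anchor cannot be resolved against the chain."""


class AmbiguousAnchorError(AnnotationError):
    """Anchor search found zero or several consistent motif placements."""


@dataclass
class AnnotationConfig:
    """Explicit anchor specification for one kinase chain.

    ``anchors`` maps anchor names to author residue numbers (int, or a
    string like ``"179"`` / ``"179A"`` with an insertion code).  Recognised
    anchor names: ``beta3_lys``, ``chelix_glu``, ``hpn_his``, ``hrd_his``,
    ``dfg_asp``, ``ape_ala`` and, for kinases without an APE motif,
    ``actloop_end``.  ``expected`` optionally gives anchor sequences (e.g.
    ``{"hrd_his": "HRD"}``) which are validated with a warning — AKT1's YRD
    is the canonical reason this is not an error.
    """

    gene_label: str
    family: str
    anchors: dict[str, int | str] = field(default_factory=dict)
    expected: dict[str, str] = field(default_factory=dict)
    loop_includes_motifs: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise AnnotationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            gene_label=data["gene_label"],
            family=data["family"],
            anchors=data.get("anchors", {}),
            expected=data.get("expected", {}),
            loop_includes_motifs=data.get("loop_includes_motifs", True),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, gene_label: str, family: str
                 ) -> "AnnotationConfig":
        """TSV with columns: anchor, auth_seq_num, icode (icode optional)."""
        anchors: dict[str, int | str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                icode = (row.get("icode") or "").strip()
                anchors[row["anchor"]] = f"{row['auth_seq_num']}{icode}"
        return cls(gene_label=gene_label, family=family, anchors=anchors)


@dataclass
class KinaseAnnotation:
    """Resolved anchor and derived positions, as 0-based ordinals.

    All fields are indices into the polymer-residue list of the annotated
    chain (hetero residues excluded); ``None`` marks an anchor the kinase
    lacks (e.g. the C-helix Glu of WNK-like kinases), which renders the
    dependent criteria unevaluable rather than failed.
    """

    family: str
    gene_label: str
    beta3_lys: Optional[int]
    chelix_glu: Optional[int]
    glu4: Optional[int]
    hpn_his: Optional[int]
    hpn7: Optional[int]
    xhrd: int
    hrd_h: int
    hrd_r: int
    hrd_d: int
    xdfg: int
    dfg_d: int
    dfg_f: int
    dfg_g: int
    dfg6: int
    ape_a: Optional[int]
    ape_p: Optional[int]
    ape_e: Optional[int]
    ape9: Optional[int]
    activation_loop: tuple[int, int]  # inclusive ordinal span
    skip_saltbridge: bool = False
    skip_actloopct: bool = False

    def loop_ordinals(self) -> range:
        start, end = self.activation_loop
        return range(start, end + 1)


def _polymer(chain: Sequence[ResidueRecord]) -> list[ResidueRecord]:
    return [r for r in chain if not r.is_hetero]


def _parse_key(value: int | str) -> tuple[int, str]:
    if isinstance(value, int):
        return value, ""
    m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", str(value).strip())
    if not m:
        raise AnnotationError(f"cannot parse residue number {value!r}")
    return int(m.group(1)), m.group(2)


def _ordinal_of(polymer: list[ResidueRecord], anchor: str,
                value: int | str) -> int:
    key = _parse_key(value)
    for i, res in enumerate(polymer):
        if res.key == key:
            return i
    raise AnnotationError(
        f"anchor {anchor!r}: residue {value!r} not present in chain"
    )


def _offset(polymer: list[ResidueRecord], base: Optional[int], delta: int,
            name: str) -> Optional[int]:
    if base is None:
        return None
    pos = base + delta
    if not 0 <= pos < len(polymer):
        raise AnnotationError(
            f"derived position {name!r} (ordinal {pos}) falls outside the chain"
        )
    return pos


def _check_expected(polymer: list[ResidueRecord], start: int,
                    expected: str, anchor: str) -> None:
    found = "".join(
        polymer[i].aa1 for i in range(start, min(start + len(expected), len(polymer)))
    )
    if found != expected:
        logger.warning(
            "anchor %s: expected sequence %r, found %r (kept; motif variants "
            "such as YRD-for-HRD are legitimate)", anchor, expected, found,
        )


def annotate_from_config(
    chain: Sequence[ResidueRecord], config: AnnotationConfig
) -> KinaseAnnotation:
    """Resolve an explicit anchor config against a chain.

    Raises :class:`AnnotationError` when a given anchor is absent from the
    chain or a derived position runs off either end.  Anchor sequence
    expectations, when provided, produce warnings only.
    """
    polymer = _polymer(chain)
    if not polymer:
        raise AnnotationError("chain has no polymer residues")

    def resolve(name: str) -> Optional[int]:
        if name not in config.anchors:
            return None
        return _ordinal_of(polymer, name, config.anchors[name])

    hrd_h = resolve("hrd_his")
    dfg_d = resolve("dfg_asp")
    if hrd_h is None or dfg_d is None:
        raise AnnotationError("anchors 'hrd_his' and 'dfg_asp' are required")
    beta3_lys = resolve("beta3_lys")
    chelix_glu = resolve("chelix_glu")
    hpn_his = resolve("hpn_his")
    ape_a = resolve("ape_ala")
    actloop_end = resolve("actloop_end")

    ape_e = _offset(polymer, ape_a, 2, "ape_e")
    if ape_e is None and actloop_end is None:
        raise AnnotationError(
            "activation-loop end unknown: give 'ape_ala' or 'actloop_end'"
        )

    for anchor, seq in config.expected.items():
        start = resolve(anchor)
        if start is not None:
            _check_expected(polymer, start, seq, anchor)

    loop_start = dfg_d
    loop_end = ape_e if ape_e is not None else actloop_end
    if not config.loop_includes_motifs:
        loop_start = _offset(polymer, dfg_d, 3, "activation_loop start")
        if ape_a is not None:
            loop_end = _offset(polymer, ape_a, -1, "activation_loop end")
    if loop_end < loop_start:
        raise AnnotationError("activation loop end precedes its start")

    annotation = KinaseAnnotation(
        family=config.family,
        gene_label=config.gene_label,
        beta3_lys=beta3_lys,
        chelix_glu=chelix_glu,
        glu4=_offset(polymer, chelix_glu, 4, "glu4"),
        hpn_his=hpn_his,
        hpn7=_offset(polymer, hpn_his, 6, "hpn7"),
        xhrd=_offset(polymer, hrd_h, -1, "xhrd"),
        hrd_h=hrd_h,
        hrd_r=_offset(polymer, hrd_h, 1, "hrd_r"),
        hrd_d=_offset(polymer, hrd_h, 2, "hrd_d"),
        xdfg=_offset(polymer, dfg_d, -1, "xdfg"),
        dfg_d=dfg_d,
        dfg_f=_offset(polymer, dfg_d, 1, "dfg_f"),
        dfg_g=_offset(polymer, dfg_d, 2, "dfg_g"),
        dfg6=_offset(polymer, dfg_d, 5, "dfg6"),
        ape_a=ape_a,
        ape_p=_offset(polymer, ape_a, 1, "ape_p"),
        ape_e=ape_e,
        ape9=_offset(polymer, ape_e, -8, "ape9"),
        activation_loop=(loop_start, loop_end),
    )
    return apply_family_exceptions(annotation)


DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    # degenerate anchor tripeptides; the His/Phe positions vary across
    # families (YRD in AKT1 and other AGC kinases, DLG/DYG etc. at DFG)
    "hrd": "[HYLF]RD",
    "dfg": "D[FLYWMV]G",
    "ape": "[ASP]PE",
}

#: acceptable ordinal separation between DFG-Asp and APE-Ala
DFG_APE_WINDOW = (15, 45)


def annotate_by_anchor_search(
    chain: Sequence[ResidueRecord],
    family: str,
    motif_patterns: Optional[dict[str, str]] = None,
    config: Optional[AnnotationConfig] = None,
    gene_label: str = "",
    dfg_ape_window: tuple[int, int] = DFG_APE_WINDOW,
) -> KinaseAnnotation:
    """Locate the HRD/DFG/APE tripeptides by degenerate pattern search.

    The placement must be unique under the ordering constraint
    HRD < DFG < APE with the DFG→APE separation inside ``dfg_ape_window``;
    otherwise an :class:`AmbiguousAnchorError` instructs use of an explicit
    config.  Non-motif anchors (β3 Lys, C-helix Glu, HPN-His) are taken from
    ``config`` when given — they are not reliably findable by pattern.
    """
    patterns = dict(DEFAULT_MOTIF_PATTERNS)
    if motif_patterns:
        patterns.update(motif_patterns)
    polymer = _polymer(chain)
    seq = "".join(r.aa1 for r in polymer)

    def hits(name: str) -> list[int]:
        return [m.start() for m in re.finditer(f"(?={patterns[name]})", seq)]

    placements = []
    lo, hi = dfg_ape_window
    for h in hits("hrd"):
        for d in hits("dfg"):
            if d <= h:
                continue
            for a in hits("ape"):
                if a <= d:
                    continue
                if lo <= a - d <= hi:
                    placements.append((h, d, a))
    if len(placements) != 1:
        raise AmbiguousAnchorError(
            f"found {len(placements)} consistent HRD/DFG/APE placements; "
            "provide an explicit AnnotationConfig"
        )
    h, d, a = placements[0]

    anchors: dict[str, int | str] = {}
    if config is not None:
        anchors.update(config.anchors)
    # translate ordinals back to author keys for the shared resolution path
    for name, ordinal in (("hrd_his", h), ("dfg_asp", d), ("ape_ala", a)):
        res = polymer[ordinal]
        anchors[name] = f"{res.seq_num}{res.insertion_code}"
    merged = AnnotationConfig(
        gene_label=(config.gene_label if config else gene_label) or gene_label,
        family=family,
        anchors=anchors,
        expected=config.expected if config else {},
        loop_includes_motifs=config.loop_includes_motifs if config else True,
    )
    return annotate_from_config(chain, merged)


def load_exception_registry(path: Optional[str | Path] = None
                            ) -> dict[str, tuple[bool, bool]]:
    """gene_label -> (skip_saltbridge, skip_actloopct), from the packaged
    registry TSV (or a user-supplied one)."""
    if path is None:
        src = resources.files("kinactive.data").joinpath("family_exceptions.tsv")
        fh = src.open()
    else:
        fh = open(path)
    registry: dict[str, tuple[bool, bool]] = {}
    with fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            registry[row["gene_label"]] = (
                row["skip_saltbridge"].strip() == "1",
                row["skip_actloopct"].strip() == "1",
            )
    return registry


def apply_family_exceptions(
    annotation: KinaseAnnotation,
    registry: Optional[dict[str, tuple[bool, bool]]] = None,
) -> KinaseAnnotation:
    """Set per-gene criterion-skip flags.

    The WNK kinases lack the β3 lysine ("with no lysine") and MAP3K12/13
    carry an Asp at the C-helix Glu position, so the salt-bridge criterion is
    skipped for them; HASPIN, TP53RK and PKDCC have no APE motif and skip the
    activation-loop C-terminal criterion.
    """
    if registry is None:
        registry = load_exception_registry()
    skip_sb, skip_ct = registry.get(annotation.gene_label, (False, False))
    return replace(annotation, skip_saltbridge=skip_sb, skip_actloopct=skip_ct)
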