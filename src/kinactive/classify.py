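"""Conformational classification of a kinase chain.

A structure is called catalytically *Active* when five criteria hold
simultaneously:

1. spatial state **DFGin** — the DFG-Phe ring tip (Cζ) sits near the C-helix
   Glu4 Cα (< 11 Å) and far from the β3-Lys Cα (> 11 Å);
2. dihedral state **BLAminus** — the X, D, F residues of the XDFG motif fall
   in the B, L, A Ramachandran regions and the Phe χ1 is gauche− (~ −60°);
3. the N-terminal domain **salt bridge** is formed: min Lys-Nζ to Glu-Oε1/2
   distance < 3.6 Å (skipped for WNK-like kinases and MAP3K12/13);
4. **ActLoopNT** — the activation loop is extended, shown by a
   backbone-backbone hydrogen bond between activation-loop residue 6 (DFG6)
   and the residue preceding HRD (XHRD): min of the N–O / O–N distances
   < 3.6 Å (the β6/β9 bridge);
5. **ActLoopCT** — the P+1 loop is placed for substrate binding: APE9 Cα to
   HRD-Arg backbone O < 6 Å in Ser/Thr kinases, < 8 Å in Tyr kinases
   (skipped for kinases lacking an APE motif).

The regulatory spine distances (HRD-His/DFG-Phe, DFG-Phe/Glu4, Glu4/HPN7)
are reported but deliberately not part of the verdict: nearly all structures
passing the five criteria have an intact spine anyway.

Missing atoms or residues make a criterion *unevaluable*, never failed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .annotation import KinaseAnnotation
from .geometry import (
    DihedralSet,
    GeometryError,
    chi1_path_atoms,
    chi1_rotamer,
    dihedral,
    distance,
    rama_region,
)
from .structure import ResidueRecord, get_atom

__all__ = [
    "FamilyCutoffs",
    "GeometryReport",
    "ConformationLabel",
    "measure_geometry",
    "spatial_label",
    "dihedral_label",
    "criterion_states",
    "classify",
    "dfg_tip_atom",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# bond-path depth of each side-chain heavy atom from CB; the DFG "Phe" tip
# surrogate is the present atom of greatest depth (name order breaks ties)
_SIDECHAIN_DEPTH: dict[str, dict[str, int]] = {
    "PHE": {"CG": 1, "CD1": 2, "CD2": 2, "CE1": 3, "CE2": 3, "CZ": 4},
    "TYR": {"CG": 1, "CD1": 2, "CD2": 2, "CE1": 3, "CE2": 3, "CZ": 4, "OH": 5},
    "TRP": {"CG": 1, "CD1": 2, "CD2": 2, "NE1": 3, "CE2": 3, "CE3": 3,
            "CZ2": 4, "CZ3": 4, "CH2": 5},
    "LEU": {"CG": 1, "CD1": 2, "CD2": 2},
    "MET": {"CG": 1, "SD": 2, "CE": 3},
    "VAL": {"CG1": 1, "CG2": 1},
    "ILE": {"CG1": 1, "CG2": 1, "CD1": 2},
    "HIS": {"CG": 1, "ND1": 2, "CD2": 2, "CE1": 3, "NE2": 3},
    "LYS": {"CG": 1, "CD": 2, "CE": 3, "NZ": 4},
    "ARG": {"CG": 1, "CD": 2, "NE": 3, "CZ": 4, "NH1": 5, "NH2": 5},
    "GLU": {"CG": 1, "CD": 2, "OE1": 3, "OE2": 3},
    "GLN": {"CG": 1, "CD": 2, "OE1": 3, "NE2": 3},
    "ASP": {"CG": 1, "OD1": 2, "OD2": 2},
    "ASN": {"CG": 1, "OD1": 2, "ND2": 2},
    "THR": {"OG1": 1, "CG2": 1},
    "SER": {"OG": 1},
    "CYS": {"SG": 1},
    "PRO": {"CG": 1, "CD": 2},
    "ALA": {},
    "GLY": {},
}


@dataclass
class FamilyCutoffs:
    """Distance cutoffs of the five criteria, Å (packaged defaults)."""

    dfg_anchor_cutoff: float = 11.0
    saltbridge_cutoff: float = 3.6
    actloop_nt_cutoff: float = 3.6
    actloop_ct_cutoff_nontyr: float = 6.0
    actloop_ct_cutoff_tyr: float = 8.0
    spine_cutoff: float = 5.0

    def __post_init__(self) -> None:
        values = (
            self.dfg_anchor_cutoff, self.saltbridge_cutoff,
            self.actloop_nt_cutoff, self.actloop_ct_cutoff_nontyr,
            self.actloop_ct_cutoff_tyr, self.spine_cutoff,
        )
        if any(v <= 0 for v in values):
            raise ValueError("all cutoffs must be positive")
        if self.actloop_ct_cutoff_tyr < self.actloop_ct_cutoff_nontyr:
            raise ValueError("TYR ActLoopCT cutoff must be >= non-TYR cutoff")

    @classmethod
    def from_json(cls, path: Optional[str | Path] = None) -> "FamilyCutoffs":
        if path is None:
            src = resources.files("kinactive.data").joinpath("cutoffs.json")
            with src.open() as fh:
                return cls(**json.load(fh))
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GeometryReport:
    """Every measured observable for one chain; ``None`` marks an
    observable whose atoms are missing (unevaluable downstream)."""

    d_phe_lys: Optional[float] = None
    d_phe_glu4: Optional[float] = None
    d_saltbridge: Optional[float] = None
    d_actloop_nt: Optional[float] = None
    d_actloop_ct: Optional[float] = None
    spine1: Optional[float] = None
    spine2: Optional[float] = None
    spine3: Optional[float] = None
    xdfg_dihedrals: dict[str, DihedralSet] = field(default_factory=dict)
    phe_chi1: Optional[float] = None

    @property
    def max_spine(self) -> Optional[float]:
        spines = (self.spine1, self.spine2, self.spine3)
        if any(s is None for s in spines):
            return None
        return max(spines)  # type: ignore[type-var]


@dataclass
class ConformationLabel:
    """Spatial/dihedral/criterion states and the Active verdict.

    ``active`` is True only when DFGin ∧ BLAminus ∧ salt bridge in-or-skipped
    ∧ ActLoopNT in ∧ ActLoopCT in-or-skipped; ``None`` when any required
    criterion is unevaluable.
    """

    spatial: str  # DFGin | DFGout | DFGinter | unevaluable
    dihedral: str  # e.g. BLAminus | ABAminus | ... | unevaluable
    saltbridge: str  # in | out | skipped | unevaluable
    actloop_nt: str  # in | out | unevaluable
    actloop_ct: str  # in | out | skipped | unevaluable
    spine_intact: Optional[bool]
    active: Optional[bool]
    reasons: list[str] = field(default_factory=list)
    report: Optional[GeometryReport] = None


def dfg_tip_atom(
    residue: ResidueRecord,
    overrides: Optional[dict[str, str]] = None,
):
    """The DFG-Phe ring-tip atom, or its surrogate for non-Phe residues.

    Cζ is used when present (Phe/Tyr); otherwise the present side-chain
    atom with the greatest bond-path distance from Cβ, ties broken by atom
    name order (Leu → CD1, Met → CE, Trp → CH2, Val → CG1).  ``overrides``
    maps three-letter codes to explicit atom names.
    """
    if overrides and residue.aa3 in overrides:
        return get_atom(residue, overrides[residue.aa3])
    cz = get_atom(residue, "CZ")
    if cz is not None:
        return cz
    depths = _SIDECHAIN_DEPTH.get(residue.aa3, {})
    candidates = [
        (depths.get(a.name, 0), a.name, a)
        for a in residue.atoms
        if a.name not in BACKBONE_ATOMS and a.name != "CB"
    ]
    if not candidates:
        return None
    best_depth = max(c[0] for c in candidates)
    tied = sorted(c for c in candidates if c[0] == best_depth)
    return tied[0][2]


def _sidechain_atoms(residue: Optional[ResidueRecord]):
    if residue is None:
        return []
    return [a for a in residue.atoms if a.name not in BACKBONE_ATOMS]


def _min_pair_distance(res_a, res_b) -> Optional[float]:
    atoms_a = _sidechain_atoms(res_a)
    atoms_b = _sidechain_atoms(res_b)
    if not atoms_a or not atoms_b:
        return None
    return min(
        distance(a.position, b.position) for a in atoms_a for b in atoms_b
    )


def _residue(polymer: list[ResidueRecord], ordinal: Optional[int]
             ) -> Optional[ResidueRecord]:
    if ordinal is None or not 0 <= ordinal < len(polymer):
        return None
    return polymer[ordinal]


def _backbone_dihedrals(polymer: list[ResidueRecord], i: int) -> DihedralSet:
    """φ/ψ of residue i (None at termini or with missing atoms)."""

    def pos(j: int, name: str):
        res = _residue(polymer, j)
        if res is None:
            return None
        atom = get_atom(res, name)
        return None if atom is None else atom.position

    n, ca, c = pos(i, "N"), pos(i, "CA"), pos(i, "C")
    c_prev = pos(i - 1, "C") if i > 0 else None
    n_next = pos(i + 1, "N")
    phi = psi = None
    try:
        if c_prev is not None and n is not None and ca is not None and c is not None:
            phi = dihedral(c_prev, n, ca, c)
    except GeometryError:
        phi = None
    try:
        if n is not None and ca is not None and c is not None and n_next is not None:
            psi = dihedral(n, ca, c, n_next)
    except GeometryError:
        psi = None
    return DihedralSet(phi=phi, psi=psi)


def _chi1(residue: Optional[ResidueRecord]) -> Optional[float]:
    if residue is None:
        return None
    path = chi1_path_atoms(residue.aa3)
    if path is None:
        return None
    atoms = [get_atom(residue, name) for name in path]
    if any(a is None for a in atoms):
        return None
    try:
        return dihedral(*(a.position for a in atoms))  # type: ignore[union-attr]
    except GeometryError:
        return None


def measure_geometry(
    chain: Sequence[ResidueRecord],
    annotation: KinaseAnnotation,
    tip_overrides: Optional[dict[str, str]] = None,
) -> GeometryReport:
    """Compute every criterion observable from heavy atoms.

    Any missing atom or residue yields ``None`` for that observable only;
    the rest of the report is still filled in.
    """
    polymer = [r for r in chain if not r.is_hetero]
    report = GeometryReport()

    lys = _residue(polymer, annotation.beta3_lys)
    glu = _residue(polymer, annotation.chelix_glu)
    glu4 = _residue(polymer, annotation.glu4)
    hpn7 = _residue(polymer, annotation.hpn7)
    xhrd = _residue(polymer, annotation.xhrd)
    hrd_h = _residue(polymer, annotation.hrd_h)
    hrd_r = _residue(polymer, annotation.hrd_r)
    dfg_f = _residue(polymer, annotation.dfg_f)
    dfg6 = _residue(polymer, annotation.dfg6)
    ape9 = _residue(polymer, annotation.ape9)

    # DFGin/DFGout anchor distances (Phe Cζ to Lys Cα and Glu4 Cα)
    tip = dfg_tip_atom(dfg_f, tip_overrides) if dfg_f is not None else None
    if tip is not None:
        for res, attr in ((lys, "d_phe_lys"), (glu4, "d_phe_glu4")):
            ca = get_atom(res, "CA") if res is not None else None
            if ca is not None:
                setattr(report, attr, distance(tip.position, ca.position))

    # salt bridge: Lys Nζ to the nearer of Glu Oε1/Oε2
    nz = get_atom(lys, "NZ") if lys is not None else None
    if nz is not None and glu is not None:
        oes = [a for n in ("OE1", "OE2") if (a := get_atom(glu, n)) is not None]
        if oes:
            report.d_saltbridge = min(
                distance(nz.position, a.position) for a in oes
            )

    # ActLoopNT: min of the two possible backbone H-bond pairings
    if dfg6 is not None and xhrd is not None:
        pairs = []
        for a_name, b_name in (("N", "O"), ("O", "N")):
            a = get_atom(dfg6, a_name)
            b = get_atom(xhrd, b_name)
            if a is not None and b is not None:
                pairs.append(distance(a.position, b.position))
        if pairs:
            report.d_actloop_nt = min(pairs)

    # ActLoopCT: APE9 Cα to HRD-Arg backbone carbonyl O
    ca9 = get_atom(ape9, "CA") if ape9 is not None else None
    o_r = get_atom(hrd_r, "O") if hrd_r is not None else None
    if ca9 is not None and o_r is not None:
        report.d_actloop_ct = distance(ca9.position, o_r.position)

    # regulatory spine: closest side-chain heavy-atom pairs
    report.spine1 = _min_pair_distance(hrd_h, dfg_f)
    report.spine2 = _min_pair_distance(dfg_f, glu4)
    report.spine3 = _min_pair_distance(glu4, hpn7)

    # XDFG backbone dihedrals and DFG-Phe χ1
    for key, ordinal in (
        ("X", annotation.xdfg), ("D", annotation.dfg_d), ("F", annotation.dfg_f),
    ):
        if ordinal is not None and 0 <= ordinal < len(polymer):
            report.xdfg_dihedrals[key] = _backbone_dihedrals(polymer, ordinal)
        else:
            report.xdfg_dihedrals[key] = DihedralSet(phi=None, psi=None)
    report.phe_chi1 = _chi1(dfg_f)
    if "F" in report.xdfg_dihedrals:
        report.xdfg_dihedrals["F"].chi1 = report.phe_chi1

    return report


def spatial_label(
    d_phe_lys: Optional[float],
    d_phe_glu4: Optional[float],
    cutoffs: Optional[FamilyCutoffs] = None,
) -> str:
    """DFGin / DFGout / DFGinter from the two Phe-Cζ anchor distances.

    DFGin: near Glu4 (≤ cutoff) and far from Lys (≥ cutoff); DFGout the
    reverse; DFGinter otherwise.  DFGin is tested first, so it takes
    precedence in the measure-zero case of exact equality on both.
    """
    cutoffs = cutoffs or FamilyCutoffs()
    if d_phe_lys is None or d_phe_glu4 is None:
        return "unevaluable"
    c = cutoffs.dfg_anchor_cutoff
    if d_phe_glu4 <= c and d_phe_lys >= c:
        return "DFGin"
    if d_phe_glu4 >= c and d_phe_lys <= c:
        return "DFGout"
    return "DFGinter"


def dihedral_label(
    x_region: Optional[str],
    d_region: Optional[str],
    f_region: Optional[str],
    f_chi1_bin: Optional[str],
) -> str:
    """Concatenated label, e.g. B+L+A+minus -> ``"BLAminus"``."""
    if None in (x_region, d_region, f_region, f_chi1_bin):
        return "unevaluable"
    return f"{x_region}{d_region}{f_region}{f_chi1_bin}"


def _rama_of(ds: Optional[DihedralSet]) -> Optional[str]:
    if ds is None or ds.phi is None or ds.psi is None:
        return None
    return rama_region(ds.phi, ds.psi)


def criterion_states(
    report: GeometryReport,
    annotation: KinaseAnnotation,
    cutoffs: Optional[FamilyCutoffs] = None,
) -> tuple[str, str, str, Optional[bool]]:
    """(saltbridge, actloop_nt, actloop_ct, spine_intact) states.

    All "in" tests are strict (<); a distance exactly at the cutoff is out.
    """
    cutoffs = cutoffs or FamilyCutoffs()

    if annotation.skip_saltbridge:
        saltbridge = "skipped"
    elif report.d_saltbridge is None:
        saltbridge = "unevaluable"
    else:
        saltbridge = "in" if report.d_saltbridge < cutoffs.saltbridge_cutoff else "out"

    if report.d_actloop_nt is None:
        actloop_nt = "unevaluable"
    else:
        actloop_nt = (
            "in" if report.d_actloop_nt < cutoffs.actloop_nt_cutoff else "out"
        )

    if annotation.skip_actloopct:
        actloop_ct = "skipped"
    elif report.d_actloop_ct is None:
        actloop_ct = "unevaluable"
    else:
        ct_cutoff = (
            cutoffs.actloop_ct_cutoff_tyr
            if annotation.family == "TYR"
            else cutoffs.actloop_ct_cutoff_nontyr
        )
        actloop_ct = "in" if report.d_actloop_ct < ct_cutoff else "out"

    max_spine = report.max_spine
    spine_intact = None if max_spine is None else max_spine < cutoffs.spine_cutoff

    return saltbridge, actloop_nt, actloop_ct, spine_intact


def classify(
    chain: Sequence[ResidueRecord],
    annotation: KinaseAnnotation,
    cutoffs: Optional[FamilyCutoffs] = None,
    tip_overrides: Optional[dict[str, str]] = None,
) -> ConformationLabel:
    """Measure all observables and render the five-criterion Active verdict."""
    cutoffs = cutoffs or FamilyCutoffs()
    report = measure_geometry(chain, annotation, tip_overrides)

    spatial = spatial_label(report.d_phe_lys, report.d_phe_glu4, cutoffs)
    regions = {k: _rama_of(report.xdfg_dihedrals.get(k)) for k in ("X", "D", "F")}
    chi1_bin = None if report.phe_chi1 is None else chi1_rotamer(report.phe_chi1)
    dihedral_state = dihedral_label(
        regions["X"], regions["D"], regions["F"], chi1_bin
    )
    saltbridge, actloop_nt, actloop_ct, spine_intact = criterion_states(
        report, annotation, cutoffs
    )

    def fmt(v: Optional[float]) -> str:
        return "absent" if v is None else f"{v:.2f} Å"

    ct_cutoff = (
        cutoffs.actloop_ct_cutoff_tyr
        if annotation.family == "TYR"
        else cutoffs.actloop_ct_cutoff_nontyr
    )
    reasons = [
        f"spatial={spatial} (PheCz-LysCa {fmt(report.d_phe_lys)}, "
        f"PheCz-Glu4Ca {fmt(report.d_phe_glu4)}, cutoff "
        f"{cutoffs.dfg_anchor_cutoff:g} Å)",
        f"dihedral={dihedral_state} (X/D/F regions "
        f"{regions['X']}/{regions['D']}/{regions['F']}, chi1 bin {chi1_bin})",
        f"saltbridge={saltbridge} ({fmt(report.d_saltbridge)}, cutoff "
        f"{cutoffs.saltbridge_cutoff:g} Å)",
        f"actloop_nt={actloop_nt} ({fmt(report.d_actloop_nt)}, cutoff "
        f"{cutoffs.actloop_nt_cutoff:g} Å)",
        f"actloop_ct={actloop_ct} ({fmt(report.d_actloop_ct)}, cutoff "
        f"{ct_cutoff:g} Å)",
        f"spine_intact={spine_intact} (max spine {fmt(report.max_spine)}, "
        f"cutoff {cutoffs.spine_cutoff:g} Å; not part of the Active verdict)",
    ]

    checks = {
        "spatial": (spatial == "DFGin", spatial == "unevaluable"),
        "dihedral": (
            dihedral_state == "BLAminus",
            dihedral_state == "unevaluable",
        ),
        "saltbridge": (
            saltbridge in ("in", "skipped"),
            saltbridge == "unevaluable",
        ),
        "actloop_nt": (actloop_nt == "in", actloop_nt == "unevaluable"),
        "actloop_ct": (
            actloop_ct in ("in", "skipped"),
            actloop_ct == "unevaluable",
        ),
    }
    if any(unev for _, unev in checks.values()):
        active: Optional[bool] = None
    else:
        active = all(ok for ok, _ in checks.values())

    return ConformationLabel(
        spatial=spatial,
        dihedral=dihedral_state,
        saltbridge=saltbridge,
        actloop_nt=actloop_nt,
        actloop_ct=actloop_ct,
        spine_intact=spine_intact,
        active=active,
        reasons=reasons,
        report=report,
    )
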