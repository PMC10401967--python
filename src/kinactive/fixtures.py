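"""Synthetic kinase-like coordinate sets with fully controlled geometry.

Real kinase structures cannot be bundled with the package, and the
classifier's contract is purely geometric, so fixtures are built to order: a
backbone is grown from prescribed (φ, ψ, ω) torsions with ideal bond lengths
and angles, and the handful of atoms the criteria actually read (Lys Nζ,
Glu Oε1/Oε2, Phe Cβ/Cγ/Cζ, spine atoms, selected backbone carbonyls) are
placed analytically so that every requested observable — salt-bridge
distance, DFG6/XHRD hydrogen-bond distance, APE9 contact, DFG anchor
distances, spine distances, χ1 — is met exactly (to 1e-6 Å).

These are not stereochemically publishable structures: carbonyl oxygens of
two catalytic-loop residues are repositioned to realise hydrogen-bond
targets, and side chains are pseudo-atoms.  They exist so that the
classifier, the ranking machinery and the RMSD pipeline can be exercised
against known ground truth without downloads.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .annotation import AnnotationConfig, KinaseAnnotation, annotate_from_config
from .structure import AtomRecord, ResidueRecord, StructureModel, THREE_TO_ONE

__all__ = [
    "ConstructionError",
    "FixtureSpec",
    "IDEAL",
    "build_backbone",
    "make_kinase_fixture",
    "perturb_loop",
    "make_model_ensemble",
    "default_fixture_spec",
    "sample_regime_spec",
    "ACTIVE_GEOMETRY",
]


class ConstructionError(ValueError):
    """Mutually unsatisfiable geometry targets."""


#: ideal backbone geometry used by the torsion-space builder
IDEAL = {
    "b_n_ca": 1.458, "b_ca_c": 1.525, "b_c_n": 1.329, "b_c_o": 1.231,
    "a_n_ca_c": 111.2, "a_ca_c_n": 116.2, "a_c_n_ca": 121.7, "a_ca_c_o": 120.8,
    "b_ca_cb": 1.530, "a_n_ca_cb": 110.5, "t_c_n_ca_cb": -122.0,
    "b_cb_cg": 1.520, "a_ca_cb_cg": 114.0,
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ConstructionError("zero-length direction vector")
    return v / n


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Natural-extension placement: the point d bonded to c with
    |cd| = bond, angle(b,c,d) = angle and torsion(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(
    phi_psi_omega: Sequence[tuple[float, float, float]]
) -> list[dict[str, np.ndarray]]:
    """Grow an N/CA/C/O backbone from per-residue (φ, ψ, ω) torsions.

    ω(i) is the torsion about the C(i)–N(i+1) peptide bond.  φ of the first
    residue and ψ/ω of the last are accepted but only enter through atoms
    they can still place (the terminal carbonyl O uses the final ψ).
    Recomputing the torsions from the coordinates reproduces the inputs.
    """
    triples = [tuple(map(float, t)) for t in phi_psi_omega]
    if len(triples) < 2:
        raise ConstructionError("need at least 2 residues")
    if not all(np.isfinite(t).all() for t in map(np.asarray, triples)):
        raise ConstructionError("non-finite torsion")

    residues: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([IDEAL["b_n_ca"], 0.0, 0.0])
    ang = np.radians(180.0 - IDEAL["a_n_ca_c"])
    c0 = ca0 + IDEAL["b_ca_c"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(len(triples) - 1):
        _, psi_i, omega_i = triples[i]
        phi_next = triples[i + 1][0]
        r = residues[i]
        n_next = place_atom(
            r["N"], r["CA"], r["C"], IDEAL["b_c_n"], IDEAL["a_ca_c_n"], psi_i
        )
        ca_next = place_atom(
            r["CA"], r["C"], n_next, IDEAL["b_n_ca"], IDEAL["a_c_n_ca"], omega_i
        )
        c_next = place_atom(
            r["C"], n_next, ca_next, IDEAL["b_ca_c"], IDEAL["a_n_ca_c"], phi_next
        )
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})

    for i, r in enumerate(residues):
        psi_i = triples[i][1]
        r["O"] = place_atom(
            r["N"], r["CA"], r["C"], IDEAL["b_c_o"], IDEAL["a_ca_c_o"],
            psi_i + 180.0,
        )
    return residues


# ---------------------------------------------------------------------------
# Kinase fixture
# ---------------------------------------------------------------------------

#: geometry targets satisfying every criterion (the generator default)
ACTIVE_GEOMETRY = {
    "d_saltbridge": 3.0,
    "d_actloop_nt": 2.9,
    "d_actloop_ct": 3.5,
    "d_phe_lys": 12.0,
    "d_phe_glu4": 9.0,
    "spine1": 4.0,
    "spine2": 4.2,
    "spine3": 4.1,
    "phe_chi1": -60.0,
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic kinase chain.

    ``anchors`` maps anchor names (``beta3_lys`` … ``ape_ala``) to 0-based
    sequence ordinals; ``anchor_geometry`` gives target observables in Å
    (``phe_chi1`` in degrees) — omit a key to leave that observable
    unconstrained/absent.  ``plddt_profile`` is a constant or per-residue
    sequence written into the B-factor column.
    """

    sequence: str
    phi_psi_omega: list[tuple[float, float, float]]
    anchors: dict[str, int]
    anchor_geometry: dict[str, float] = field(default_factory=dict)
    plddt_profile: Union[float, Sequence[float]] = 90.0
    family: str = "CAMK"
    gene_label: str = "CAMK_SYNTH1"
    entry_id: str = "SYNTH"
    seed: int = 0
    loop_includes_motifs: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.phi_psi_omega):
            raise ConstructionError(
                "sequence length and dihedral list length differ"
            )
        for key, value in self.anchor_geometry.items():
            if key != "phe_chi1" and value <= 0:
                raise ConstructionError(f"target {key!r} must be > 0")


def default_fixture_spec(
    geometry: Optional[dict[str, float]] = None,
    family: str = "CAMK",
    gene_label: str = "CAMK_SYNTH1",
    plddt_profile: Union[float, Sequence[float]] = 90.0,
    dihedral_overrides: Optional[dict[int, tuple[float, float, float]]] = None,
) -> FixtureSpec:
    """A 100-residue kinase-like chain with motifs at fixed ordinals.

    Layout (0-based ordinals): β3 Lys 18, C-helix Glu 24 (Glu4 28), HPN
    34–36 (HPN7 40), XHRD 59, HRD 60–62, XDFG 69, DFG 70–72, DFG6 75,
    APE 90–92 (APE9 84); activation loop 70–92 (23 residues).  The XDFG
    torsions default to the B/L/A basins, residues 10–32 form a helical
    block (so the two DFG anchor Cα atoms are mutually reachable), and the
    rest of the chain is an extended strand.  The default geometry
    classifies as Active.
    """
    seq = list("A" * 100)
    anchors = {
        "beta3_lys": 18, "chelix_glu": 24, "hpn_his": 34,
        "hrd_his": 60, "dfg_asp": 70, "ape_ala": 90,
    }
    seq[18] = "K"
    seq[24] = "E"
    seq[28] = "L"          # Glu4
    seq[34:37] = "HPN"
    seq[40] = "L"          # HPN7
    seq[59] = "V"          # XHRD
    seq[60:63] = "HRD"
    seq[69] = "T"          # XDFG
    seq[70:73] = "DFG"
    seq[75] = "K"          # DFG6
    seq[84] = "G"          # APE9
    seq[90:93] = "APE"

    strand = (-120.0, 130.0, 180.0)
    helix = (-57.0, -47.0, 180.0)
    torsions = [strand] * 100
    # a compact helical N-lobe block keeps the β3-Lys and Glu4 Cα atoms
    # within range of jointly satisfiable DFG anchor-distance targets
    torsions[10:33] = [helix] * 23
    # XDFG basins: X in B (beta), D in L (left-handed), F in A (alpha)
    torsions[69] = (-119.0, 137.0, 180.0)
    torsions[70] = (57.0, 39.0, 180.0)
    torsions[71] = (-63.0, -43.0, 180.0)
    torsions[72] = (-80.0, 120.0, 180.0)
    if dihedral_overrides:
        for ordinal, triple in dihedral_overrides.items():
            torsions[ordinal] = triple

    target = dict(ACTIVE_GEOMETRY)
    if geometry:
        target.update(geometry)
    return FixtureSpec(
        sequence="".join(seq),
        phi_psi_omega=torsions,
        anchors=anchors,
        anchor_geometry=target,
        plddt_profile=plddt_profile,
        family=family,
        gene_label=gene_label,
    )


def sample_regime_spec(
    rng: np.random.Generator,
) -> tuple[FixtureSpec, dict[str, object]]:
    """Draw a random fixture spanning in/out regimes of every criterion.

    Each criterion's regime (in or out, with values sampled away from the
    cutoff) is drawn independently, together with the kinase family (which
    switches the ActLoopCT cutoff) and the dihedral regime (the canonical
    B/L/A basins with a gauche− χ1, or a perturbed X-basin / χ1 bin).
    Returns the spec and the intended per-criterion states.
    """
    family = str(rng.choice(["AGC", "CAMK", "CMGC", "STE", "TKL", "TYR"]))

    sb_in = bool(rng.integers(2))
    d_sb = float(rng.uniform(2.6, 3.4) if sb_in else rng.uniform(4.0, 9.0))

    nt_in = bool(rng.integers(2))
    d_nt = float(rng.uniform(2.6, 3.4) if nt_in else rng.uniform(4.0, 8.0))

    ct_in = bool(rng.integers(2))
    if family == "TYR":
        d_ct = float(rng.uniform(3.2, 7.7) if ct_in else rng.uniform(8.4, 12.0))
    else:
        d_ct = float(rng.uniform(3.2, 5.7) if ct_in else rng.uniform(6.4, 12.0))

    spatial = str(rng.choice(["DFGin", "DFGout", "DFGinter"]))
    near = lambda: float(rng.uniform(8.6, 10.6))   # noqa: E731
    far = lambda: float(rng.uniform(11.4, 14.0))   # noqa: E731
    if spatial == "DFGin":
        d_lys, d_glu4 = far(), near()
    elif spatial == "DFGout":
        d_lys, d_glu4 = near(), far()
    elif rng.integers(2):
        d_lys, d_glu4 = near(), near()
    else:
        d_lys, d_glu4 = far(), far()

    spine_in = bool(rng.integers(2))
    spines = (
        rng.uniform(3.2, 4.7, 3) if spine_in else rng.uniform(5.4, 8.0, 3)
    )

    dihedral_regime = str(rng.choice(["blaminus", "x_in_a", "chi1_plus"]))
    chi1 = float(rng.uniform(-100.0, -20.0))
    overrides = None
    expected_dihedral_is_bla = dihedral_regime == "blaminus"
    if dihedral_regime == "x_in_a":
        overrides = {69: (-63.0, -43.0, 180.0)}  # X slips into the α basin
    elif dihedral_regime == "chi1_plus":
        chi1 = float(rng.uniform(20.0, 100.0))

    spec = default_fixture_spec(
        geometry={
            "d_saltbridge": d_sb, "d_actloop_nt": d_nt, "d_actloop_ct": d_ct,
            "d_phe_lys": d_lys, "d_phe_glu4": d_glu4,
            "spine1": float(spines[0]), "spine2": float(spines[1]),
            "spine3": float(spines[2]), "phe_chi1": chi1,
        },
        family=family,
        gene_label=f"{family}_SYNTH1",
        dihedral_overrides=overrides,
    )
    expected = {
        "spatial": spatial,
        "dihedral_is_blaminus": expected_dihedral_is_bla,
        "saltbridge": "in" if sb_in else "out",
        "actloop_nt": "in" if nt_in else "out",
        "actloop_ct": "in" if ct_in else "out",
        "spine_intact": spine_in,
        "active": (spatial == "DFGin" and expected_dihedral_is_bla
                   and sb_in and nt_in and ct_in),
    }
    return spec, expected


def _candidate_directions(n: int = 64) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden spiral)."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _place_min_distance(points: list[np.ndarray], dist: float,
                        label: str) -> np.ndarray:
    """A point whose minimum distance to ``points`` equals ``dist``.

    The point is placed at ``dist`` from one member along a direction with
    non-positive projection onto every other member, which guarantees all
    remaining distances are >= ``dist``.
    """
    for base in points:
        others = [p - base for p in points if p is not base]
        if others:
            first = -sum(_unit(o) for o in others)
            candidates = [first] if np.linalg.norm(first) > 1e-9 else []
        else:
            candidates = [np.array([0.0, 0.0, 1.0])]
        candidates = list(candidates) + list(_candidate_directions())
        for cand in candidates:
            u = _unit(np.asarray(cand, float))
            if all(np.dot(o, u) <= 1e-9 for o in others):
                return base + dist * u
    raise ConstructionError(f"cannot realise minimum-distance target {label!r}")


def _sphere_intersection(center_a, r_a, center_b, r_b,
                         labels: tuple[str, str]) -> np.ndarray:
    """Deterministic point at distance r_a from A and r_b from B."""
    center_a = np.asarray(center_a, float)
    center_b = np.asarray(center_b, float)
    d = float(np.linalg.norm(center_b - center_a))
    if d < 1e-9:
        raise ConstructionError(
            f"anchors for {labels[0]!r}/{labels[1]!r} coincide"
        )
    if d > r_a + r_b or d < abs(r_a - r_b):
        raise ConstructionError(
            f"targets {labels[0]!r} = {r_a:g} and {labels[1]!r} = {r_b:g} "
            f"violate the triangle inequality with anchor separation {d:.2f} Å"
        )
    u = (center_b - center_a) / d
    a = (d * d + r_a * r_a - r_b * r_b) / (2.0 * d)
    h = float(np.sqrt(max(0.0, r_a * r_a - a * a)))
    axis = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, axis)) > 0.9:
        axis = np.array([0.0, 1.0, 0.0])
    v = _unit(np.cross(u, axis))
    return center_a + a * u + h * v


def _atom(name: str, pos: np.ndarray, element: str = "C",
          b: float = 0.0) -> AtomRecord:
    return AtomRecord(name=name, element=element, position=np.asarray(pos, float),
                      b_factor=b)


def make_kinase_fixture(
    spec: FixtureSpec,
) -> tuple[StructureModel, KinaseAnnotation]:
    """Build a synthetic kinase chain realising the spec's geometry targets.

    Raises :class:`ConstructionError` when targets are mutually
    unsatisfiable (naming the conflicting pair).  The returned annotation is
    consistent with the placed motifs, including family exception flags
    derived from ``gene_label``.
    """
    backbone = build_backbone(spec.phi_psi_omega)
    n_res = len(spec.sequence)
    geometry = spec.anchor_geometry
    anchors = spec.anchors

    def ordinal(name: str) -> Optional[int]:
        return anchors.get(name)

    i_lys = ordinal("beta3_lys")
    i_glu = ordinal("chelix_glu")
    i_hpn = ordinal("hpn_his")
    i_hrd = anchors["hrd_his"]
    i_dfg = anchors["dfg_asp"]
    i_ape = ordinal("ape_ala")
    i_glu4 = None if i_glu is None else i_glu + 4
    i_hpn7 = None if i_hpn is None else i_hpn + 6
    i_xhrd, i_hrd_r = i_hrd - 1, i_hrd + 1
    i_dfg_f, i_dfg6 = i_dfg + 1, i_dfg + 5
    i_ape9 = None if i_ape is None else i_ape + 2 - 8

    extra: dict[int, list[AtomRecord]] = {}

    def add(i: int, atom: AtomRecord) -> None:
        extra.setdefault(i, []).append(atom)

    # --- DFG-Phe side chain: CB/CG realise chi1, CZ the anchor distances
    bb_f = backbone[i_dfg_f]
    cb = place_atom(bb_f["C"], bb_f["N"], bb_f["CA"], IDEAL["b_ca_cb"],
                    IDEAL["a_n_ca_cb"], IDEAL["t_c_n_ca_cb"])
    chi1 = geometry.get("phe_chi1")
    cg = None
    if chi1 is not None:
        cg = place_atom(bb_f["N"], bb_f["CA"], cb, IDEAL["b_cb_cg"],
                        IDEAL["a_ca_cb_cg"], chi1)
    add(i_dfg_f, _atom("CB", cb))
    if cg is not None:
        add(i_dfg_f, _atom("CG", cg))

    cz = None
    if "d_phe_lys" in geometry and "d_phe_glu4" in geometry:
        if i_lys is None or i_glu4 is None:
            raise ConstructionError(
                "DFG anchor distances need beta3_lys and chelix_glu anchors"
            )
        cz = _sphere_intersection(
            backbone[i_lys]["CA"], geometry["d_phe_lys"],
            backbone[i_glu4]["CA"], geometry["d_phe_glu4"],
            ("d_phe_lys", "d_phe_glu4"),
        )
        add(i_dfg_f, _atom("CZ", cz))

    # --- salt bridge: Nζ off the Lys CA, Oε1 at the target distance
    if "d_saltbridge" in geometry:
        if i_lys is None or i_glu is None:
            raise ConstructionError(
                "d_saltbridge needs beta3_lys and chelix_glu anchors"
            )
        t = geometry["d_saltbridge"]
        nz = backbone[i_lys]["CA"] + 1.5 * _unit(
            backbone[i_lys]["CA"] - backbone[i_lys]["N"]
        )
        u = _unit(backbone[i_glu]["CA"] - nz)
        oe1 = nz + t * u
        oe2 = nz + (t + 1.0) * u
        add(i_lys, _atom("NZ", nz, element="N"))
        add(i_glu, _atom("OE1", oe1, element="O"))
        add(i_glu, _atom("OE2", oe2, element="O"))

    # --- ActLoopNT: reposition the XHRD carbonyl O onto the target sphere,
    #     keeping the alternative O(DFG6)-N(XHRD) pairing at least as long
    if "d_actloop_nt" in geometry:
        t = geometry["d_actloop_nt"]
        n_dfg6 = backbone[i_dfg6]["N"]
        u = _unit(backbone[i_xhrd]["O"] - n_dfg6)
        backbone[i_xhrd]["O"] = n_dfg6 + t * u
        n_xhrd = backbone[i_xhrd]["N"]
        alt = float(np.linalg.norm(backbone[i_dfg6]["O"] - n_xhrd))
        if alt < t:
            v = _unit(backbone[i_dfg6]["O"] - n_xhrd)
            backbone[i_dfg6]["O"] = n_xhrd + (t + 0.5) * v

    # --- ActLoopCT: reposition the HRD-Arg carbonyl O
    if "d_actloop_ct" in geometry:
        if i_ape9 is None:
            raise ConstructionError("d_actloop_ct needs the ape_ala anchor")
        t = geometry["d_actloop_ct"]
        ca9 = backbone[i_ape9]["CA"]
        u = _unit(backbone[i_hrd_r]["O"] - ca9)
        backbone[i_hrd_r]["O"] = ca9 + t * u

    # --- regulatory spine pseudo-atoms
    dfg_f_sidechain = [cb] + ([cg] if cg is not None else []) \
        + ([cz] if cz is not None else [])
    if "spine1" in geometry:
        s_h = _place_min_distance(dfg_f_sidechain, geometry["spine1"], "spine1")
        add(i_hrd, _atom("CG", s_h))
    s_g = None
    if "spine2" in geometry:
        if i_glu4 is None:
            raise ConstructionError("spine2 needs the chelix_glu anchor")
        s_g = _place_min_distance(dfg_f_sidechain, geometry["spine2"], "spine2")
        add(i_glu4, _atom("CG", s_g))
    if "spine3" in geometry:
        if s_g is None or i_hpn7 is None:
            raise ConstructionError(
                "spine3 needs spine2 and the hpn_his anchor"
            )
        s_p = s_g + geometry["spine3"] * np.array([0.0, 0.0, 1.0])
        if abs(np.linalg.norm(s_p - s_g) - geometry["spine3"]) > 1e-9:
            raise ConstructionError("spine3 placement failed")
        add(i_hpn7, _atom("CG", s_p))

    # --- assemble residues with the pLDDT profile in the B-factor column
    if np.isscalar(spec.plddt_profile):
        plddt = np.full(n_res, float(spec.plddt_profile))  # type: ignore[arg-type]
    else:
        plddt = np.asarray(spec.plddt_profile, float)
        if plddt.shape != (n_res,):
            raise ConstructionError("plddt_profile length mismatch")

    residues = []
    for i in range(n_res):
        aa1 = spec.sequence[i]
        rec = ResidueRecord(
            chain_id="A", seq_num=i + 1, insertion_code="",
            aa3=ONE_TO_THREE.get(aa1, "ALA"), aa1=aa1,
        )
        for name in ("N", "CA", "C", "O"):
            element = name[0]
            rec.atoms.append(
                _atom(name, backbone[i][name], element=element, b=plddt[i])
            )
        for atom in extra.get(i, []):
            atom.b_factor = plddt[i]
            rec.atoms.append(atom)
        residues.append(rec)

    structure = StructureModel(
        entry_id=spec.entry_id, chains={"A": residues},
        source_format="synthetic", is_model=True,
    )

    config = AnnotationConfig(
        gene_label=spec.gene_label,
        family=spec.family,
        anchors={
            name: anchors[name] + 1
            for name in ("beta3_lys", "chelix_glu", "hpn_his",
                         "hrd_his", "dfg_asp", "ape_ala")
            if name in anchors
        },
        loop_includes_motifs=spec.loop_includes_motifs,
    )
    annotation = annotate_from_config(residues, config)
    _verify_targets(residues, annotation, geometry)
    return structure, annotation


def _verify_targets(chain, annotation, geometry: dict[str, float]) -> None:
    """Generator/measurer cross-validation: every requested target must be
    reproduced by the measurement code within 1e-6 Å (1e-6° for chi1)."""
    from .classify import measure_geometry  # local import: avoid cycle

    report = measure_geometry(chain, annotation)
    observed = {
        "d_saltbridge": report.d_saltbridge,
        "d_actloop_nt": report.d_actloop_nt,
        "d_actloop_ct": report.d_actloop_ct,
        "d_phe_lys": report.d_phe_lys,
        "d_phe_glu4": report.d_phe_glu4,
        "spine1": report.spine1,
        "spine2": report.spine2,
        "spine3": report.spine3,
        "phe_chi1": report.phe_chi1,
    }
    both_anchors = "d_phe_lys" in geometry and "d_phe_glu4" in geometry
    for key, target in geometry.items():
        if key in ("d_phe_lys", "d_phe_glu4") and not both_anchors:
            continue  # the tip atom is only placed when both are constrained
        got = observed.get(key)
        if got is None or abs(got - target) > 1e-6:
            raise ConstructionError(
                f"target {key!r} = {target:g} not realised (measured {got})"
            )


def perturb_loop(
    structure: StructureModel,
    annotation: KinaseAnnotation,
    sigma: float,
    seed: int = 0,
) -> StructureModel:
    """Gaussian displacement (std ``sigma`` per coordinate, Å) of all atoms
    of the activation-loop residues; the rest of the chain is untouched."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(structure)
    loop = set(annotation.loop_ordinals())
    for residues in out.chains.values():
        polymer = [r for r in residues if not r.is_hetero]
        for i, res in enumerate(polymer):
            if i in loop:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(0.0, sigma, 3)
    return out


def make_model_ensemble(
    base_spec: FixtureSpec,
    n_models: int,
    plddt_rmsd_coupling: float = 1.0,
    seed: int = 0,
) -> list[StructureModel]:
    """Seeded ensemble of models with loop error coupled to loop pLDDT.

    Per-model loop perturbations use a geometric ladder of sigmas from 0.2
    to 2.0 Å (shuffled per seed) so error levels are distinct; the loop
    pLDDT is set to 95 − 20·σ plus Gaussian noise of
    std 30·(1 − coupling).  At coupling 1 the pLDDT ordering is exactly the
    inverse of the σ ordering; at coupling 0 it is uninformative.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    if not 0.0 <= plddt_rmsd_coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sigmas = np.geomspace(0.2, 2.0, n_models)
    rng.shuffle(sigmas)
    noise_sd = 30.0 * (1.0 - plddt_rmsd_coupling)

    base_structure, annotation = make_kinase_fixture(base_spec)
    loop = list(annotation.loop_ordinals())
    models = []
    for i, sigma in enumerate(sigmas):
        model = perturb_loop(
            base_structure, annotation, float(sigma),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model.entry_id = f"model_{i:03d}"
        model.is_model = True
        loop_plddt = float(
            np.clip(95.0 - 20.0 * sigma + rng.normal(0.0, noise_sd), 1.0, 99.0)
        )
        for residues in model.chains.values():
            polymer = [r for r in residues if not r.is_hetero]
            for j in loop:
                for atom in polymer[j].atoms:
                    atom.b_factor = loop_plddt
        models.append(model)
    return models
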