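"""Geometric primitives: distances, torsions, Ramachandran/χ1 binning,
Kabsch superposition, RMSD.

Angle conventions: all torsions are signed IUPAC torsions in degrees wrapped
to (−180, 180] (cis = 0, trans = ±180 reported as +180).  Region tests use
half-open intervals so every (φ, ψ) point receives exactly one label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "DihedralSet",
    "RigidTransform",
    "distance",
    "dihedral",
    "wrap_angle",
    "rama_region",
    "chi1_rotamer",
    "kabsch_superpose",
    "rmsd_no_fit",
    "default_rama_regions",
    "CHI1_GAMMA_ATOM",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear torsion, underdetermined fit, ...)."""


@dataclass
class DihedralSet:
    """Backbone (φ, ψ) and side-chain χ1 torsions of one residue, degrees."""

    phi: Optional[float]
    psi: Optional[float]
    chi1: Optional[float] = None


@dataclass
class RigidTransform:
    """Proper rotation + translation: y = R·x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise GeometryError("rotation determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance in Å."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    wrapped = ((float(deg) + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, (−180, 180], cis = 0."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise GeometryError("central torsion atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear atoms in torsion")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # minus sign: IUPAC right-handed convention (clockwise positive when
    # viewed from p2 towards p3)
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# Ramachandran regions and χ1 rotamer bins
# ---------------------------------------------------------------------------

def default_rama_regions() -> dict:
    """Packaged default region partition (overridable via JSON config)."""
    with resources.files("kinactive.data").joinpath("rama_regions.json").open() as fh:
        return json.load(fh)


def rama_region(phi: float, psi: float, regions: Optional[dict] = None) -> str:
    """Assign one of the labels B (beta), A (alpha), L (left-handed), E.

    The default partition is rectangular and total: for φ < 0 the β basin is
    ψ ≥ 50 or ψ < −120 and the α basin is −120 ≤ ψ < 50; for φ ≥ 0 the
    left-handed basin is −50 ≤ ψ < 100 and everything else is E.  Boundaries
    are half-open so every grid point gets exactly one label.  Exact basin
    outlines of the Kincore reference labelling differ slightly; substitute
    them via ``regions`` when replicating its sublabels.
    """
    regions = regions if regions is not None else _RAMA_DEFAULT
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    # phi = 180 belongs with the phi >= 0 half-plane by the wrap convention
    if phi < regions["phi_split"]:
        lo, hi = regions["alpha_psi"]
        return "A" if lo <= psi < hi else "B"
    lo, hi = regions["left_psi"]
    return "L" if lo <= psi < hi else "E"


def chi1_rotamer(chi1: float, edges: Sequence[float] = (-120.0, 0.0, 120.0)) -> str:
    """Bin a χ1 torsion into the staggered wells.

    gauche− ("minus", ~ −60°) for χ1 ∈ [−120, 0); gauche+ ("plus", ~ +60°)
    for [0, 120); "trans" (~180°) otherwise.
    """
    chi1 = wrap_angle(chi1)
    g_minus, zero, g_plus = edges
    if g_minus <= chi1 < zero:
        return "minus"
    if zero <= chi1 < g_plus:
        return "plus"
    return "trans"


#: per-residue gamma heavy atom completing the N-CA-CB-G χ1 path
CHI1_GAMMA_ATOM = {
    "ILE": "CG1", "VAL": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
    "ALA": None, "GLY": None,
}


def chi1_path_atoms(aa3: str) -> Optional[tuple[str, str, str, str]]:
    """Atom names for χ1 of a residue type, or None (Gly/Ala: no χ1)."""
    gamma = CHI1_GAMMA_ATOM.get(aa3, "CG")
    if gamma is None:
        return None
    return ("N", "CA", "CB", gamma)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper superposition of paired point sets.

    Returns the rigid transform mapping ``mobile`` onto ``reference`` and
    the RMSD of the fitted points.  SVD with determinant correction, so
    reflections are never returned.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must be matched (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")

    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # rank-deficient H with a reflective optimum => degenerate configuration
    if s[1] < 1e-12:
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    fitted = x @ rot.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return RigidTransform(rot, trans), rmsd


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between already-superposed matched point sets (no refitting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError("point sets must be matched (n, 3) arrays")
    if a.shape[0] < 1:
        raise GeometryError("need at least one point")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


_RAMA_DEFAULT = {
    "phi_split": 0.0,
    "alpha_psi": [-120.0, 50.0],
    "left_psi": [-50.0, 100.0],
}
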