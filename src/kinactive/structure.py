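"""Minimal hierarchical structure model and PDB/mmCIF reading.

The classifier needs very little from a coordinate file: residue identity in
author numbering, heavy-atom coordinates, and the B-factor column (which holds
the per-residue pLDDT in predicted models).  Parsing is delegated to gemmi;
this module flattens its hierarchy into plain dataclasses so the rest of the
package never touches a parser object.

Only the first model of a multi-model file is read.  Hydrogens are dropped on
input: every geometric criterion in this package is defined on heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureError",
    "ChainLookupError",
    "read_structure",
    "select_chain",
    "get_atom",
    "write_pdb",
    "chain_sequence",
]

#: three-letter -> one-letter translation for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(Exception):
    """Raised for unreadable or malformed structure files."""


class ChainLookupError(KeyError):
    """Raised when a requested chain id is absent from a structure."""


@dataclass
class AtomRecord:
    """One heavy atom: PDB-convention name, element, position (Å), B-factor.

    For AlphaFold-style model files the B-factor column carries the
    per-residue pLDDT (0-100) and is exposed unrescaled.
    """

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.name!r}: position must be a finite 3-vector"
            )
        if self.b_factor < 0:
            raise StructureError(f"atom {self.name!r}: negative B-factor")


@dataclass
class ResidueRecord:
    """One residue keyed by (chain_id, author seq_num, insertion_code)."""

    chain_id: str
    seq_num: int
    insertion_code: str
    aa3: str
    aa1: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_num, self.insertion_code)

    def __str__(self) -> str:  # e.g. "A:179" or "A:179A"
        return f"{self.chain_id}:{self.seq_num}{self.insertion_code}"


@dataclass
class StructureModel:
    """All chains of the first model of one entry.

    ``is_model`` distinguishes predicted models (B-factor = pLDDT) from
    experimental structures; pLDDT-dependent operations refuse the latter.
    """

    entry_id: str
    chains: dict[str, list[ResidueRecord]]
    source_format: str  # "pdb" | "mmcif" | "synthetic"
    resolution: Optional[float] = None
    is_model: bool = False

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)


def _convert_residue(chain_id: str, res: gemmi.Residue) -> ResidueRecord:
    aa3 = res.name.strip().upper()
    rec = ResidueRecord(
        chain_id=chain_id,
        seq_num=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        aa3=aa3,
        aa1=THREE_TO_ONE.get(aa3, "X"),
        is_hetero=res.het_flag == "H",
    )
    for atom in res:
        if atom.is_hydrogen():
            continue
        rec.atoms.append(
            AtomRecord(
                name=atom.name,
                element=atom.element.name,
                position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                b_factor=max(atom.b_iso, 0.0),
                occupancy=atom.occ,
                alt_loc=(atom.altloc or "").strip(),
            )
        )
    return rec


def read_structure(
    path: str | Path,
    format: str = "auto",
    is_model: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content).
    is_model:
        Mark the structure as a predicted model whose B-factor column is a
        pLDDT.  Never inferred: callers that rank models must say so.

    Only model 1 of a multi-model file is read (a warning is logged when more
    are present).  Alternate locations are retained; reduction happens in
    :func:`select_chain`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")

    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r} (pdb, mmcif, auto)")

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models present")
    if len(st) > 1:
        logger.warning("%s: %d models present; reading model 1 only", path, len(st))

    model = st[0]
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        residues = [_convert_residue(chain.name, res) for res in chain]
        residues.sort(key=lambda r: (r.seq_num, r.insertion_code))
        chains[chain.name] = residues

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        entry_id=st.name or path.stem,
        chains=chains,
        source_format=fmt,
        resolution=resolution,
        is_model=is_model,
    )


def _reduce_alt_locs(residue: ResidueRecord) -> ResidueRecord:
    """Keep one atom per name: highest occupancy, ties by alt-loc id."""
    by_name: dict[str, AtomRecord] = {}
    for atom in residue.atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occupancy, _altloc_rank(atom)) > (
            prev.occupancy,
            _altloc_rank(prev),
        ):
            by_name[atom.name] = atom
    reduced = ResidueRecord(
        chain_id=residue.chain_id,
        seq_num=residue.seq_num,
        insertion_code=residue.insertion_code,
        aa3=residue.aa3,
        aa1=residue.aa1,
        atoms=list(by_name.values()),
        is_hetero=residue.is_hetero,
    )
    return reduced


def _altloc_rank(atom: AtomRecord) -> int:
    # alphabetically earlier alt-loc wins a tie -> higher rank
    return -ord(atom.alt_loc) if atom.alt_loc else 0


def select_chain(structure: StructureModel, chain_id: str) -> list[ResidueRecord]:
    """Return one chain with alternate locations deterministically reduced.

    Per atom name the highest-occupancy alt-loc is kept; ties go to the
    alphabetically first alt-loc id.
    """
    if chain_id not in structure.chains:
        raise ChainLookupError(
            f"chain {chain_id!r} not in {structure.entry_id}; "
            f"available: {structure.chain_ids}"
        )
    return [_reduce_alt_locs(r) for r in structure.chains[chain_id]]


def get_atom(residue: ResidueRecord, name: str) -> Optional[AtomRecord]:
    """Return the named atom after alt-loc reduction, or ``None``.

    Absence is a value: criteria treat a missing atom as unevaluable, never
    as a failed criterion.
    """
    candidates = [a for a in residue.atoms if a.name == name]
    if not candidates:
        return None
    return max(candidates, key=lambda a: (a.occupancy, _altloc_rank(a)))


def chain_sequence(chain: Iterable[ResidueRecord]) -> str:
    """One-letter sequence of the polymer residues of a chain."""
    return "".join(r.aa1 for r in chain if not r.is_hetero)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (fixture support; not a general exporter)."""
    lines: list[str] = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name column convention: pad 1-letter elements
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.position
                lines.append(
                    f"{record}{serial:>5d} {name_field}{atom.alt_loc or ' '}"
                    f"{res.aa3:>3s} {chain_id:1s}{res.seq_num:>4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
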