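"""Shared fixtures: tiny hand-written coordinate files and synthetic chains."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kinactive.fixtures import default_fixture_spec, make_kinase_fixture

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from kinactive.structure import ResidueRecord

# one small coordinate table serialized both as PDB and as mmCIF
_ATOMS = [
    # (resnum, resname, atom, element, x, y, z, occ, b, altloc)
    (1, "ALA", "N", "N", 0.000, 0.000, 0.000, 1.00, 10.00, ""),
    (1, "ALA", "CA", "C", 1.458, 0.000, 0.000, 1.00, 11.00, ""),
    (1, "ALA", "C", "C", 2.009, 1.420, 0.000, 1.00, 12.00, ""),
    (2, "PHE", "N", "N", 3.332, 1.536, 0.000, 1.00, 13.00, ""),
    (2, "PHE", "CA", "C", 4.021, 2.801, 0.210, 1.00, 14.00, ""),
    (2, "PHE", "CZ", "C", 6.500, 3.100, 1.750, 1.00, 15.00, ""),
    (3, "GLY", "N", "N", 5.321, 2.771, 0.310, 1.00, 16.00, ""),
    (3, "GLY", "CA", "C", 6.100, 3.962, 0.420, 1.00, 17.00, ""),
]


def _pdb_line(serial, resnum, resname, atom, element, x, y, z, occ, b, alt):
    name_field = f" {atom:<3s}" if len(atom) < 4 else atom
    return (
        f"ATOM  {serial:>5d} {name_field}{alt or ' '}{resname:>3s} A"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def _as_pdb(atoms) -> str:
    lines = [_pdb_line(i + 1, *row) for i, row in enumerate(atoms)]
    return "\n".join(lines + ["TER", "END"]) + "\n"


def _as_mmcif(atoms) -> str:
    header = """data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
"""
    rows = []
    for i, (num, res, atom, el, x, y, z, occ, b, alt) in enumerate(atoms):
        rows.append(
            f"ATOM {i + 1} {el} {atom} {alt or '.'} {res} A {num} ? "
            f"{x:.3f} {y:.3f} {z:.3f} {occ:.2f} {b:.2f} {num} {res} A {atom} 1"
        )
    return header + "\n".join(rows) + "\n"


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(_as_pdb(_ATOMS))
    return path


@pytest.fixture
def mmcif_file(tmp_path):
    path = tmp_path / "mini.cif"
    path.write_text(_as_mmcif(_ATOMS))
    return path


@pytest.fixture
def altloc_pdb_file(tmp_path):
    atoms = list(_ATOMS[:3])
    atoms.append((1, "ALA", "CB", "C", 1.900, -1.100, 0.900, 0.60, 12.0, "A"))
    atoms.append((1, "ALA", "CB", "C", 1.950, -1.050, 0.850, 0.40, 12.0, "B"))
    path = tmp_path / "altloc.pdb"
    path.write_text(_as_pdb(atoms))
    return path


@pytest.fixture
def multimodel_pdb_file(tmp_path):
    body = _as_pdb(_ATOMS).replace("TER\nEND\n", "TER\n")
    shifted = [(n, r, a, e, x + 5.0, y, z, o, b, al)
               for (n, r, a, e, x, y, z, o, b, al) in _ATOMS]
    body2 = _as_pdb(shifted).replace("TER\nEND\n", "TER\n")
    text = "MODEL        1\n" + body + "ENDMDL\nMODEL        2\n" \
        + body2 + "ENDMDL\nEND\n"
    path = tmp_path / "multi.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def active_fixture():
    """Default synthetic kinase in the fully active geometry."""
    spec = default_fixture_spec()
    structure, annotation = make_kinase_fixture(spec)
    return spec, structure, annotation


def bare_chain(sequence: str, chain_id: str = "A", offset: int = 1
               ) -> list[ResidueRecord]:
    """Atom-less chain for annotation arithmetic tests."""
    from kinactive.structure import THREE_TO_ONE

    three = {v: k for k, v in THREE_TO_ONE.items()}
    return [
        ResidueRecord(chain_id=chain_id, seq_num=i + offset, insertion_code="",
                      aa3=three.get(aa, "ALA"), aa1=aa)
        for i, aa in enumerate(sequence)
    ]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_structure(structure, rotation, translation):
    """Rigidly move every atom of a StructureModel (deep copy)."""
    import copy

    out = copy.deepcopy(structure)
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.position = rotation @ atom.position + translation
    return out
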