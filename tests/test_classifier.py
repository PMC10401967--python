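"""Criterion states, the Active verdict, and its invariances."""

import numpy as np
import pytest

from kinactive.classify import (
    FamilyCutoffs,
    classify,
    criterion_states,
    dihedral_label,
    measure_geometry,
    spatial_label,
)
from kinactive.fixtures import default_fixture_spec, make_kinase_fixture
from kinactive.structure import get_atom

from conftest import random_rotation, transform_structure


# ---------------------------------------------------------------------------
# label operations on explicit values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d_lys,d_glu4,expected",
    [
        (12.0, 9.0, "DFGin"),
        (9.0, 14.0, "DFGout"),
        (9.0, 9.0, "DFGinter"),
        (14.0, 14.0, "DFGinter"),
        (None, 9.0, "unevaluable"),
        (12.0, None, "unevaluable"),
    ],
)
def test_spatial_label(d_lys, d_glu4, expected):
    assert spatial_label(d_lys, d_glu4) == expected


def test_spatial_label_exact_boundary_prefers_dfgin():
    assert spatial_label(11.0, 11.0) == "DFGin"


@pytest.mark.parametrize(
    "regions,expected",
    [
        (("B", "L", "A", "minus"), "BLAminus"),
        (("A", "B", "A", "minus"), "ABAminus"),
        (("B", "L", "A", "plus"), "BLAplus"),
        (("E", "L", "A", "trans"), "ELAtrans"),
        (("B", None, "A", "minus"), "unevaluable"),
        (("B", "L", "A", None), "unevaluable"),
    ],
)
def test_dihedral_label_concatenation(regions, expected):
    assert dihedral_label(*regions) == expected


# ---------------------------------------------------------------------------
# measured observables on hand-built residues
# ---------------------------------------------------------------------------

def test_saltbridge_uses_nearest_carboxylate_oxygen(active_fixture):
    spec, _, annotation = active_fixture
    spec2 = default_fixture_spec()
    structure, ann = make_kinase_fixture(spec2)
    chain = structure.chains["A"]
    lys = chain[ann.beta3_lys]
    glu = chain[ann.chelix_glu]
    nz = get_atom(lys, "NZ").position
    # move OE1 to exactly 3.0 and OE2 to 5.0 from NZ
    u = np.array([1.0, 0.0, 0.0])
    get_atom(glu, "OE1").position = nz + 3.0 * u
    get_atom(glu, "OE2").position = nz + 5.0 * u
    report = measure_geometry(chain, ann)
    assert report.d_saltbridge == pytest.approx(3.0, abs=1e-9)


def test_actloop_nt_takes_minimum_of_both_pairings(active_fixture):
    structure, ann = make_kinase_fixture(default_fixture_spec())
    chain = structure.chains["A"]
    dfg6 = chain[ann.dfg6]
    xhrd = chain[ann.xhrd]
    n6 = get_atom(dfg6, "N").position
    get_atom(xhrd, "O").position = n6 + np.array([2.9, 0.0, 0.0])
    # make the other pairing clearly longer
    get_atom(dfg6, "O").position = get_atom(xhrd, "N").position + np.array(
        [5.0, 0.0, 0.0]
    )
    report = measure_geometry(chain, ann)
    assert report.d_actloop_nt == pytest.approx(2.9, abs=1e-9)


@pytest.mark.parametrize(
    "distance,family,expected",
    [
        (3.0, "AGC", "in"),
        (7.3, "TYR", "in"),   # inside the wider Tyr-kinase cutoff
        (7.3, "AGC", "out"),
        (9.0, "TYR", "out"),
    ],
)
def test_actloopct_family_specific_cutoffs(distance, family, expected):
    spec = default_fixture_spec(
        geometry={"d_actloop_ct": distance},
        family=family, gene_label=f"{family}_SYNTH1",
    )
    structure, ann = make_kinase_fixture(spec)
    report = measure_geometry(structure.chains["A"], ann)
    _, _, actloop_ct, _ = criterion_states(report, ann)
    assert actloop_ct == expected


def test_distances_exactly_at_cutoff_are_out(active_fixture):
    # all "in" tests are strict: a distance equal to its cutoff fails
    from kinactive.classify import GeometryReport

    _, _, ann = active_fixture
    report = GeometryReport(d_saltbridge=3.6, d_actloop_nt=3.6,
                            d_actloop_ct=6.0)
    saltbridge, actloop_nt, actloop_ct, _ = criterion_states(report, ann)
    assert (saltbridge, actloop_nt, actloop_ct) == ("out", "out", "out")


# ---------------------------------------------------------------------------
# the Active verdict
# ---------------------------------------------------------------------------

def test_active_geometry_classifies_active(active_fixture):
    _, structure, ann = active_fixture
    label = classify(structure.chains["A"], ann)
    assert label.spatial == "DFGin"
    assert label.dihedral == "BLAminus"
    assert label.saltbridge == "in"
    assert label.actloop_nt == "in"
    assert label.actloop_ct == "in"
    assert label.active is True


def test_broken_saltbridge_fails_with_named_reason():
    spec = default_fixture_spec(geometry={"d_saltbridge": 8.0})
    structure, ann = make_kinase_fixture(spec)
    label = classify(structure.chains["A"], ann)
    assert label.active is False
    assert label.saltbridge == "out"
    assert any("saltbridge=out" in r for r in label.reasons)


def test_wnk_skips_saltbridge_and_stays_active():
    spec = default_fixture_spec(
        geometry={"d_saltbridge": 8.0},
        family="OTHER", gene_label="OTHER_WNK1",
    )
    structure, ann = make_kinase_fixture(spec)
    assert ann.skip_saltbridge
    label = classify(structure.chains["A"], ann)
    assert label.saltbridge == "skipped"
    assert label.active is True


def test_haspin_like_skips_actloopct():
    spec = default_fixture_spec(
        geometry={"d_actloop_ct": 11.0},
        family="OTHER", gene_label="OTHER_HASPIN",
    )
    structure, ann = make_kinase_fixture(spec)
    label = classify(structure.chains["A"], ann)
    assert label.actloop_ct == "skipped"
    assert label.active is True


def test_missing_atoms_yield_unevaluable_not_false(active_fixture):
    structure, ann = make_kinase_fixture(default_fixture_spec())
    chain = structure.chains["A"]
    lys = chain[ann.beta3_lys]
    lys.atoms = [a for a in lys.atoms if a.name != "NZ"]
    label = classify(chain, ann)
    assert label.saltbridge == "unevaluable"
    assert label.active is None


def test_broken_spine_does_not_affect_verdict():
    spec = default_fixture_spec(
        geometry={"spine1": 7.5, "spine2": 7.0, "spine3": 8.0}
    )
    structure, ann = make_kinase_fixture(spec)
    label = classify(structure.chains["A"], ann)
    assert label.spine_intact is False
    assert label.active is True


def test_active_implies_blaminus():
    rng = np.random.default_rng(42)
    base = default_fixture_spec()
    for _ in range(20):
        geometry = dict(base.anchor_geometry)
        geometry["d_saltbridge"] = float(rng.uniform(2.5, 6.0))
        geometry["d_actloop_nt"] = float(rng.uniform(2.5, 6.0))
        geometry["phe_chi1"] = float(rng.uniform(-180.0, 180.0))
        spec = default_fixture_spec(geometry=geometry)
        structure, ann = make_kinase_fixture(spec)
        label = classify(structure.chains["A"], ann)
        if label.active is True:
            assert label.dihedral == "BLAminus"


def test_classification_invariant_under_rigid_transform(active_fixture):
    _, structure, ann = active_fixture
    reference = classify(structure.chains["A"], ann)
    rng = np.random.default_rng(9)
    for _ in range(5):
        moved = transform_structure(
            structure, random_rotation(rng), rng.normal(size=3) * 30
        )
        label = classify(moved.chains["A"], ann)
        assert (label.spatial, label.dihedral, label.saltbridge,
                label.actloop_nt, label.actloop_ct, label.active) == (
            reference.spatial, reference.dihedral, reference.saltbridge,
            reference.actloop_nt, reference.actloop_ct, reference.active)


@pytest.mark.parametrize(
    "key,state_index",
    [("d_saltbridge", 0), ("d_actloop_nt", 1), ("d_actloop_ct", 2)],
)
def test_criterion_monotonic_out_to_in_as_distance_shrinks(key, state_index):
    order = {"out": 0, "in": 1}
    previous = None
    for value in (8.0, 5.5, 3.4, 2.6):
        spec = default_fixture_spec(geometry={key: value})
        structure, ann = make_kinase_fixture(spec)
        report = measure_geometry(structure.chains["A"], ann)
        state = criterion_states(report, ann)[state_index]
        if previous is not None:
            assert order[state] >= order[previous]
        previous = state


def test_table1_like_agc_geometry_reports_published_observables():
    """Synthetic stand-in at an AGC substrate-complex geometry (salt bridge
    3.0 Å, DFG6 3.1 Å, APE9 4.1 Å, max spine 3.9 Å) is Active and every
    distance is echoed to the printed precision."""
    spec = default_fixture_spec(
        geometry={"d_saltbridge": 3.0, "d_actloop_nt": 3.1,
                  "d_actloop_ct": 4.1, "spine1": 3.7, "spine2": 3.9,
                  "spine3": 3.5},
        family="AGC", gene_label="AGC_SYNTH1",
    )
    structure, ann = make_kinase_fixture(spec)
    label = classify(structure.chains["A"], ann)
    rep = label.report
    assert rep.d_saltbridge == pytest.approx(3.0, abs=0.05)
    assert rep.d_actloop_nt == pytest.approx(3.1, abs=0.05)
    assert rep.d_actloop_ct == pytest.approx(4.1, abs=0.05)
    assert rep.max_spine == pytest.approx(3.9, abs=0.05)
    assert label.active is True


def test_cutoffs_validation():
    with pytest.raises(ValueError):
        FamilyCutoffs(saltbridge_cutoff=-1.0)
    with pytest.raises(ValueError):
        FamilyCutoffs(actloop_ct_cutoff_tyr=5.0, actloop_ct_cutoff_nontyr=6.0)
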