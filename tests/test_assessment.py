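"""pLDDT ranking, residue correspondence, and the two-stage RMSD protocol."""

import copy

import numpy as np
import pytest

from kinactive.assess import (
    ModelScore,
    activation_loop_rmsd,
    benchmark_summary,
    build_correspondence,
    min_plddt_activation_loop,
    rank_models,
)
from kinactive.fixtures import (
    default_fixture_spec,
    make_kinase_fixture,
    make_model_ensemble,
    perturb_loop,
)
from kinactive.geometry import GeometryError
from kinactive.structure import get_atom

from conftest import random_rotation, transform_structure


def _score(model_id, mn, mean=None, rmsd=None, label=None):
    return ModelScore(model_id=model_id, min_plddt_al=mn,
                      mean_plddt_al=mean if mean is not None else mn,
                      rmsd_al=rmsd, active_label=label)


# ---------------------------------------------------------------------------
# pLDDT extraction
# ---------------------------------------------------------------------------

def test_min_plddt_constant_profile(active_fixture):
    _, structure, ann = active_fixture
    mn, mean = min_plddt_activation_loop(structure, ann)
    assert mn == pytest.approx(90.0)
    assert mean == pytest.approx(90.0)


def test_min_plddt_single_low_residue():
    spec = default_fixture_spec()
    profile = np.full(len(spec.sequence), 90.0)
    profile[75] = 42.5  # inside the activation loop
    spec = default_fixture_spec(plddt_profile=profile)
    structure, ann = make_kinase_fixture(spec)
    mn, _ = min_plddt_activation_loop(structure, ann)
    assert mn == pytest.approx(42.5)


def test_min_and_mean_plddt_arithmetic():
    spec = default_fixture_spec()
    profile = np.full(len(spec.sequence), 70.0)
    loop = list(range(70, 93))
    profile[loop[0]] = 60.0
    profile[loop[1]] = 80.0  # rest of the loop stays at 70
    spec = default_fixture_spec(plddt_profile=profile)
    structure, ann = make_kinase_fixture(spec)
    mn, mean = min_plddt_activation_loop(structure, ann)
    assert mn == pytest.approx(60.0)
    assert mean == pytest.approx((60.0 + 80.0 + 21 * 70.0) / 23)


def test_min_plddt_refuses_experimental_structures(active_fixture):
    _, structure, ann = active_fixture
    experimental = copy.deepcopy(structure)
    experimental.is_model = False
    with pytest.raises(ValueError, match="experimental"):
        min_plddt_activation_loop(experimental, ann)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_rank_models_descending_by_min_plddt():
    scores = [_score("a", 84.2), _score("b", 50.1), _score("c", 77.0)]
    ranked = rank_models(scores)
    assert [s.min_plddt_al for s in ranked] == [84.2, 77.0, 50.1]


def test_rank_models_tie_broken_by_mean_then_id():
    scores = [_score("b", 70.0, mean=70.0), _score("a", 70.0, mean=80.0),
              _score("c", 70.0, mean=70.0)]
    ranked = rank_models(scores)
    assert [s.model_id for s in ranked] == ["a", "b", "c"]


def test_rank_models_is_permutation_invariant():
    rng = np.random.default_rng(13)
    scores = [_score(f"m{i}", float(v), mean=float(v) + 1.0)
              for i, v in enumerate(rng.uniform(40, 95, 12))]
    reference = [s.model_id for s in rank_models(scores)]
    for _ in range(5):
        shuffled = list(scores)
        rng.shuffle(shuffled)
        assert [s.model_id for s in rank_models(shuffled)] == reference


def test_require_active_excludes_inactive_top_scorer(active_fixture):
    _, structure, ann = active_fixture
    from kinactive.classify import classify

    active_label = classify(structure.chains["A"], ann)
    spec = default_fixture_spec(geometry={"d_saltbridge": 8.0})
    st_inactive, ann2 = make_kinase_fixture(spec)
    inactive_label = classify(st_inactive.chains["A"], ann2)
    scores = [_score("best_but_inactive", 95.0, label=inactive_label),
              _score("active_runner_up", 80.0, label=active_label)]
    ranked = rank_models(scores, require_active=True)
    assert [s.model_id for s in ranked] == ["active_runner_up"]


def test_rank_models_all_excluded_warns_and_returns_empty(caplog):
    scores = [_score("m", 80.0, label=None)]
    with caplog.at_level("WARNING"):
        assert rank_models(scores, require_active=True) == []


# ---------------------------------------------------------------------------
# correspondence and RMSD
# ---------------------------------------------------------------------------

def test_identity_correspondence(active_fixture):
    _, structure, ann = active_fixture
    chain = structure.chains["A"]
    cmap = build_correspondence(chain, chain, ann, ann)
    assert cmap.identity == pytest.approx(1.0)
    assert all(i == j for i, j in cmap.ctd_pairs)
    assert [i for i, _ in cmap.loop_pairs] == list(ann.loop_ordinals())


def test_missing_loop_residues_are_dropped_from_loop_pairs(active_fixture):
    _, structure, ann = active_fixture
    chain = structure.chains["A"]
    ref = copy.deepcopy(structure).chains["A"]
    for ordinal in (78, 79):  # strip backbone of two loop residues
        ref[ordinal].atoms = [a for a in ref[ordinal].atoms if a.name == "CA"]
    cmap = build_correspondence(chain, ref, ann, ann)
    assert len(cmap.loop_pairs) == len(list(ann.loop_ordinals())) - 2


def test_nterminal_extension_absorbed_by_alignment(active_fixture):
    _, structure, ann = active_fixture
    from kinactive.annotation import AnnotationConfig, annotate_from_config
    from kinactive.structure import ResidueRecord

    extended = copy.deepcopy(structure).chains["A"]
    for k in range(3):
        extended.insert(0, ResidueRecord(
            chain_id="A", seq_num=-k, insertion_code="", aa3="GLY", aa1="G"))
    config = AnnotationConfig(
        gene_label="CAMK_SYNTH1", family="CAMK",
        anchors={"beta3_lys": 19, "chelix_glu": 25, "hpn_his": 35,
                 "hrd_his": 61, "dfg_asp": 71, "ape_ala": 91},
    )
    ann_ext = annotate_from_config(extended, config)
    cmap = build_correspondence(extended, structure.chains["A"], ann_ext, ann)
    assert all(i == j + 3 for i, j in cmap.loop_pairs)


def test_rmsd_zero_for_identical_structures(active_fixture):
    _, structure, ann = active_fixture
    chain = structure.chains["A"]
    cmap = build_correspondence(chain, chain, ann, ann)
    rmsd_al, rmsd_ctd = activation_loop_rmsd(chain, chain, cmap)
    assert rmsd_al == pytest.approx(0.0, abs=1e-9)
    assert rmsd_ctd == pytest.approx(0.0, abs=1e-9)


def test_translated_loop_gives_exact_offset_rmsd(active_fixture):
    _, structure, ann = active_fixture
    model = copy.deepcopy(structure)
    chain = model.chains["A"]
    for i in ann.loop_ordinals():
        for atom in chain[i].atoms:
            atom.position = atom.position + np.array([2.0, 0.0, 0.0])
    cmap = build_correspondence(chain, structure.chains["A"], ann, ann)
    rmsd_al, rmsd_ctd = activation_loop_rmsd(chain, structure.chains["A"], cmap)
    assert rmsd_ctd == pytest.approx(0.0, abs=1e-9)
    assert rmsd_al == pytest.approx(2.0, abs=1e-9)


def test_two_stage_protocol_matches_independent_reimplementation(
        active_fixture):
    """Fit-then-measure cross-checked against a quaternion-based
    re-implementation of the same protocol."""
    from test_geometry import quaternion_superpose_rmsd

    _, structure, ann = active_fixture
    model = perturb_loop(structure, ann, sigma=1.0, seed=5)
    chain_m = model.chains["A"]
    chain_r = structure.chains["A"]
    cmap = build_correspondence(chain_m, chain_r, ann, ann)
    rmsd_al, rmsd_ctd = activation_loop_rmsd(chain_m, chain_r, cmap)

    # independent recomputation: quaternion rotation from CTD CAs
    ctd_m = np.array([get_atom(chain_m[i], "CA").position
                      for i, _ in cmap.ctd_pairs])
    ctd_r = np.array([get_atom(chain_r[j], "CA").position
                      for _, j in cmap.ctd_pairs])
    assert rmsd_ctd == pytest.approx(
        quaternion_superpose_rmsd(ctd_m, ctd_r), abs=1e-9
    )
    # CTD untouched by the loop perturbation -> transform is identity;
    # the loop RMSD must equal the direct no-fit RMSD over loop backbone
    loop_m, loop_r = [], []
    for i, j in cmap.loop_pairs:
        for name in ("N", "CA", "C", "O"):
            loop_m.append(get_atom(chain_m[i], name).position)
            loop_r.append(get_atom(chain_r[j], name).position)
    direct = float(np.sqrt(np.mean(
        np.sum((np.array(loop_m) - np.array(loop_r)) ** 2, axis=1))))
    assert rmsd_al == pytest.approx(direct, abs=1e-9)


def test_rmsd_invariant_to_rigid_transform_of_model(active_fixture):
    _, structure, ann = active_fixture
    model = perturb_loop(structure, ann, sigma=0.8, seed=11)
    chain_r = structure.chains["A"]
    cmap = build_correspondence(model.chains["A"], chain_r, ann, ann)
    baseline, _ = activation_loop_rmsd(model.chains["A"], chain_r, cmap)
    rng = np.random.default_rng(17)
    for _ in range(5):
        moved = transform_structure(
            model, random_rotation(rng), rng.normal(size=3) * 40
        )
        rmsd_al, _ = activation_loop_rmsd(moved.chains["A"], chain_r, cmap)
        assert rmsd_al == pytest.approx(baseline, abs=1e-8)


def test_removing_worst_loop_pair_never_increases_rmsd(active_fixture):
    _, structure, ann = active_fixture
    model = perturb_loop(structure, ann, sigma=1.2, seed=23)
    chain_m = model.chains["A"]
    chain_r = structure.chains["A"]
    cmap = build_correspondence(chain_m, chain_r, ann, ann)
    full, _ = activation_loop_rmsd(chain_m, chain_r, cmap)

    def pair_error(pair):
        i, j = pair
        return sum(
            np.sum((get_atom(chain_m[i], n).position
                    - get_atom(chain_r[j], n).position) ** 2)
            for n in ("N", "CA", "C", "O")
        )

    worst = max(cmap.loop_pairs, key=pair_error)
    reduced = copy.deepcopy(cmap)
    reduced.loop_pairs = [p for p in cmap.loop_pairs if p != worst]
    smaller, _ = activation_loop_rmsd(chain_m, chain_r, reduced)
    assert smaller <= full + 1e-12


def test_degenerate_ctd_raises(active_fixture):
    _, structure, ann = active_fixture
    chain = structure.chains["A"]
    cmap = build_correspondence(chain, chain, ann, ann)
    cmap.ctd_pairs = cmap.ctd_pairs[:2]
    with pytest.raises(GeometryError):
        activation_loop_rmsd(chain, chain, cmap)


# ---------------------------------------------------------------------------
# benchmark summary and pLDDT-error coupling
# ---------------------------------------------------------------------------

def test_benchmark_summary_fractions():
    summary = benchmark_summary([("a", 0.5), ("b", 1.5), ("c", 2.5)])
    assert summary.fraction_below_1 == pytest.approx(1 / 3)
    assert summary.fraction_below_2 == pytest.approx(2 / 3)
    assert sum(count for _, _, count in summary.histogram) == 3


def test_benchmark_summary_all_zero():
    summary = benchmark_summary([(f"k{i}", 0.0) for i in range(5)])
    assert summary.fraction_below_1 == 1.0
    assert summary.fraction_below_2 == 1.0


def test_benchmark_summary_constructed_distribution():
    rng = np.random.default_rng(31)
    rmsds = np.concatenate([rng.uniform(0.1, 0.95, 104),
                            rng.uniform(1.05, 4.0, 26)])
    summary = benchmark_summary(
        [(f"k{i}", float(r)) for i, r in enumerate(rmsds)]
    )
    assert summary.n == 130
    assert summary.fraction_below_1 == pytest.approx(104 / 130)


def test_perfectly_coupled_ensemble_top_model_has_minimum_rmsd():
    spec = default_fixture_spec()
    base, ann = make_kinase_fixture(spec)
    models = make_model_ensemble(spec, 6, plddt_rmsd_coupling=1.0, seed=29)
    scores = []
    for model in models:
        mn, mean = min_plddt_activation_loop(model, ann)
        cmap = build_correspondence(
            model.chains["A"], base.chains["A"], ann, ann
        )
        rmsd_al, _ = activation_loop_rmsd(
            model.chains["A"], base.chains["A"], cmap
        )
        scores.append(_score(model.entry_id, mn, mean=mean, rmsd=rmsd_al))
    ranked = rank_models(scores)
    assert ranked[0].rmsd_al == pytest.approx(
        min(s.rmsd_al for s in scores)
    )
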