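import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pocketpharm.filtering import FeaturePoint, FeatureType, Provenance
from pocketpharm.model import Pharmacophore
from pocketpharm.screening import (
    LigandFeatures,
    compute_auc,
    compute_ef,
    match_ligand,
    perceive_ligand_features,
    triangle_index,
)


def fp(ftype, position):
    return FeaturePoint(ftype=ftype, position=np.asarray(position, float), score=1.0,
                        provenance=Provenance.PT2)


def simple_model(n=4):
    types = [FeatureType.HBA, FeatureType.HBD, FeatureType.POS, FeatureType.HYDROPHOBIC,
             FeatureType.NEG, FeatureType.AROMATIC]
    positions = [[0, 0, 0], [3.1, 0, 0], [0.4, 4.2, 0], [1.0, 1.7, 3.3], [4.0, 3.0, 2.0],
                 [2.2, 0.8, 1.1]]
    return Pharmacophore(features=[fp(t, p) for t, p in zip(types[:n], positions[:n])])


def as_ligand(model, lid="lig"):
    return LigandFeatures(
        ligand_id=lid,
        features=[fp(f.ftype, f.position.copy()) for f in model.features],
    )


# ---------------------------------------------------------------------------
# ligand feature perception (RDKit)
# ---------------------------------------------------------------------------


def embedded(smiles):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return mol


def test_benzene_has_one_aromatic_and_one_hydrophobic_feature():
    lig = perceive_ligand_features(embedded("c1ccccc1"))
    counts = {}
    for f in lig.features:
        counts[f.ftype.value] = counts.get(f.ftype.value, 0) + 1
    assert counts == {"AROMATIC": 1, "HYDROPHOBIC": 1}
    aro = next(f for f in lig.features if f.ftype is FeatureType.AROMATIC)
    assert aro.direction is not None


def test_methanol_is_donor_and_acceptor_at_the_oxygen():
    lig = perceive_ligand_features(embedded("CO"))
    types = sorted(f.ftype.value for f in lig.features)
    assert types == ["HBA", "HBD"]
    np.testing.assert_allclose(lig.features[0].position, lig.features[1].position, atol=1e-9)


def test_acetate_gives_one_negative_feature_at_carboxylate_midpoint():
    from rdkit import Chem

    lig = perceive_ligand_features(embedded("CC(=O)[O-]"))
    neg = [f for f in lig.features if f.ftype is FeatureType.NEG]
    assert len(neg) == 1
    mol = embedded("CC(=O)[O-]")
    conf = mol.GetConformer()
    o_pos = [
        np.array([conf.GetAtomPosition(a.GetIdx()).x, conf.GetAtomPosition(a.GetIdx()).y,
                  conf.GetAtomPosition(a.GetIdx()).z])
        for a in mol.GetAtoms() if a.GetSymbol() == "O"
    ]
    np.testing.assert_allclose(neg[0].position, np.mean(o_pos, axis=0), atol=1e-6)


def test_molecule_without_coordinates_is_rejected():
    from rdkit import Chem

    with pytest.raises(ValueError):
        perceive_ligand_features(Chem.MolFromSmiles("CCO"))


# ---------------------------------------------------------------------------
# triangle index
# ---------------------------------------------------------------------------


def test_triple_counts_follow_binomial():
    assert len(triangle_index(simple_model(3))) == 1
    assert len(triangle_index(simple_model(5))) == math.comb(5, 3)


def test_too_few_features_gives_empty_index():
    assert len(triangle_index(simple_model(2))) == 0


def test_collinear_triple_is_flagged_degenerate():
    model = Pharmacophore(features=[
        fp(FeatureType.HBA, [0, 0, 0]),
        fp(FeatureType.HBA, [1, 0, 0]),
        fp(FeatureType.HBA, [2, 0, 0]),
    ])
    index = triangle_index(model)
    entries = [e for v in index.entries.values() for e in v]
    assert len(entries) == 1 and entries[0]["degenerate"]
    # a degenerate-only index can seed no transform
    result = match_ligand(index, as_ligand(model))
    assert result.fit_score == 0.0


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def test_identical_ligand_matches_perfectly():
    model = simple_model(5)
    result = match_ligand(triangle_index(model), as_ligand(model))
    assert result.fit_score == 1.0
    assert result.n_matched == 5
    assert result.rmsd < 1e-9


def test_rigidly_moved_ligand_matches_perfectly():
    model = simple_model(6)
    lig = as_ligand(model)
    rot = Rotation.from_euler("xyz", [90, 15, -30], degrees=True).as_matrix()
    for f in lig.features:
        f.position = rot @ f.position + np.array([7.0, -2.0, 4.0])
    result = match_ligand(triangle_index(model), lig)
    assert result.fit_score == 1.0
    assert result.rmsd < 1e-6


def test_no_shared_types_scores_zero():
    model = simple_model(3)  # HBA, HBD, POS
    lig = LigandFeatures(
        ligand_id="x",
        features=[fp(FeatureType.AROMATIC, [0, 0, 0]), fp(FeatureType.AROMATIC, [3, 0, 0]),
                  fp(FeatureType.AROMATIC, [0, 3, 0])],
    )
    result = match_ligand(triangle_index(model), lig)
    assert result.fit_score == 0.0 and result.n_matched == 0


def test_partial_ligand_cannot_reach_full_score():
    model = simple_model(6)
    lig = as_ligand(model)
    lig.features = lig.features[:4]
    result = match_ligand(triangle_index(model), lig)
    assert result.n_matched == 4
    assert result.fit_score == pytest.approx(4 / 6)


def test_match_is_invariant_to_rigid_motion_of_the_ligand(rng):
    model = simple_model(6)
    index = triangle_index(model)
    lig = as_ligand(model)
    for f in lig.features:  # distort slightly so the match is non-trivial
        f.position = f.position + rng.normal(0, 0.2, 3)
    base = match_ligand(index, lig)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    for f in lig.features:
        f.position = rot @ f.position + shift
    moved = match_ligand(index, lig)
    assert moved.fit_score == base.fit_score
    assert moved.rmsd == pytest.approx(base.rmsd, abs=1e-6)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_ef_reproduces_contingency_example():
    # 5 of the top 10 are active, 10 actives in a library of 100
    scores = [(f"a{i}", 1.0 - 0.01 * i, i % 2 == 0) for i in range(10)]
    scores += [(f"d{i}", 0.1, i < 5) for i in range(90)]
    assert compute_ef(scores, 0.1) == pytest.approx((5 / 10) * (100 / 10))


def test_ef_at_full_fraction_is_one(rng):
    scores = [(f"m{i}", float(rng.uniform()), bool(rng.uniform() < 0.3)) for i in range(50)]
    if not any(a for _, _, a in scores):
        scores[0] = (scores[0][0], scores[0][1], True)
    assert compute_ef(scores, 1.0) == pytest.approx(1.0)


def test_ef_zero_when_top_fraction_has_no_actives():
    scores = [("d", 0.9, False), ("a", 0.1, True)] + [(f"x{i}", 0.5, False) for i in range(48)]
    assert compute_ef(scores, 0.02) == 0.0


def test_ef_requires_actives_and_valid_fraction():
    with pytest.raises(ValueError):
        compute_ef([("a", 1.0, False)], 0.1)
    with pytest.raises(ValueError):
        compute_ef([("a", 1.0, True)], 0.0)


def test_ef_invariant_under_monotone_score_transform(rng):
    scores = [(f"m{i}", float(rng.uniform()), bool(rng.uniform() < 0.2)) for i in range(100)]
    if not any(a for _, _, a in scores):
        scores[0] = (scores[0][0], scores[0][1], True)
    transformed = [(lid, math.exp(3 * s), a) for lid, s, a in scores]
    for frac in (0.01, 0.05, 0.2):
        assert compute_ef(scores, frac) == pytest.approx(compute_ef(transformed, frac))


def test_auc_perfect_tied_and_mixed_cases():
    assert compute_auc([(0.9, True), (0.8, True), (0.2, False)]) == 1.0
    assert compute_auc([(0.5, True), (0.5, False), (0.5, True)]) == 0.5
    # 4 pairs: (0.9 beats both), (0.4 beats 0.1 only) -> 3/4
    assert compute_auc([(0.9, True), (0.4, True), (0.6, False), (0.1, False)]) == 0.75


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        compute_auc([(0.5, True), (0.6, True)])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_auc_equals_bruteforce_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 100))
    scores = np.round(rng.uniform(0, 1, n), 2)  # coarse grid forces ties
    labels = rng.uniform(size=n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = True
        labels[1] = False
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    brute = wins / (len(pos) * len(neg))
    got = compute_auc(list(zip(scores, labels)))
    assert got == pytest.approx(brute, abs=1e-12)
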