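"""Interaction fingerprints, decoy generation, and the nativeness classifier."""

import numpy as np
import pytest

from frasebot import fixtures, frase_db, nativeness
from frasebot.complex_io import (
    assign_ligand_atom_types,
    assign_protein_atom_types,
)
from frasebot.nativeness import (
    N_FEATURES,
    DecoyError,
    NativenessModel,
    TrainConfig,
    distance_weight,
    feature_index,
    generate_decoys,
    interaction_fingerprint,
    score,
    train_model,
)


def _single_pair_frase(distance):
    """One carbon-probe ligand atom and one glycine Calpha at a set distance."""
    frag = fixtures._point_fragment(np.zeros(3))
    res = fixtures._make_residue("GLY", np.array([distance, 0.0, 0.0]), "A", 1)
    return frase_db.Frase(fragment=frag, environment=[res], label="true")


def brute_force_fingerprint(frase, optimum=3.0, cutoff=10.0):
    """Independent double loop over typed atoms with per-pair weights."""
    lig = assign_ligand_atom_types(frase.fragment.mol)
    prot = assign_protein_atom_types(frase.environment)
    out = np.zeros(N_FEATURES)
    for ta in lig:
        for tb in prot:
            d = float(np.linalg.norm(ta.atom.coord - tb.atom.coord))
            if d > cutoff:
                continue
            w = np.exp(-((d - optimum) ** 2))
            for m in ta.types:
                for n in tb.types:
                    out[feature_index(m, n)] += w
    return out


class TestFingerprint:
    def test_single_pair_at_optimum(self):
        fp = interaction_fingerprint(_single_pair_frase(3.0))
        idx = feature_index("Aliphatic Carbon", "Aliphatic Carbon")
        assert fp[idx] == pytest.approx(1.0, abs=1e-12)
        rest = np.delete(fp, idx)
        assert np.all(rest == 0)

    def test_pair_beyond_cutoff_zero(self):
        fp = interaction_fingerprint(_single_pair_frase(11.0))
        assert np.all(fp == 0)

    def test_length_377(self, small_frase_pool):
        assert interaction_fingerprint(small_frase_pool[0]).shape == (N_FEATURES,)
        assert N_FEATURES == 377

    def test_matches_brute_force_on_random_fixtures(self, small_frase_pool):
        for frase in small_frase_pool:
            got = interaction_fingerprint(frase)
            ref = brute_force_fingerprint(frase)
            np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_additivity_over_ligand_atoms(self):
        res = fixtures._make_residue("GLY", np.array([3.0, 0.0, 0.0]), "A", 1)
        a = fixtures._point_fragment(np.zeros(3))
        b = fixtures._point_fragment(np.array([0.0, 2.0, 0.0]))
        from rdkit import Chem

        both = Chem.RWMol()
        both.AddAtom(Chem.Atom(6))
        both.AddAtom(Chem.Atom(6))
        m = both.GetMol()
        conf = Chem.Conformer(2)
        conf.SetAtomPosition(0, [0.0, 0.0, 0.0])
        conf.SetAtomPosition(1, [0.0, 2.0, 0.0])
        m.AddConformer(conf)
        Chem.SanitizeMol(m)
        pair = frase_db.Fragment(mol=m, mol_weight=32.0)
        fp_a = interaction_fingerprint(frase_db.Frase(a, [res]))
        fp_b = interaction_fingerprint(frase_db.Frase(b, [res]))
        fp_ab = interaction_fingerprint(frase_db.Frase(pair, [res]))
        np.testing.assert_allclose(fp_ab, fp_a + fp_b, atol=1e-12)

    def test_weight_shape(self):
        d = np.array([3.0, 5.0, 9.9, 10.0, 10.01, 15.0])
        w = distance_weight(d)
        assert w[0] == 1.0
        assert w[0] > w[1] > w[2] >= w[3] > 0
        assert w[4] == 0 and w[5] == 0

    def test_hard_count_variant(self):
        fp = interaction_fingerprint(_single_pair_frase(4.9), hard_count=True)
        idx = feature_index("Aliphatic Carbon", "Aliphatic Carbon")
        assert fp[idx] == 1.0
        fp = interaction_fingerprint(_single_pair_frase(5.1), hard_count=True)
        assert np.all(fp == 0)

    def test_rigid_motion_invariance(self, small_frase_pool):
        rng = np.random.default_rng(13)
        frase = small_frase_pool[0]
        R = fixtures.random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        from frasebot.triplet_screen import _transform_residue, transform_fragment

        moved = frase_db.Frase(
            fragment=transform_fragment(frase.fragment, R, t),
            environment=[_transform_residue(r, R, t) for r in frase.environment])
        np.testing.assert_allclose(interaction_fingerprint(frase),
                                   interaction_fingerprint(moved), atol=1e-9)


class TestDecoys:
    def test_count_contract(self, small_frase_pool):
        truths = [f for f in small_frase_pool if f.label == "true"]
        decoys = generate_decoys(truths, multiplicity=2, seed=1)
        assert len(decoys) == 2 * len(truths)

    def test_fragment_differs_from_native(self):
        truths, _ = fixtures.make_separable_frase_set(n_true=2, multiplicity=1, seed=4)
        from rdkit import Chem

        decoys = generate_decoys(truths, multiplicity=1, seed=4)
        for native, decoy in zip(truths, decoys):
            assert Chem.MolToSmiles(native.fragment.mol) != Chem.MolToSmiles(decoy.fragment.mol)

    def test_centroid_preserved(self, small_frase_pool):
        truths = [f for f in small_frase_pool if f.label == "true"]
        decoys = generate_decoys(truths, multiplicity=1, seed=2)
        for native, decoy in zip(truths, decoys):
            np.testing.assert_allclose(native.fragment.centroid(),
                                       decoy.fragment.centroid(), atol=1e-9)

    def test_seed_determinism(self, small_frase_pool):
        truths = [f for f in small_frase_pool if f.label == "true"]
        d1 = generate_decoys(truths, multiplicity=2, seed=9)
        d2 = generate_decoys(truths, multiplicity=2, seed=9)
        for a, b in zip(d1, d2):
            assert a.provenance == b.provenance
            np.testing.assert_allclose(a.fragment.heavy_coords(),
                                       b.fragment.heavy_coords(), atol=0)

    def test_identical_fragments_rejected(self):
        frag1 = fixtures.fragment_from_smiles("c1ccccc1", 1)
        frag2 = fixtures.fragment_from_smiles("c1ccccc1", 2)
        res = fixtures._make_residue("GLY", np.zeros(3), "A", 1)
        frases = [frase_db.Frase(frag1, [res]), frase_db.Frase(frag2, [res])]
        with pytest.raises(DecoyError):
            generate_decoys(frases, seed=0)


class TestModel:
    def test_holdout_accuracy_on_separable_set(self, trained_model):
        assert trained_model.accuracy >= 0.9

    def test_true_class_scores_high(self, trained_model, separable_set):
        truths, _ = separable_set
        # fresh frases from the same construction, unseen seed
        fresh, _ = fixtures.make_separable_frase_set(n_true=50, multiplicity=1, seed=99)
        scores = [score(trained_model, f) for f in fresh]
        assert np.mean(np.array(scores) > 0.5) >= 0.9

    def test_seed_determinism(self, small_frase_pool):
        truths = [f for f in small_frase_pool if f.label == "true"]
        decoys = generate_decoys(truths, multiplicity=2, seed=3)
        cfg = TrainConfig(epochs=10)
        m1 = train_model(truths, decoys, cfg, seed=5)
        m2 = train_model(truths, decoys, cfg, seed=5)
        for w1, w2 in zip(m1.net.coefs_, m2.net.coefs_):
            np.testing.assert_array_equal(w1, w2)

    def test_score_in_unit_interval_and_deterministic(self, trained_model,
                                                      small_frase_pool):
        s1 = [score(trained_model, f) for f in small_frase_pool[:5]]
        s2 = [score(trained_model, f) for f in small_frase_pool[:5]]
        assert s1 == s2
        assert all(0 < s < 1 for s in s1)

    def test_score_rigid_motion_invariant(self, trained_model, small_frase_pool):
        rng = np.random.default_rng(17)
        frase = small_frase_pool[3]
        R = fixtures.random_rotation(rng)
        t = rng.uniform(-8, 8, 3)
        from frasebot.triplet_screen import _transform_residue, transform_fragment

        moved = frase_db.Frase(
            fragment=transform_fragment(frase.fragment, R, t),
            environment=[_transform_residue(r, R, t) for r in frase.environment])
        assert score(trained_model, frase) == pytest.approx(
            score(trained_model, moved), abs=1e-6)

    def test_model_round_trip(self, trained_model, small_frase_pool, tmp_path):
        path = tmp_path / "model.joblib"
        trained_model.save(path)
        back = NativenessModel.load(path)
        assert back.accuracy == trained_model.accuracy
        f = small_frase_pool[0]
        assert score(back, f) == score(trained_model, f)

    def test_empty_class_raises(self):
        with pytest.raises(nativeness.TrainingError):
            train_model([], [], TrainConfig(epochs=1), seed=0)
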