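"""Triplet enumeration, fingerprint matching, rigid alignment, and seeding."""

import itertools

import numpy as np
import pytest

from frasebot import fixtures, frase_db, triplet_screen
from frasebot.complex_io import Complex
from frasebot.triplet_screen import (
    ResidueTriplet,
    enumerate_triplets,
    kabsch,
    match_triplets,
    screen,
    triplet_fingerprints,
)


def _residues_at(names, coords):
    return [fixtures._make_residue(n, np.asarray(c, float), "A", i + 1)
            for i, (n, c) in enumerate(zip(names, coords))]


def brute_force_triplets(residues, lo=8.0, hi=12.0):
    """O(n^3) reference enumeration."""
    usable = [r for r in residues if r.is_standard and r.ca_coord is not None]
    out = []
    for i, j, k in itertools.combinations(range(len(usable)), 3):
        d = [np.linalg.norm(usable[a].ca_coord - usable[b].ca_coord)
             for a, b in ((i, j), (j, k), (i, k))]
        if all(lo <= x <= hi for x in d):
            out.append((usable[i], usable[j], usable[k]))
    return out


class TestEnumeration:
    def test_midrange_equilateral_found(self):
        res = _residues_at(["GLY"] * 3, [(0, 0, 0), (10, 0, 0), (5, 8.6603, 0)])
        assert len(enumerate_triplets(res)) == 1

    def test_edge_below_window_rejected(self):
        res = _residues_at(["GLY"] * 3, [(0, 0, 0), (7.9, 0, 0), (4, 9.2, 0)])
        d01 = np.linalg.norm(res[0].ca_coord - res[1].ca_coord)
        assert d01 < 8
        assert enumerate_triplets(res) == []

    def test_matches_brute_force_on_random_cloud(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 30, size=(30, 3))
        res = _residues_at(["ALA"] * 30, coords)
        got = enumerate_triplets(res)
        ref = brute_force_triplets(res)
        assert len(got) == len(ref)
        got_keys = {frozenset(r.seq_index for r in t.residues) for t in got}
        ref_keys = {frozenset(r.seq_index for r in t) for t in ref}
        assert got_keys == ref_keys

    def test_fewer_than_three_residues(self):
        res = _residues_at(["GLY", "ALA"], [(0, 0, 0), (10, 0, 0)])
        assert enumerate_triplets(res) == []


class TestFingerprints:
    def _triplet(self, names):
        res = _residues_at(names, [(0, 0, 0), (10, 0, 0), (5, 8.6603, 0)])
        return enumerate_triplets(res)[0]

    def test_heterogeneous_triplet_six_distinct(self):
        fps = triplet_fingerprints(self._triplet(["TRP", "GLY", "ARG"]))
        assert len(fps) == 6
        assert len({fp.tobytes() for fp in fps}) == 6

    def test_homogeneous_triplet_six_identical(self):
        fps = triplet_fingerprints(self._triplet(["ALA", "ALA", "ALA"]))
        assert len({fp.tobytes() for fp in fps}) == 1

    def test_length_33(self):
        for fp in triplet_fingerprints(self._triplet(["SER", "PHE", "LYS"])):
            assert fp.shape == (33,)

    def test_concatenation_of_residue_bits(self):
        from frasebot.complex_io import encode_residue

        t = self._triplet(["TRP", "GLY", "ARG"])
        expected = np.concatenate([encode_residue(n) for n in ("TRP", "GLY", "ARG")])
        assert any((fp == expected).all() for fp in t.fingerprints)


class TestMatching:
    def _db_with_env(self, names, coords, seed=0):
        env = _residues_at(names, coords)
        frag = fixtures._point_fragment(np.mean(coords, axis=0))
        frase = frase_db.Frase(fragment=frag, environment=env, label="true",
                               provenance="t", frase_id=0)
        db = frase_db.FraseDB(frases=[frase])
        db.build_index()
        return db

    def test_self_match(self):
        coords = [(0, 0, 0), (10, 0, 0), (5, 8.6603, 0)]
        db = self._db_with_env(["TRP", "GLY", "ARG"], coords)
        target = enumerate_triplets(_residues_at(["TRP", "GLY", "ARG"], coords))
        matches = match_triplets(target, db)
        assert len(matches) == 1

    def test_order_invariance(self):
        coords = [(0, 0, 0), (10, 0, 0), (5, 8.6603, 0)]
        db = self._db_with_env(["GLY", "ARG", "TRP"],
                               [coords[1], coords[2], coords[0]])
        target = enumerate_triplets(_residues_at(["TRP", "GLY", "ARG"], coords))
        matches = match_triplets(target, db)
        assert len(matches) == 1
        corr = {(d.name, t.name) for d, t in matches[0].correspondence}
        assert corr == {("TRP", "TRP"), ("GLY", "GLY"), ("ARG", "ARG")}

    def test_matches_equal_exhaustive_comparison(self):
        rng = np.random.default_rng(7)
        names = ["TRP", "GLY", "ARG", "SER", "PHE", "LYS", "ALA", "LEU"] * 3
        coords = rng.uniform(0, 40, size=(len(names), 3))
        target_res = _residues_at(names, coords)
        target_trips = enumerate_triplets(target_res)
        db_res = _residues_at(names[::-1], coords + rng.normal(scale=0.3, size=coords.shape))
        frag = fixtures._point_fragment(np.zeros(3))
        frase = frase_db.Frase(fragment=frag, environment=db_res, label="true",
                               provenance="t", frase_id=0)
        db = frase_db.FraseDB(frases=[frase])
        db.build_index()
        db_trips = enumerate_triplets(db_res)
        assert len(target_trips) <= 100 and len(db_trips) <= 100

        def key(trip):
            return frozenset(r.seq_index for r in trip.residues)

        got = {(key(m.target_triplet), key(m.db_triplet))
               for m in match_triplets(target_trips, db, edge_tol=None)}
        ref = {(key(t), key(d)) for t in target_trips for d in db_trips
               if t.canonical_key == d.canonical_key}
        assert got == ref

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        spec = fixtures.FixtureSpec(seed=3, planted_triplets=[
            (("TRP", "GLY", "ARG"), (10.0, 10.0, 10.0)),
            (("SER", "PHE", "LYS"), (9.0, 11.0, 10.0))])
        cx = fixtures.make_planted_protein(spec)
        R = fixtures.random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        moved = fixtures.apply_rigid_motion(cx, R, t)
        t1 = enumerate_triplets(cx.protein_residues)
        t2 = enumerate_triplets(moved.protein_residues)
        assert len(t1) == len(t2)
        assert ({a.canonical_key for a in t1} == {a.canonical_key for a in t2})


class TestAlignment:
    def test_self_alignment_identity(self):
        P = np.array([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]], float)
        R, t, rmsd = kabsch(P, P)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, np.zeros(3), atol=1e-9)

    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(11)
        P = np.array([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]], float)
        R0 = fixtures.random_rotation(rng)
        t0 = rng.uniform(-50, 50, 3)
        Q = (R0 @ P.T).T + t0
        R, t, rmsd = kabsch(P, Q)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(R, R0, atol=1e-8)
        np.testing.assert_allclose(t, t0, atol=1e-7)

    def test_reflection_rejected(self):
        # scalene triangle and its mirror image cannot superpose exactly
        P = np.array([[0, 0, 0], [10, 0, 0], [3, 9, 0]], float)
        Q = P.copy()
        Q[:, 2] = [0, 0, 0]
        Q[2] = [3, -9, 0]  # reflected through the x-axis
        mirrored = P * np.array([1, -1, 1])
        R, t, rmsd = kabsch(P, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        # in-plane mirror of a planar triangle is reachable by a proper
        # rotation; force chirality with a non-planar 4th point instead
        P4 = np.vstack([P, [4, 3, 5]])
        R, t, rmsd = kabsch(P4, P4 * np.array([1, 1, -1]))
        assert rmsd > 0.1
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_optimality_against_random_rotations(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0, 10, (3, 3))
        Q = rng.uniform(0, 10, (3, 3))
        _, _, best = kabsch(P, Q)
        pc, qc = P.mean(0), Q.mean(0)
        for _ in range(100):
            R = fixtures.random_rotation(rng)
            moved = (R @ (P - pc).T).T + qc
            rmsd = np.sqrt(((moved - Q) ** 2).sum(axis=1).mean())
            assert best <= rmsd + 1e-12


class TestScreening:
    def test_planted_pose_recovered(self, planted_db):
        cx, db = planted_db
        spec = fixtures.FixtureSpec(seed=9)
        target = fixtures.make_planted_protein(spec)
        seeded = screen(target, db)
        assert len(seeded) == 1
        # fragment should land at the target triplet's centroid
        tri = enumerate_triplets(target.protein_residues)[0]
        center = np.mean([r.ca_coord for r in tri.residues], axis=0)
        assert np.linalg.norm(seeded[0].fragment.centroid() - center) < 1.0
        assert seeded[0].alignment_rmsd <= 1e-6

    def test_no_match_empty(self, planted_db):
        _, db = planted_db
        spec = fixtures.FixtureSpec(seed=9, planted_triplets=[
            (("SER", "PHE", "LYS"), (9.0, 11.0, 10.0))])
        target = fixtures.make_planted_protein(spec)
        assert screen(target, db) == []

    def test_two_matches_two_seeds(self, planted_db):
        _, db = planted_db
        spec = fixtures.FixtureSpec(seed=9, planted_triplets=[
            (("TRP", "GLY", "ARG"), (10.0, 10.0, 10.0)),
            (("TRP", "GLY", "ARG"), (10.0, 10.0, 10.0))])
        target = fixtures.make_planted_protein(spec)
        seeded = screen(target, db)
        assert len(seeded) == 2

    def test_seeded_poses_move_with_protein(self, planted_db):
        _, db = planted_db
        rng = np.random.default_rng(21)
        spec = fixtures.FixtureSpec(seed=9)
        target = fixtures.make_planted_protein(spec)
        R = fixtures.random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        moved = fixtures.apply_rigid_motion(target, R, t)
        s1 = screen(target, db)
        s2 = screen(moved, db)
        assert len(s1) == len(s2) == 1
        np.testing.assert_allclose(
            R @ s1[0].fragment.centroid() + t, s2[0].fragment.centroid(), atol=1e-6)
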