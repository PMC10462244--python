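"""Residue-triplet enumeration, matching, and fragment seeding.

Screening encodes every triplet of residues whose Calpha atoms form an
approximately equilateral triangle (all edges within 8-12 A) as six
order-permuted 33-bit fingerprints (three concatenated 11-bit residue
strings).  Database and target triplets are compared by exact fingerprint
equality through a hash index keyed on the lexicographically smallest of the
six permutations, which makes matching invariant to residue order.  A hit
triplet aligns its FRASE into the target frame by least-squares rigid
superposition (proper rotations only) of the three Calpha atoms, seeding the
fragment into the target protein.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .complex_io import Complex, Residue, encode_residue
from .frase_db import Fragment, Frase, FraseDB, extract_environment

__all__ = [
    "ResidueTriplet",
    "TripletMatch",
    "SeededFragment",
    "enumerate_triplets",
    "triplet_fingerprints",
    "match_triplets",
    "kabsch",
    "align_frase",
    "make_target_frase",
    "screen",
    "AlignmentError",
]

_PERMS = tuple(itertools.permutations(range(3)))


class AlignmentError(RuntimeError):
    pass


def _pack(bits: np.ndarray) -> bytes:
    # big-endian bit packing preserves lexicographic order of the bit string
    return np.packbits(bits).tobytes()


@dataclass
class ResidueTriplet:
    residues: tuple[Residue, Residue, Residue]
    edges: tuple[float, float, float]  # d(0,1), d(1,2), d(0,2)
    fingerprints: tuple[np.ndarray, ...] = ()  # 6 x 33 bits, one per permutation

    def __post_init__(self) -> None:
        if not self.fingerprints:
            self.fingerprints = triplet_fingerprints(self)

    @property
    def canonical_key(self) -> bytes:
        return min(_pack(fp) for fp in self.fingerprints)

    def edges_for_perm(self, perm: tuple[int, int, int]) -> tuple[float, float, float]:
        ca = [np.asarray(self.residues[i].ca_coord) for i in perm]
        return (
            float(np.linalg.norm(ca[0] - ca[1])),
            float(np.linalg.norm(ca[1] - ca[2])),
            float(np.linalg.norm(ca[0] - ca[2])),
        )


@dataclass
class TripletMatch:
    target_triplet: ResidueTriplet
    db_triplet: ResidueTriplet
    frase_id: int
    #: permutations (target, db) such that residue db[perm_db[m]] corresponds
    #: to target[perm_target[m]] for m = 0..2
    perm_target: tuple[int, int, int] = (0, 1, 2)
    perm_db: tuple[int, int, int] = (0, 1, 2)

    @property
    def correspondence(self) -> tuple[tuple[Residue, Residue], ...]:
        return tuple(
            (self.db_triplet.residues[d], self.target_triplet.residues[t])
            for t, d in zip(self.perm_target, self.perm_db)
        )


@dataclass
class SeededFragment:
    fragment: Fragment
    source_frase: int
    alignment_rmsd: float
    score: float | None = None
    environment: list[Residue] = field(default_factory=list)


def triplet_fingerprints(triplet: ResidueTriplet) -> tuple[np.ndarray, ...]:
    """The six order-permuted 33-bit fingerprints of a triplet."""
    bits = [encode_residue(r.name) for r in triplet.residues]
    return tuple(
        np.concatenate([bits[p[0]], bits[p[1]], bits[p[2]]]) for p in _PERMS
    )


def enumerate_triplets(
    residues: list[Residue], min_edge: float = 8.0, max_edge: float = 12.0
) -> list[ResidueTriplet]:
    """All unordered residue triples with pairwise Calpha distances in window.

    Non-standard residues and residues lacking a Calpha are skipped.
    """
    usable = [r for r in residues if r.is_standard and r.ca_coord is not None]
    if len(usable) < 3:
        return []
    ca = np.array([r.ca_coord for r in usable])
    d = cdist(ca, ca)
    ok = (d >= min_edge) & (d <= max_edge)
    neighbors = [set(np.nonzero(ok[i])[0]) for i in range(len(usable))]
    out = []
    for i in range(len(usable)):
        for j in sorted(neighbors[i]):
            if j <= i:
                continue
            for k in sorted(neighbors[i] & neighbors[j]):
                if k <= j:
                    continue
                out.append(
                    ResidueTriplet(
                        residues=(usable[i], usable[j], usable[k]),
                        edges=(float(d[i, j]), float(d[j, k]), float(d[i, k])),
                    )
                )
    return out


def _find_correspondence(
    target: ResidueTriplet,
    db: ResidueTriplet,
    edge_tol: float | None,
) -> tuple[tuple[int, int, int], tuple[int, int, int]] | None:
    """First permutation pair with equal fingerprints and compatible edges."""
    target_fps = [_pack(fp) for fp in target.fingerprints]
    db_fps = [_pack(fp) for fp in db.fingerprints]
    for ti, tperm in enumerate(_PERMS):
        for di, dperm in enumerate(_PERMS):
            if target_fps[ti] != db_fps[di]:
                continue
            if edge_tol is not None:
                te = target.edges_for_perm(tperm)
                de = db.edges_for_perm(dperm)
                if any(abs(a - b) > edge_tol for a, b in zip(te, de)):
                    continue
            return tperm, dperm
    return None


def match_triplets(
    target_triplets: list[ResidueTriplet],
    db: FraseDB,
    edge_tol: float | None = 2.0,
) -> list[TripletMatch]:
    """Match target triplets against the database fingerprint index.

    A match requires exact 33-bit fingerprint equality under some pair of
    residue orderings; with ``edge_tol`` set (default 2 A) the corresponding
    Calpha-Calpha edges must also agree within the tolerance.
    """
    out = []
    for t in target_triplets:
        for frase_id, db_trip in db.triplet_index.get(t.canonical_key, ()):
            corr = _find_correspondence(t, db_trip, edge_tol)
            if corr is not None:
                out.append(
                    TripletMatch(target_triplet=t, db_triplet=db_trip,
                                 frase_id=frase_id, perm_target=corr[0],
                                 perm_db=corr[1])
                )
    return out


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points P onto Q (proper rotation).

    Returns ``(R, t, rmsd)`` with ``x -> R @ x + t``.  Reflections are never
    produced: the rotation determinant is forced to +1.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    if not np.isfinite(rmsd):
        raise AlignmentError("non-finite superposition")
    return R, t, rmsd


def _transform_residue(res: Residue, R: np.ndarray, t: np.ndarray) -> Residue:
    atoms = [
        type(a)(element=a.element, coord=R @ a.coord + t, residue_id=a.residue_id,
                name=a.name, is_hydrogen=a.is_hydrogen)
        for a in res.atoms
    ]
    ca = None if res.ca_coord is None else R @ res.ca_coord + t
    return Residue(name=res.name, chain=res.chain, seq_index=res.seq_index,
                   ca_coord=ca, atoms=atoms)


def transform_fragment(frag: Fragment, R: np.ndarray, t: np.ndarray) -> Fragment:
    mol = type(frag.mol)(frag.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        newp = R @ np.array([p.x, p.y, p.z]) + t
        conf.SetAtomPosition(i, newp.tolist())
    return Fragment(mol, frag.mol_weight, frag.parent_ligand,
                    frag.attachment_points, frag.parent_atom_indices)


def align_frase(frase: Frase, match: TripletMatch) -> tuple[Frase, float]:
    """Superpose a database FRASE onto the target via the matched triplet.

    The three database Calpha atoms are fitted onto the three corresponding
    target Calpha atoms; the resulting rigid transform is applied to the
    whole FRASE (fragment and environment).  Returns the transformed FRASE
    and the 3-point superposition RMSD.
    """
    P = np.array([match.db_triplet.residues[d].ca_coord for d in match.perm_db])
    Q = np.array([match.target_triplet.residues[t].ca_coord for t in match.perm_target])
    R, t, rmsd = kabsch(P, Q)
    moved = Frase(
        fragment=transform_fragment(frase.fragment, R, t),
        environment=[_transform_residue(r, R, t) for r in frase.environment],
        label=frase.label,
        provenance=frase.provenance,
        frase_id=frase.frase_id,
    )
    return moved, rmsd


def make_target_frase(
    target: Complex, seeded: SeededFragment, radius: float = 4.5
) -> Frase | None:
    """Cut target residues around a seeded fragment into a new, unscored FRASE.

    Returns ``None`` when no residue lies within the radius (the fragment is
    then excluded from scoring).
    """
    env = extract_environment(target, seeded.fragment, radius)
    if not env:
        return None
    return Frase(fragment=seeded.fragment, environment=env, label=None,
                 provenance=f"seeded:{seeded.source_frase}",
                 frase_id=seeded.source_frase)


def screen(
    target_protein: Complex,
    db: FraseDB,
    min_edge: float = 8.0,
    max_edge: float = 12.0,
    edge_tol: float | None = 2.0,
    env_radius: float = 4.5,
    dedupe_dist: float = 0.5,
) -> list[SeededFragment]:
    """Seed database fragments into the target protein.

    Pipeline: enumerate target triplets -> match against the database index ->
    align each hit FRASE by its triplet Calphas -> keep one pose per
    (frase id, fragment centroid) within ``dedupe_dist``.  The target
    environment of each pose is attached for scoring.
    """
    triplets = enumerate_triplets(target_protein.protein_residues, min_edge, max_edge)
    matches = match_triplets(triplets, db, edge_tol)
    kept: list[SeededFragment] = []
    centroids: dict[int, list[np.ndarray]] = {}
    for match in matches:
        frase = db.frases[match.frase_id]
        moved, rmsd = align_frase(frase, match)
        c = moved.fragment.centroid()
        dupes = centroids.setdefault(match.frase_id, [])
        if any(np.linalg.norm(c - prev) < dedupe_dist for prev in dupes):
            continue
        dupes.append(c)
        env = extract_environment(target_protein, moved.fragment, env_radius)
        kept.append(
            SeededFragment(fragment=moved.fragment, source_frase=match.frase_id,
                           alignment_rmsd=rmsd, environment=env)
        )
    return kept
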