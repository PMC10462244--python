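"""Synthetic structures with planted, known ground truth.

Real inputs to this pipeline are curated protein-ligand complexes; this
module builds small stand-ins where every quantity a test needs is known by
construction: proteins with planted residue triplets at chosen edge lengths,
complexes whose only valid fragment and environment are planted, class-
separable true/decoy FRASE sets for classifier checks, Gaussian feature
blobs for cluster recovery, and a filter test set with planted violations.
Residue side chains are minimal proxies (a few signature atoms), sufficient
for the typing and distance logic the algorithms actually consume.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .complex_io import AtomRecord, Complex, Residue, write_complex
from .frase_db import Fragment, Frase
from .nativeness import generate_decoys
from .pharmacophore import PharmFeature
from .triplet_screen import SeededFragment

__all__ = [
    "FixtureSpec",
    "make_planted_protein",
    "make_planted_complex",
    "apply_rigid_motion",
    "random_rotation",
    "make_separable_frase_set",
    "make_feature_blobs",
    "make_filter_testset",
    "mol_from_smiles_3d",
    "fragment_from_smiles",
    "write_fixture_bundle",
]

# Minimal side-chain proxies: atom name -> offset from Calpha (A).  Offsets
# are loosely bond-geometric; enough for typing and distance tests.
_RING = [np.array([2.4 + 1.39 * np.cos(a), 1.39 * np.sin(a), 0.0])
         for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
RESIDUE_PROXIES: dict[str, list[tuple[str, np.ndarray]]] = {
    "GLY": [],
    "ALA": [("CB", np.array([1.5, 0.0, 0.0]))],
    "SER": [("CB", np.array([1.5, 0.0, 0.0])), ("OG", np.array([2.2, 1.1, 0.0]))],
    "THR": [("CB", np.array([1.5, 0.0, 0.0])), ("OG1", np.array([2.2, 1.1, 0.0]))],
    "LYS": [("CB", np.array([1.5, 0.0, 0.0])), ("NZ", np.array([4.5, 0.8, 0.0]))],
    "ARG": [("CB", np.array([1.5, 0.0, 0.0])), ("NH1", np.array([4.8, 0.8, 0.0])),
            ("NH2", np.array([4.8, -0.8, 1.0]))],
    "ASP": [("CB", np.array([1.5, 0.0, 0.0])), ("OD1", np.array([2.8, 1.0, 0.0])),
            ("OD2", np.array([2.8, -1.0, 0.4]))],
    "GLU": [("CB", np.array([1.5, 0.0, 0.0])), ("OE1", np.array([3.9, 1.0, 0.0])),
            ("OE2", np.array([3.9, -1.0, 0.4]))],
    "ASN": [("CB", np.array([1.5, 0.0, 0.0])), ("OD1", np.array([2.8, 1.0, 0.0])),
            ("ND2", np.array([2.8, -1.0, 0.4]))],
    "PHE": [("CB", np.array([1.5, 0.0, 0.0]))]
    + [(nm, off) for nm, off in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _RING)],
    "TRP": [("CB", np.array([1.5, 0.0, 0.0])), ("CG", np.array([2.4, 0.8, 0.0])),
            ("CD1", np.array([3.3, 1.6, 0.0])), ("NE1", np.array([4.4, 1.0, 0.0])),
            ("CD2", np.array([3.2, -0.5, 0.0])), ("CE2", np.array([4.4, -0.3, 0.0]))],
    "LEU": [("CB", np.array([1.5, 0.0, 0.0])), ("CG", np.array([2.6, 1.0, 0.0])),
            ("CD1", np.array([3.9, 0.5, 0.0])), ("CD2", np.array([2.6, 2.0, 1.0]))],
    "VAL": [("CB", np.array([1.5, 0.0, 0.0])), ("CG1", np.array([2.6, 1.0, 0.0])),
            ("CG2", np.array([2.1, -1.2, 0.8]))],
}

_FILLER_NAMES = ("ALA", "LEU", "VAL", "GLY", "THR")


def _icosahedron() -> np.ndarray:
    """Unit-norm icosahedron vertices (12 points, well spread on the sphere)."""
    g = (1 + np.sqrt(5)) / 2
    raw = [v for s1 in (-1, 1) for s2 in (-1, 1)
           for v in ([0, s1, s2 * g], [s1, s2 * g, 0], [s1 * g, 0, s2])]
    pts = np.unique(np.round(np.array(raw, dtype=float), 6), axis=0)
    return pts / np.linalg.norm(pts[0])


def _cage_residues(center: np.ndarray, radius: float, chain: str,
                   first_seq: int) -> list[Residue]:
    """Glycine Calpha cage on a sphere; lines a pocket so fragments seeded at
    its center pass the collision and buriedness filters.  The radius stays
    under 4 A so no two cage atoms are 8+ A apart (no cage-only triplets)."""
    out = []
    for i, v in enumerate(_icosahedron()):
        out.append(_make_residue("GLY", center + radius * v, chain, first_seq + i))
    return out


@dataclass
class FixtureSpec:
    seed: int = 0
    n_residues: int = 12
    #: list of ((name1, name2, name3), (d01, d12, d02)) planted triplets
    planted_triplets: list[tuple[tuple[str, str, str], tuple[float, float, float]]] = field(
        default_factory=lambda: [(("TRP", "GLY", "ARG"), (10.0, 10.0, 10.0))]
    )
    noise: float = 0.0  # positional jitter sigma, A
    pocket_cages: bool = False  # line each planted pocket with a glycine cage


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return Q


def _triangle(edges: tuple[float, float, float]) -> np.ndarray:
    """Vertices of a triangle with |v0v1|, |v1v2|, |v0v2| = edges."""
    d01, d12, d02 = edges
    x = (d01 ** 2 + d02 ** 2 - d12 ** 2) / (2 * d01)
    y2 = d02 ** 2 - x ** 2
    if y2 <= 0:
        raise ValueError(f"edges {edges} violate the triangle inequality")
    return np.array([[0.0, 0.0, 0.0], [d01, 0.0, 0.0], [x, np.sqrt(y2), 0.0]])


def _make_residue(name: str, ca: np.ndarray, chain: str, seq: int,
                  rot: np.ndarray | None = None) -> Residue:
    rot = np.eye(3) if rot is None else rot
    atoms = [AtomRecord(element="C", coord=ca, residue_id=f"{chain}:{seq}", name="CA")]
    for atom_name, offset in RESIDUE_PROXIES.get(name, []):
        atoms.append(
            AtomRecord(element=atom_name[0], coord=ca + rot @ offset,
                       residue_id=f"{chain}:{seq}", name=atom_name)
        )
    return Residue(name=name, chain=chain, seq_index=seq, ca_coord=ca, atoms=atoms)


def make_planted_protein(spec: FixtureSpec) -> Complex:
    """A synthetic protein whose only qualifying triplets are the planted ones.

    Each planted triplet is laid out at its requested Calpha edge lengths in
    its own region (regions 60 A apart); filler residues are placed on a
    sparse grid with >=13 A spacing so they can form no triplet of their own
    and none with the planted residues.
    """
    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    seq = 1
    for t_idx, (names, edges) in enumerate(spec.planted_triplets):
        verts = _triangle(edges) + np.array([60.0 * t_idx, 0.0, 0.0])
        for name, v in zip(names, verts):
            ca = v + rng.normal(scale=spec.noise, size=3)
            residues.append(_make_residue(name, ca, "A", seq, random_rotation(rng)))
            seq += 1
        if spec.pocket_cages:
            cage = _cage_residues(verts.mean(axis=0), 4.0, "A", seq)
            residues.extend(cage)
            seq += len(cage)
    n_fill = max(0, spec.n_residues - seq + 1)
    base = np.array([0.0, 80.0, 0.0])
    for i in range(n_fill):
        ca = base + np.array([15.0 * (i % 5), 15.0 * (i // 5), 0.0])
        ca = ca + rng.normal(scale=spec.noise, size=3)
        name = _FILLER_NAMES[i % len(_FILLER_NAMES)]
        residues.append(_make_residue(name, ca, "A", seq, random_rotation(rng)))
        seq += 1
    return Complex(protein_residues=residues, ligand_atoms=[], ligand_mol=None,
                   provenance=f"planted-{spec.seed}")


def mol_from_smiles_3d(smiles: str, seed: int = 0) -> Chem.Mol:
    """An RDKit molecule with a deterministic 3D conformer (heavy atoms only)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return Chem.RemoveHs(mol)


def fragment_from_smiles(smiles: str, seed: int = 0, name: str = "") -> Fragment:
    mol = mol_from_smiles_3d(smiles, seed)
    return Fragment(mol=mol, mol_weight=Descriptors.MolWt(mol),
                    parent_ligand=name or smiles)


def apply_rigid_motion(cx: Complex, R: np.ndarray, t: np.ndarray) -> Complex:
    """Rigidly move a whole complex (protein and ligand)."""
    from .triplet_screen import _transform_residue, transform_fragment

    residues = [_transform_residue(r, R, t) for r in cx.protein_residues]
    lig_atoms = [AtomRecord(element=a.element, coord=R @ a.coord + t,
                            residue_id=a.residue_id, name=a.name,
                            is_hydrogen=a.is_hydrogen) for a in cx.ligand_atoms]
    mol = cx.ligand_mol
    if mol is not None and mol.GetNumConformers():
        frag = transform_fragment(Fragment(mol, 0.0), R, t)
        mol = frag.mol
    return Complex(protein_residues=residues, ligand_atoms=lig_atoms,
                   ligand_mol=mol, provenance=cx.provenance + ":moved")


def make_planted_complex(
    seed: int = 0,
    ligand_smiles: str = "c1ccccc1",
    triplet_names: tuple[str, str, str] = ("TRP", "GLY", "ARG"),
    edges: tuple[float, float, float] = (10.0, 10.0, 10.0),
    cage: bool = False,
) -> Complex:
    """A complex whose ligand sits at the centroid of one planted triplet.

    The three triplet residues get an extra pocket-lining CB atom pulled to
    ~4 A of the ligand so they all belong to the fragment's environment.
    """
    rng = np.random.default_rng(seed)
    verts = _triangle(edges)
    center = verts.mean(axis=0)
    mol = mol_from_smiles_3d(ligand_smiles, seed)
    conf = mol.GetConformer()
    lig_centroid = np.array([list(conf.GetAtomPosition(i))
                             for i in range(mol.GetNumAtoms())]).mean(axis=0)
    shift = center - lig_centroid
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (np.array([p.x, p.y, p.z]) + shift).tolist())

    residues = []
    for seq, (name, v) in enumerate(zip(triplet_names, verts), start=1):
        res = _make_residue(name, v, "A", seq, random_rotation(rng))
        toward = (center - v) / np.linalg.norm(center - v)
        # unique name: a second "CB" would collide with the proxy side chain
        pocket_atom = AtomRecord(element="C", coord=v + toward * (np.linalg.norm(center - v) - 4.0),
                                 residue_id=f"A:{seq}", name="CP")
        res.atoms.append(pocket_atom)
        residues.append(res)
    if cage:
        residues.extend(_cage_residues(center, 4.0, "A", len(residues) + 1))
    from .complex_io import mol_to_atom_records

    return Complex(protein_residues=residues,
                   ligand_atoms=mol_to_atom_records(mol), ligand_mol=mol,
                   provenance=f"planted-complex-{seed}")


# ---------------------------------------------------------------------------
# Separable FRASE sets for classifier checks
# ---------------------------------------------------------------------------

_FRAGMENT_POOL = (
    "c1ccccc1",        # benzene
    "Oc1ccccc1",       # phenol
    "CC(=O)[O-]",      # acetate
    "CCN",             # ethylamine
    "CCO",             # ethanol
    "CC(N)=O",         # acetamide
    "c1ccncc1",        # pyridine
    "CCCC",            # butane
)


def _contact_residue(name: str, contact_atom: str, target: np.ndarray,
                     direction: np.ndarray, dist: float, chain: str, seq: int) -> Residue:
    """A proxy residue whose named atom sits ``dist`` from ``target`` along
    ``direction``, with the Calpha pushed further out along the same line."""
    contact_pos = target + direction * dist
    ca = target + direction * (dist + 4.0)
    atoms = [AtomRecord(element="C", coord=ca, residue_id=f"{chain}:{seq}", name="CA"),
             AtomRecord(element=contact_atom[0], coord=contact_pos,
                        residue_id=f"{chain}:{seq}", name=contact_atom)]
    return Residue(name=name, chain=chain, seq_index=seq, ca_coord=ca, atoms=atoms)


def make_separable_frase_set(
    n_true: int = 500,
    multiplicity: int = 2,
    seed: int = 0,
) -> tuple[list[Frase], list[Frase]]:
    """Class-separable true FRASEs and fragment-shuffled decoys.

    Every true FRASE plants complementary short contacts: an acceptor-bearing
    serine OG at 2.8-3.5 A from a fragment polar atom (or, failing that, a
    hydrophobic leucine carbon near an apolar atom) plus an aromatic
    phenylalanine ring stacked near any fragment ring.  Decoys pair the same
    environments with shuffled fragments, scrambling the contact chemistry.
    """
    from .complex_io import assign_ligand_atom_types

    rng = np.random.default_rng(seed)
    mol_cache = {s: mol_from_smiles_3d(s, seed=seed + k)
                 for k, s in enumerate(_FRAGMENT_POOL)}
    truths: list[Frase] = []
    for i in range(n_true):
        smi = _FRAGMENT_POOL[int(rng.integers(len(_FRAGMENT_POOL)))]
        mol = Chem.Mol(mol_cache[smi])
        frag = Fragment(mol=mol, mol_weight=Descriptors.MolWt(mol), parent_ligand=smi)
        R = random_rotation(rng)
        c = frag.centroid()
        from .triplet_screen import transform_fragment

        frag = transform_fragment(frag, R, -R @ c)  # random orientation at origin
        typed = assign_ligand_atom_types(frag.mol)
        conf = frag.mol.GetConformer()
        env: list[Residue] = []
        seq = 1
        polar = [t for t in typed
                 if {"H-bond Donor", "H-bond Acceptor"} & t.types]
        apolar = [t for t in typed if "Aliphatic Carbon" in t.types]
        anchors = polar[:2] if polar else apolar[:2]
        for ta in anchors:
            direction = ta.atom.coord - frag.centroid()
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
            dist = float(rng.uniform(2.8, 3.5))
            if ta in polar:
                env.append(_contact_residue("SER", "OG", ta.atom.coord, direction, dist, "A", seq))
            else:
                env.append(_contact_residue("LEU", "CD1", ta.atom.coord, direction, dist, "A", seq))
            seq += 1
        rings = frag.mol.GetRingInfo().AtomRings()
        if rings:
            pts = np.array([list(conf.GetAtomPosition(j)) for j in rings[0]])
            ring_center = pts.mean(axis=0)
            normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            normal /= np.linalg.norm(normal)
            stack = ring_center + normal * float(rng.uniform(3.4, 3.9))
            res = _make_residue("PHE", stack + np.array([4.0, 0.0, 0.0]), "A", seq)
            # pull the proxy ring onto the stacking position
            delta = stack - np.mean([a.coord for a in res.atoms if a.name.startswith(("CG", "CD", "CE", "CZ"))], axis=0)
            for a in res.atoms:
                if a.name != "CA":
                    a.coord = a.coord + delta
            env.append(res)
        truths.append(Frase(fragment=frag, environment=env, label="true",
                            provenance=f"separable:{i}", frase_id=i))
    decoys = generate_decoys(truths, multiplicity=multiplicity, seed=seed + 1)
    return truths, decoys


# ---------------------------------------------------------------------------
# Feature blobs and filter test set
# ---------------------------------------------------------------------------


def make_feature_blobs(
    k_blobs: int = 3,
    per_blob: int = 20,
    sigma: float = 0.5,
    min_sep: float = 8.0,
    seed: int = 0,
    ftype: str = "HBA",
) -> tuple[list[PharmFeature], np.ndarray]:
    """Gaussian blobs of same-typed features; returns (features, true centers)."""
    rng = np.random.default_rng(seed)
    centers = np.array([[min_sep * 1.25 * i, 0.0, 0.0] for i in range(k_blobs)])
    feats = []
    for c in centers:
        for _ in range(per_blob):
            feats.append(PharmFeature(ftype, tuple(c + rng.normal(scale=sigma, size=3)),
                                      source_fragment="blob"))
    return feats, centers


def _point_fragment(pos: np.ndarray) -> Fragment:
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(6))
    m = mol.GetMol()
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, pos.tolist())
    m.AddConformer(conf)
    Chem.SanitizeMol(m)
    return Fragment(mol=m, mol_weight=16.04, parent_ligand="probe")


def make_filter_testset(seed: int = 0) -> tuple[Complex, list[SeededFragment], set[int]]:
    """20 seeded fragments with planted filter violations.

    The protein is a 14-atom cage of glycine Calphas 3 A around a pocket
    center.  Five fragments collide (0.5 A from a cage atom), five are fully
    exposed (20+ A away), five sit in the pocket but carry a sub-threshold
    score, and five are clean.  Returns (protein, seeded set, indices of the
    fragments that should survive).
    """
    rng = np.random.default_rng(seed)
    cage = 3.0 * _icosahedron()
    residues = [
        _make_residue("GLY", p, "A", i + 1) for i, p in enumerate(cage)
    ]
    protein = Complex(protein_residues=residues, ligand_atoms=[],
                      ligand_mol=None, provenance="filter-cage")

    seeded: list[SeededFragment] = []
    expected: set[int] = set()
    jitter = lambda: rng.normal(scale=0.05, size=3)  # noqa: E731
    for i in range(20):
        kind = i % 4
        if kind == 0:  # clean: pocket center, good score
            pos, sc = np.zeros(3) + jitter(), 0.9
            expected.add(i)
        elif kind == 1:  # collision: 0.5 A from a cage atom
            atom = cage[int(rng.integers(len(cage)))]
            pos, sc = atom * (1 - 0.5 / 3.0) + jitter() * 0.0, 0.9
        elif kind == 2:  # exposed: far outside the cage
            pos, sc = np.array([25.0, 0.0, 0.0]) + jitter(), 0.9
        else:  # low score: clean pose, score under threshold
            pos, sc = np.zeros(3) + jitter(), 0.1
        seeded.append(SeededFragment(fragment=_point_fragment(pos),
                                     source_frase=i, alignment_rmsd=0.0, score=sc))
    return protein, seeded, expected


# ---------------------------------------------------------------------------
# Bundles on disk
# ---------------------------------------------------------------------------


#: (ligand SMILES, triplet residue names, Calpha edge lengths) per demo complex
BUNDLE_COMPLEXES = (
    ("c1ccccc1", ("TRP", "GLY", "ARG"), (10.0, 10.0, 10.0)),
    ("Oc1ccccc1", ("SER", "PHE", "LYS"), (9.0, 11.0, 10.0)),
    ("c1ccncc1", ("ASP", "LEU", "THR"), (11.0, 9.5, 10.5)),
)


def write_fixture_bundle(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a self-describing fixture bundle (PDB/SDF + ground-truth JSON).

    Emits one complex per entry of :data:`BUNDLE_COMPLEXES` (distinct ligands,
    so decoy shuffling is possible) under ``complexes/`` and a target protein
    carrying all the planted triplets.
    """
    out = Path(out_dir)
    cdir = out / "complexes"
    cdir.mkdir(parents=True, exist_ok=True)
    for i, (smi, names, edges) in enumerate(BUNDLE_COMPLEXES):
        cx = make_planted_complex(seed=seed + i, ligand_smiles=smi,
                                  triplet_names=names, edges=edges, cage=True)
        write_complex(cx, cdir / f"c{i}.pdb")
        writer = Chem.SDWriter(str(cdir / f"c{i}_ligand.sdf"))
        writer.write(cx.ligand_mol)
        writer.close()
    spec = FixtureSpec(
        seed=seed,
        n_residues=3 * len(BUNDLE_COMPLEXES) + 3,
        planted_triplets=[(names, edges) for _, names, edges in BUNDLE_COMPLEXES],
        pocket_cages=True,
    )
    target = make_planted_protein(spec)
    write_complex(target, out / "target.pdb")
    truth = {
        "seed": seed,
        "complexes": [{"ligand": smi, "triplet": list(n), "edges": list(e)}
                      for smi, n, e in BUNDLE_COMPLEXES],
        "target": {"planted_triplets": [[list(n), list(e)] for n, e in spec.planted_triplets],
                   "n_residues": spec.n_residues},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
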