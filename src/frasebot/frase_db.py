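"""Building, persisting, and loading the fragment-in-environment database.

A FRASE couples a ligand fragment (50-300 Da, produced by cutting acyclic
single bonds while keeping ring systems whole) with its structural
environment: every protein residue having at least one heavy atom within
4.5 A of the fragment.  The database stores one record per fragment +
environment pair as an SDF V2000 file with the environment serialized in
property tags, plus a JSON sidecar carrying the residue-triplet fingerprint
index used for fast screening.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy.spatial.distance import cdist

from .complex_io import AtomRecord, Complex, Residue

__all__ = [
    "Fragment",
    "Frase",
    "FraseDB",
    "fragment_ligand",
    "extract_environment",
    "build_frase_db",
    "write_db",
    "read_db",
    "DBError",
]

logger = logging.getLogger(__name__)

MARKER_PROP = "_frasebot_marker"


class DBError(RuntimeError):
    """Raised on database persistence failures (e.g. checksum mismatch)."""


@dataclass
class Fragment:
    """A ligand fragment with 3D coordinates inherited from its parent.

    ``attachment_points`` are fragment-atom indices where bonds were cut;
    marker atoms (carbon-like placeholders standing for the first atom of a
    cut substituent on a ring) are flagged with an RDKit atom property and
    contribute to molecular weight and geometry but never to atom typing.
    """

    mol: Chem.Mol
    mol_weight: float
    parent_ligand: str = ""
    attachment_points: tuple[int, ...] = ()
    parent_atom_indices: frozenset[int] = frozenset()

    def heavy_coords(self) -> np.ndarray:
        if self.mol.GetNumAtoms() == 0:
            return np.empty((0, 3))
        conf = self.mol.GetConformer()
        pts = [
            list(conf.GetAtomPosition(a.GetIdx()))
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() > 1
        ]
        return np.asarray(pts, dtype=float)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def translate(self, shift: np.ndarray) -> "Fragment":
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (np.array([p.x, p.y, p.z]) + shift).tolist())
        return Fragment(mol, self.mol_weight, self.parent_ligand,
                        self.attachment_points, self.parent_atom_indices)


@dataclass
class Frase:
    fragment: Fragment
    environment: list[Residue]
    label: str | None = None  # "true" | "decoy" | None (unscored)
    provenance: str = ""
    frase_id: int | None = None


@dataclass
class FraseDB:
    frases: list[Frase] = field(default_factory=list)
    #: canonical triplet fingerprint (bytes) -> list of (frase_id, triplet)
    triplet_index: dict[bytes, list] = field(default_factory=dict)

    def build_index(self) -> None:
        from .triplet_screen import enumerate_triplets

        self.triplet_index = {}
        for frase in self.frases:
            for trip in enumerate_triplets(frase.environment):
                self.triplet_index.setdefault(trip.canonical_key, []).append(
                    (frase.frase_id, trip)
                )

    def index_digest(self) -> str:
        h = hashlib.sha1()
        for key in sorted(self.triplet_index):
            h.update(key)
            h.update(len(self.triplet_index[key]).to_bytes(4, "little"))
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


def _components(n_atoms: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(n_atoms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for i in range(n_atoms):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def _build_fragment(parent: Chem.Mol, atom_set: frozenset[int], parent_name: str) -> Fragment | None:
    conf = parent.GetConformer()
    em = Chem.RWMol()
    new_idx: dict[int, int] = {}
    coords: list[list[float]] = []
    for idx in sorted(atom_set):
        src = parent.GetAtomWithIdx(idx)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetIsAromatic(src.GetIsAromatic())
        new_idx[idx] = em.AddAtom(atom)
        coords.append(list(conf.GetAtomPosition(idx)))
    for bond in parent.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in atom_set and b in atom_set:
            em.AddBond(new_idx[a], new_idx[b], bond.GetBondType())

    # cut bonds: keep the alpha atom of a substituent cut off a ring atom
    attach: list[int] = []
    ring_info = parent.GetRingInfo()
    for bond in parent.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for inside, outside in ((a, b), (b, a)):
            if inside in atom_set and outside not in atom_set:
                attach.append(new_idx[inside])
                if ring_info.NumAtomRings(inside) > 0:
                    marker = Chem.Atom(6)
                    marker.SetProp(MARKER_PROP, "1")
                    mi = em.AddAtom(marker)
                    em.AddBond(new_idx[inside], mi, Chem.BondType.SINGLE)
                    coords.append(list(conf.GetAtomPosition(outside)))
    mol = em.GetMol()
    cc = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        cc.SetAtomPosition(i, xyz)
    mol.AddConformer(cc)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        try:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            )
        except Exception:
            return None
    return Fragment(
        mol=mol,
        mol_weight=Descriptors.MolWt(mol),
        parent_ligand=parent_name,
        attachment_points=tuple(sorted(set(attach))),
        parent_atom_indices=atom_set,
    )


def fragment_ligand(
    ligand: Chem.Mol,
    min_mw: float = 50.0,
    max_mw: float = 300.0,
    max_cuts: int = 3,
    parent_name: str = "",
) -> list[Fragment]:
    """Enumerate fragments by breaking subsets of acyclic single bonds.

    Every connected piece obtainable by deleting up to ``max_cuts`` acyclic
    single bonds is a candidate; pieces are deduplicated by parent atom set
    and kept when their molecular weight (implicit hydrogens included) lies
    in ``[min_mw, max_mw]``.  Ring bonds are never broken, so any ring that
    intersects a fragment is wholly contained in it.  When a cut removes a
    substituent from a ring atom, the substituent's first atom is retained as
    a carbon-like marker.
    """
    heavy = Chem.RemoveHs(ligand)
    cuttable = [
        b.GetIdx()
        for b in heavy.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]
    seen: set[frozenset[int]] = set()
    out: list[Fragment] = []
    n = heavy.GetNumAtoms()
    all_edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetIdx()) for b in heavy.GetBonds()]
    for k in range(0, min(max_cuts, len(cuttable)) + 1):
        for cut in itertools.combinations(cuttable, k):
            cut_set = set(cut)
            edges = [(a, b) for a, b, i in all_edges if i not in cut_set]
            for comp in _components(n, edges):
                key = frozenset(comp)
                if key in seen:
                    continue
                seen.add(key)
                frag = _build_fragment(heavy, key, parent_name)
                if frag is not None and min_mw <= frag.mol_weight <= max_mw:
                    out.append(frag)
    return out


# ---------------------------------------------------------------------------
# Environment extraction and DB construction
# ---------------------------------------------------------------------------


def extract_environment(
    cx: Complex, fragment: Fragment, radius: float = 4.5
) -> list[Residue]:
    """Residues of ``cx`` with >=1 heavy atom within ``radius`` of the fragment."""
    fpts = fragment.heavy_coords()
    if fpts.size == 0:
        return []
    env = []
    for res in cx.protein_residues:
        rpts = res.heavy_coords()
        if rpts.size and cdist(rpts, fpts).min() <= radius:
            env.append(res)
    return env


def build_frase_db(
    complexes: list[Complex],
    min_mw: float = 50.0,
    max_mw: float = 300.0,
    radius: float = 4.5,
    max_cuts: int = 3,
    ligand_max_mw: float | None = None,
) -> FraseDB:
    """Fragment every complex's ligand and pair fragments with environments.

    Per-complex failures are logged and skipped.  ``ligand_max_mw`` optionally
    gates whole ligands by molecular weight before fragmentation.
    """
    db = FraseDB()
    for cx in complexes:
        try:
            if cx.ligand_mol is None:
                raise ValueError("complex has no ligand connectivity")
            if ligand_max_mw is not None and Descriptors.MolWt(cx.ligand_mol) > ligand_max_mw:
                continue
            for frag in fragment_ligand(cx.ligand_mol, min_mw, max_mw, max_cuts,
                                        parent_name=cx.provenance):
                env = extract_environment(cx, frag, radius)
                if env:
                    db.frases.append(
                        Frase(fragment=frag, environment=env, label="true",
                              provenance=cx.provenance, frase_id=len(db.frases))
                    )
        except Exception as exc:
            logger.warning("skipping complex %s: %s", cx.provenance, exc)
    db.build_index()
    return db


# ---------------------------------------------------------------------------
# Persistence (SDF + JSON sidecar)
# ---------------------------------------------------------------------------


def _residue_to_dict(res: Residue) -> dict:
    return {
        "name": res.name,
        "chain": res.chain,
        "seq": res.seq_index,
        "ca": None if res.ca_coord is None else [round(v, 3) for v in res.ca_coord],
        "atoms": [
            {"el": a.element, "nm": a.name, "xyz": [round(v, 3) for v in a.coord],
             "h": int(a.is_hydrogen)}
            for a in res.atoms
        ],
    }


def _residue_from_dict(d: dict) -> Residue:
    atoms = [
        AtomRecord(element=a["el"], coord=np.array(a["xyz"]),
                   residue_id=f"{d['chain']}:{d['seq']}", name=a["nm"],
                   is_hydrogen=bool(a["h"]))
        for a in d["atoms"]
    ]
    return Residue(name=d["name"], chain=d["chain"], seq_index=d["seq"],
                   ca_coord=None if d["ca"] is None else np.array(d["ca"]),
                   atoms=atoms)


def write_db(db: FraseDB, path: str | Path) -> None:
    """Write the database as SDF V2000 plus a ``.index.json`` sidecar."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for frase in db.frases:
        mol = Chem.Mol(frase.fragment.mol)
        markers = [a.GetIdx() for a in mol.GetAtoms() if a.HasProp(MARKER_PROP)]
        mol.SetProp("frasebot_id", str(frase.frase_id))
        mol.SetProp("frasebot_label", frase.label or "")
        mol.SetProp("frasebot_provenance", frase.provenance)
        mol.SetProp("frasebot_parent", frase.fragment.parent_ligand)
        mol.SetProp("frasebot_mw", f"{frase.fragment.mol_weight:.3f}")
        mol.SetProp("frasebot_markers", " ".join(map(str, markers)))
        mol.SetProp("frasebot_attach", " ".join(map(str, frase.fragment.attachment_points)))
        mol.SetProp("frasebot_environment",
                    json.dumps([_residue_to_dict(r) for r in frase.environment]))
        writer.write(mol)
    writer.close()
    sidecar = {
        "n_frases": len(db.frases),
        "index_digest": db.index_digest(),
        "entries": {
            key.hex(): [fid for fid, _ in vals] for key, vals in db.triplet_index.items()
        },
    }
    Path(str(path) + ".index.json").write_text(json.dumps(sidecar))


def read_db(path: str | Path) -> FraseDB:
    """Load a database written by :func:`write_db`; verifies the index digest."""
    path = Path(path)
    db = FraseDB()
    supp = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supp:
        if mol is None:
            logger.warning("skipping corrupt SDF record in %s", path)
            continue
        try:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            )
            markers = mol.GetProp("frasebot_markers").split()
            for i in markers:
                mol.GetAtomWithIdx(int(i)).SetProp(MARKER_PROP, "1")
            attach = tuple(int(i) for i in mol.GetProp("frasebot_attach").split())
            frag = Fragment(
                mol=mol,
                mol_weight=float(mol.GetProp("frasebot_mw")),
                parent_ligand=mol.GetProp("frasebot_parent"),
                attachment_points=attach,
            )
            env = [_residue_from_dict(d)
                   for d in json.loads(mol.GetProp("frasebot_environment"))]
            db.frases.append(
                Frase(fragment=frag, environment=env,
                      label=mol.GetProp("frasebot_label") or None,
                      provenance=mol.GetProp("frasebot_provenance"),
                      frase_id=int(mol.GetProp("frasebot_id")))
            )
        except Exception as exc:
            logger.warning("skipping corrupt record in %s: %s", path, exc)
    db.build_index()
    sidecar_path = Path(str(path) + ".index.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar["n_frases"] != len(db.frases) or sidecar["index_digest"] != db.index_digest():
            raise DBError(f"index checksum mismatch for {path}")
    return db
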