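"""Structure I/O and physicochemical typing.

This module reads and writes protein-ligand complexes (PDB for the protein,
PDB ``HETATM`` or SDF for the ligand), encodes residues as 11-bit many-hot
property strings, and assigns atoms the pharmacophoric types used by the
interaction fingerprint: a 29-label vocabulary on the ligand side and a
13-label vocabulary on the protein side.

All downstream geometry works on heavy atoms only; hydrogens are parsed but
flagged and excluded from distances, counts, and typing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds

__all__ = [
    "AtomRecord",
    "Residue",
    "TypedAtom",
    "Complex",
    "LIGAND_TYPES",
    "PROTEIN_TYPES",
    "STANDARD_RESIDUES",
    "DEFAULT_EXCLUDE",
    "FormatError",
    "SelectionError",
    "EncodingError",
    "TypingError",
    "load_residue_bits",
    "encode_residue",
    "read_complex",
    "write_complex",
    "mol_to_atom_records",
    "assign_ligand_atom_types",
    "assign_protein_atom_types",
]


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a ligand selector matches nothing."""


class EncodingError(KeyError):
    """Raised for residue names absent from the bit-string table."""


class TypingError(ValueError):
    """Raised when atom typing cannot proceed (e.g. missing connectivity)."""


#: Ligand-side atom-type vocabulary; list order fixes the fingerprint layout.
LIGAND_TYPES: tuple[str, ...] = (
    "Aromatic", "Hetero", "Halogen", "Negative Ionizable", "Positive Ionizable",
    "H-bond Donor", "H-bond Acceptor", "Amide Nitrogen", "Amine Nitrogen",
    "Vinyl", "Carboxylate Oxygen", "Alcohol Oxygen", "Nitro Oxygen",
    "Nitro Nitrogen", "Phosphate Oxygen", "Sulfone Sulfur", "Sulfoxide Sulfur",
    "Enol Oxygen", "Imine Nitrogen", "Enamine Nitrogen", "Aromatic Nitrogen",
    "Aromatic Oxygen", "Aromatic Sulfur", "Aromatic Carbon", "Aliphatic Carbon",
    "F", "Cl", "Br", "I",
)

#: Protein-side atom-type vocabulary.
PROTEIN_TYPES: tuple[str, ...] = (
    "Aromatic", "NegativeIonizable", "Positive Ionizable", "H-bond Donor",
    "H-bond Acceptor", "Amide Nitrogen", "Amine Nitrogen", "Carboxylate Oxygen",
    "Alcohol Oxygen", "Imine Nitrogen", "Aromatic Nitrogen", "Aromatic Carbon",
    "Aliphatic Carbon",
)

STANDARD_RESIDUES: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Waters and common crystallization additives dropped on read.
DEFAULT_EXCLUDE: frozenset[str] = frozenset(
    "HOH WAT DOD SO4 PO4 GOL EDO PEG PG4 DMS ACT FMT NO3 CL NA K MG CA ZN BR IOD".split()
)


@dataclass(eq=False)
class AtomRecord:
    element: str
    coord: np.ndarray
    residue_id: str = "ligand"
    name: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("coord must be 3 finite components")


@dataclass(eq=False)
class Residue:
    name: str
    chain: str
    seq_index: int
    ca_coord: np.ndarray | None
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    @property
    def key(self) -> str:
        return f"{self.chain}:{self.seq_index}:{self.name}"

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass(frozen=True, eq=False)
class TypedAtom:
    atom: AtomRecord
    types: frozenset[str]


@dataclass
class Complex:
    protein_residues: list[Residue]
    ligand_atoms: list[AtomRecord]
    ligand_mol: Chem.Mol | None = None
    provenance: str = ""

    @property
    def ligand_bonds(self) -> list[tuple[int, int, float, bool]]:
        """Bonds as (begin, end, order, in_ring); empty without connectivity."""
        if self.ligand_mol is None:
            return []
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.IsInRing())
            for b in self.ligand_mol.GetBonds()
        ]


# ---------------------------------------------------------------------------
# Residue 11-bit encoding
# ---------------------------------------------------------------------------

_DATA = importlib.resources.files("frasebot") / "data"
_tables: dict[str, dict] = {}


def _load_yaml(name: str) -> dict:
    if name not in _tables:
        _tables[name] = yaml.safe_load((_DATA / name).read_text())
    return _tables[name]


def load_residue_bits(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Load the 20-row residue bit-string table (the shipped one by default)."""
    raw = yaml.safe_load(Path(path).read_text()) if path else _load_yaml("residue_bits.yaml")
    table = {}
    for name, bits in raw.items():
        vec = np.asarray(bits, dtype=np.uint8)
        if vec.shape != (11,) or not np.isin(vec, (0, 1)).all():
            raise FormatError(f"bad bit string for {name}")
        table[name] = vec
    return table


def encode_residue(residue_name: str, table: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Return the 11-bit many-hot property vector for a standard residue.

    Positions 0-2 encode size and 3-5 hydrophobicity as 3-bit thermometers
    (all ones for tryptophan, all zeros for glycine); the remaining single
    bits flag H-bond acceptor/donor capability, positive/negative ionizable
    groups, and aromaticity of the side chain.
    """
    table = table if table is not None else load_residue_bits()
    try:
        return table[residue_name.upper()]
    except KeyError:
        raise EncodingError(f"no bit string for residue {residue_name!r}") from None


# ---------------------------------------------------------------------------
# Reading and writing complexes
# ---------------------------------------------------------------------------


def _mol_from_records(atoms: list[AtomRecord]) -> Chem.Mol | None:
    """Infer ligand connectivity from coordinates (PDB HETATM ligands)."""
    if not atoms:
        return None
    mol = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, rec in enumerate(atoms):
        mol.AddAtom(Chem.Atom(rec.element))
        conf.SetAtomPosition(i, rec.coord.tolist())
    m = mol.GetMol()
    m.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineConnectivity(m)
        Chem.SanitizeMol(
            m,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        )
    except Exception:
        return None
    return m


def read_complex(
    path: str | Path,
    ligand_selector: str | None = None,
    ligand_sdf: str | Path | None = None,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> Complex:
    """Read a protein(-ligand) complex from a PDB file.

    ``ligand_selector`` names the HETATM residue (e.g. ``"LIG"``) or a chain
    (``"chain:L"``) holding the ligand; ``ligand_sdf`` optionally supplies the
    ligand with full connectivity from an SDF/MOL file instead.  Waters and
    residues on the exclusion list are dropped.  Only the first model and the
    first alternate location are used.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    st.remove_alternative_conformations()

    want_chain = None
    if ligand_selector and ligand_selector.lower().startswith("chain:"):
        want_chain = ligand_selector.split(":", 1)[1]

    residues: list[Residue] = []
    ligand_records: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            is_ligand = (
                (want_chain is not None and chain.name == want_chain)
                or (want_chain is None and ligand_selector is not None and res.name == ligand_selector)
            )
            if is_ligand:
                for at in res:
                    ligand_records.append(
                        AtomRecord(
                            element=at.element.name,
                            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            residue_id="ligand",
                            name=at.name,
                            is_hydrogen=at.element.is_hydrogen,
                        )
                    )
                continue
            if res.name in exclude:
                continue
            rid = f"{chain.name}:{res.seqid.num}"
            recs = [
                AtomRecord(
                    element=at.element.name,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_id=rid,
                    name=at.name,
                    is_hydrogen=at.element.is_hydrogen,
                )
                for at in res
            ]
            ca = next((a.coord for a in recs if a.name == "CA"), None)
            residues.append(
                Residue(name=res.name, chain=chain.name, seq_index=res.seqid.num,
                        ca_coord=ca, atoms=recs)
            )

    if ligand_selector is not None and not ligand_records and ligand_sdf is None:
        raise SelectionError(f"selector {ligand_selector!r} matched nothing in {path}")

    mol: Chem.Mol | None = None
    if ligand_sdf is not None:
        supp = Chem.SDMolSupplier(str(ligand_sdf), removeHs=False)
        mol = next((m for m in supp if m is not None), None)
        if mol is None:
            raise FormatError(f"cannot parse ligand SDF {ligand_sdf}")
        ligand_records = mol_to_atom_records(mol)
    elif ligand_records:
        mol = _mol_from_records([r for r in ligand_records if not r.is_hydrogen])

    return Complex(
        protein_residues=residues,
        ligand_atoms=ligand_records,
        ligand_mol=mol,
        provenance=path.stem,
    )


def mol_to_atom_records(mol: Chem.Mol) -> list[AtomRecord]:
    """Convert an RDKit molecule with a conformer into AtomRecords."""
    if mol.GetNumConformers() == 0:
        raise FormatError("molecule has no 3D coordinates")
    conf = mol.GetConformer()
    out = []
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        out.append(
            AtomRecord(
                element=atom.GetSymbol(),
                coord=np.array([p.x, p.y, p.z]),
                residue_id="ligand",
                name=atom.GetSymbol() + str(atom.GetIdx() + 1),
                is_hydrogen=atom.GetAtomicNum() == 1,
            )
        )
    return out


def write_complex(cx: Complex, path: str | Path, ligand_resname: str = "LIG") -> None:
    """Write a complex to PDB (protein as ATOM, ligand as HETATM)."""
    lines = []
    serial = 1
    for res in cx.protein_residues:
        for at in res.atoms:
            lines.append(_pdb_line("ATOM", serial, at.name, res.name, res.chain,
                                   res.seq_index, at.coord, at.element))
            serial += 1
    for at in cx.ligand_atoms:
        lines.append(_pdb_line("HETATM", serial, at.name, ligand_resname, "X",
                               1, at.coord, at.element))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(rec, serial, name, resname, chain, seq, coord, element) -> str:
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{rec:<6s}{serial:>5d} {nm:<4s}{resname:>4s} {chain[:1]}{seq:>4d}    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

_smarts_cache: list[tuple[str, Chem.Mol, tuple[int, ...]]] | None = None


def _ligand_rules() -> list[tuple[str, Chem.Mol, tuple[int, ...]]]:
    global _smarts_cache
    if _smarts_cache is None:
        rules = []
        for rule in _load_yaml("ligand_type_smarts.yaml")["rules"]:
            patt = Chem.MolFromSmarts(rule["smarts"])
            if patt is None:
                raise FormatError(f"bad SMARTS {rule['smarts']!r}")
            rules.append((rule["type"], patt, tuple(rule.get("atoms", [0]))))
        _smarts_cache = rules
    return _smarts_cache


def assign_ligand_atom_types(mol: Chem.Mol, records: list[AtomRecord] | None = None) -> list[TypedAtom]:
    """Assign each heavy ligand atom zero or more of the 29 ligand labels.

    Typing is driven by the shipped SMARTS rules file; an atom matching several
    rules carries all their labels (the Kronecker-delta sum in the fingerprint
    accommodates multi-typing).  Attachment markers left by fragmentation
    (atom property ``_frasebot_marker``) are not typed.
    """
    if mol is None:
        raise TypingError("ligand connectivity unavailable; cannot type atoms")
    types: list[set[str]] = [set() for _ in range(mol.GetNumAtoms())]
    for label, patt, idxs in _ligand_rules():
        for match in mol.GetSubstructMatches(patt, uniquify=False):
            for i in idxs:
                types[match[i]].add(label)
    if records is None:
        records = mol_to_atom_records(mol)
    out = []
    for atom, rec in zip(mol.GetAtoms(), records):
        if atom.GetAtomicNum() == 1 or atom.HasProp("_frasebot_marker"):
            labels: frozenset[str] = frozenset()
        else:
            labels = frozenset(types[atom.GetIdx()])
        bad = labels - set(LIGAND_TYPES)
        if bad:
            raise TypingError(f"out-of-vocabulary ligand labels {bad}")
        out.append(TypedAtom(atom=rec, types=labels))
    return out


def assign_protein_atom_types(residues: list[Residue]) -> list[TypedAtom]:
    """Assign each heavy protein atom zero or more of the 13 protein labels.

    Uses per-residue side-chain templates plus backbone and element-default
    rules from the shipped template file.
    """
    tpl = _load_yaml("protein_atom_types.yaml")
    backbone = tpl["backbone"]
    side = tpl["side_chains"]
    defaults = tpl["element_defaults"]
    out = []
    for res in residues:
        res_tpl = side.get(res.name, {})
        for at in res.atoms:
            if at.is_hydrogen:
                out.append(TypedAtom(atom=at, types=frozenset()))
                continue
            if at.name in res_tpl:
                labels = res_tpl[at.name]
            elif at.name in backbone:
                labels = backbone[at.name]
            else:
                labels = defaults.get(at.element, [])
            labels = frozenset(labels)
            bad = labels - set(PROTEIN_TYPES)
            if bad:
                raise TypingError(f"out-of-vocabulary protein labels {bad}")
            out.append(TypedAtom(atom=at, types=labels))
    return out
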