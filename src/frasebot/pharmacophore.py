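"""Pharmacophore feature perception, clustering, and query assembly.

Surviving fragments are converted into typed 3D features -- H-bond donor
(HBD), H-bond acceptor (HBA), positive/negative ionizable (Pos/Neg),
aromatic (Ar, at ring centroids), and hydrophobic aliphatic (Hyd, at
centroids of connected aliphatic-carbon groups).  Features are clustered
per type with k-means, increasing k until every cluster's diameter (max
pairwise member distance) is within the bound (default 3 A); clusters are
ranked by size and the selected centroids become the pharmacophore query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .complex_io import assign_ligand_atom_types
from .frase_db import MARKER_PROP, Fragment

__all__ = [
    "FEATURE_TYPES",
    "PharmFeature",
    "FeatureCluster",
    "PharmacophoreQuery",
    "perceive_features",
    "cluster_features",
    "build_query",
    "export_query",
    "load_query",
    "SelectionError",
]

FEATURE_TYPES = ("HBD", "HBA", "Pos", "Neg", "Ar", "Hyd")

#: ligand atom-type label -> point feature type placed on the atom itself
_ATOM_FEATURES = {
    "H-bond Donor": "HBD",
    "H-bond Acceptor": "HBA",
    "Positive Ionizable": "Pos",
    "Negative Ionizable": "Neg",
}


class SelectionError(KeyError):
    pass


@dataclass(frozen=True)
class PharmFeature:
    ftype: str
    coord: tuple[float, float, float]
    source_fragment: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")


@dataclass
class FeatureCluster:
    ftype: str
    members: list[PharmFeature]
    centroid: np.ndarray
    cluster_id: int = 0  # 1-based rank after sorting by size

    @property
    def size(self) -> int:
        return len(self.members)

    def diameter(self) -> float:
        pts = np.array([m.coord for m in self.members])
        if len(pts) < 2:
            return 0.0
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        return float(d.max())


@dataclass
class PharmacophoreQuery:
    features: list[tuple[str, np.ndarray, float]]  # (type, centroid, radius)
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a pharmacophore query needs at least one feature")


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------


def perceive_features(fragment: Fragment, provenance: str = "") -> list[PharmFeature]:
    """Typed 3D pharmacophoric features of one fragment.

    Point features (HBD/HBA/Pos/Neg) sit on the qualifying atoms, reusing the
    ligand atom-typing rules; Ar features sit at aromatic-ring centroids; Hyd
    features at centroids of bond-connected groups of aliphatic carbons.
    Attachment markers contribute nothing.
    """
    mol = fragment.mol
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    typed = assign_ligand_atom_types(mol)
    out: list[PharmFeature] = []
    for i, ta in enumerate(typed):
        for label, ftype in _ATOM_FEATURES.items():
            if label in ta.types:
                out.append(PharmFeature(ftype, tuple(coords[i]), provenance))

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            out.append(PharmFeature("Ar", tuple(coords[list(ring)].mean(axis=0)), provenance))

    aliph = {
        a.GetIdx()
        for a, ta in zip(mol.GetAtoms(), typed)
        if "Aliphatic Carbon" in ta.types and not a.HasProp(MARKER_PROP)
    }
    seen: set[int] = set()
    for start in sorted(aliph):
        if start in seen:
            continue
        group, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            group.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() in aliph and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        out.append(PharmFeature("Hyd", tuple(coords[group].mean(axis=0)), provenance))
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _diameter_ok(pts: np.ndarray, labels: np.ndarray, k: int, bound: float) -> bool:
    for c in range(k):
        sub = pts[labels == c]
        if len(sub) > 1:
            d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
            if d.max() > bound + 1e-9:
                return False
    return True


def cluster_features(
    features: list[PharmFeature],
    max_diameter: float = 3.0,
    seed: int = 0,
) -> list[FeatureCluster]:
    """Per-type k-means with an emergent k satisfying the diameter bound.

    For each feature type, k grows from 1 until every cluster's max pairwise
    member distance is within ``max_diameter`` (singletons always qualify, so
    termination is guaranteed).  The returned clusters are sorted by size
    descending, ties broken by compactness (smaller mean distance to
    centroid), and numbered from 1.
    """
    clusters: list[FeatureCluster] = []
    for ftype in FEATURE_TYPES:
        feats = [f for f in features if f.ftype == ftype]
        if not feats:
            continue
        pts = np.array([f.coord for f in feats])
        for k in range(1, len(feats) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pts)
            if _diameter_ok(pts, km.labels_, k, max_diameter):
                break
        for c in range(k):
            members = [f for f, lbl in zip(feats, km.labels_) if lbl == c]
            if members:
                centroid = np.array([m.coord for m in members]).mean(axis=0)
                clusters.append(FeatureCluster(ftype, members, centroid))

    def sort_key(cl: FeatureCluster):
        spread = float(np.mean(np.linalg.norm(
            np.array([m.coord for m in cl.members]) - cl.centroid, axis=1)))
        return (-cl.size, spread)

    clusters.sort(key=sort_key)
    for rank, cl in enumerate(clusters, start=1):
        cl.cluster_id = rank
    return clusters


def build_query(
    clusters: list[FeatureCluster],
    selected_ids: list[int],
    tolerance: float = 1.5,
) -> PharmacophoreQuery:
    """Assemble a query from chosen cluster centroids (ids are 1-based ranks).

    Which clusters make the query is an explicit user choice, typically
    guided by pocket adjacency of the top-ranked centroids.
    """
    if not selected_ids:
        raise SelectionError("no clusters selected")
    by_id = {cl.cluster_id: cl for cl in clusters}
    feats = []
    for cid in selected_ids:
        if cid not in by_id:
            raise SelectionError(f"unknown cluster id {cid}")
        cl = by_id[cid]
        feats.append((cl.ftype, cl.centroid.copy(), tolerance))
    return PharmacophoreQuery(features=feats, provenance=list(selected_ids))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_query(query: PharmacophoreQuery, path: str | Path, fmt: str = "json") -> None:
    """Write a query as canonical JSON or a simple one-feature-per-line text."""
    path = Path(path)
    if fmt == "json":
        doc = {
            "features": [
                {"type": t, "x": round(float(c[0]), 4), "y": round(float(c[1]), 4),
                 "z": round(float(c[2]), 4), "radius": float(r)}
                for t, c, r in query.features
            ],
            "provenance": query.provenance,
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    elif fmt == "txt":
        lines = [f"{t} {c[0]:.4f} {c[1]:.4f} {c[2]:.4f} {r:.3f}"
                 for t, c, r in query.features]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_query(path: str | Path) -> PharmacophoreQuery:
    doc = json.loads(Path(path).read_text())
    feats = [
        (f["type"], np.array([f["x"], f["y"], f["z"]]), float(f["radius"]))
        for f in doc["features"]
    ]
    return PharmacophoreQuery(features=feats, provenance=list(doc.get("provenance", [])))
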