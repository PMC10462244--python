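"""Interaction fingerprints and the pose-nativeness classifier.

Each fragment-environment pair is featurized into a 377-element vector: one
element per (ligand atom type, protein atom type) pair, 29 x 13 types.  The
element for type pair (m, n) sums a Gaussian distance weight over all ligand
atoms of type m and protein atoms of type n,

    f_mn = sum_i sum_j  delta_mi * delta_nj * w(d_ij),
    w(d) = exp(-(d - 3)^2)  for d <= 10 A, else 0,

so contacts near the 3 A interaction optimum dominate.  A small dense network
(377 -> 32 ReLU -> 16 ReLU -> 1 sigmoid, binary cross-entropy, Adam, batch
50) is trained to separate true pairs from decoys obtained by shuffling
fragments between environments; its output is the nativeness score in (0,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .complex_io import (
    LIGAND_TYPES,
    PROTEIN_TYPES,
    assign_ligand_atom_types,
    assign_protein_atom_types,
)
from .frase_db import Frase

__all__ = [
    "N_FEATURES",
    "feature_index",
    "distance_weight",
    "interaction_fingerprint",
    "featurize",
    "generate_decoys",
    "TrainConfig",
    "NativenessModel",
    "train_model",
    "score",
    "FeaturizationError",
    "DecoyError",
    "TrainingError",
]

N_FEATURES = len(LIGAND_TYPES) * len(PROTEIN_TYPES)

_LIG_INDEX = {t: i for i, t in enumerate(LIGAND_TYPES)}
_PROT_INDEX = {t: i for i, t in enumerate(PROTEIN_TYPES)}

DEFAULT_OPTIMUM = 3.0  # A, distance of maximal weight
DEFAULT_CUTOFF = 10.0  # A, weight is zero beyond this


class FeaturizationError(ValueError):
    pass


class DecoyError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


def feature_index(ligand_type: str, protein_type: str) -> int:
    """Position of the (ligand type, protein type) pair in the 377-vector."""
    return _LIG_INDEX[ligand_type] * len(PROTEIN_TYPES) + _PROT_INDEX[protein_type]


def distance_weight(
    d: np.ndarray,
    optimum: float = DEFAULT_OPTIMUM,
    cutoff: float = DEFAULT_CUTOFF,
    hard_count: bool = False,
) -> np.ndarray:
    """Gaussian interaction weight, or a 0/1 contact count within 5 A."""
    d = np.asarray(d, float)
    if hard_count:
        return (d <= 5.0).astype(float)
    return np.where(d <= cutoff, np.exp(-((d - optimum) ** 2)), 0.0)


def interaction_fingerprint(
    frase: Frase,
    optimum: float = DEFAULT_OPTIMUM,
    cutoff: float = DEFAULT_CUTOFF,
    hard_count: bool = False,
) -> np.ndarray:
    """The 377-element distance-weighted type-pair fingerprint of a FRASE.

    Multi-typed atoms contribute to every matching element.  Hydrogens and
    fragment attachment markers contribute nothing.
    """
    try:
        lig_typed = assign_ligand_atom_types(frase.fragment.mol)
    except Exception as exc:
        raise FeaturizationError(f"cannot type ligand: {exc}") from exc
    prot_typed = assign_protein_atom_types(frase.environment)

    lig = [(ta.atom.coord, [_LIG_INDEX[t] for t in ta.types]) for ta in lig_typed if ta.types]
    prot = [(ta.atom.coord, [_PROT_INDEX[t] for t in ta.types]) for ta in prot_typed if ta.types]
    out = np.zeros(N_FEATURES)
    if not lig or not prot:
        return out
    L = np.zeros((len(lig), len(LIGAND_TYPES)))
    for i, (_, ts) in enumerate(lig):
        L[i, ts] = 1.0
    P = np.zeros((len(prot), len(PROTEIN_TYPES)))
    for j, (_, ts) in enumerate(prot):
        P[j, ts] = 1.0
    D = cdist(np.array([c for c, _ in lig]), np.array([c for c, _ in prot]))
    W = distance_weight(D, optimum, cutoff, hard_count)
    return (L.T @ W @ P).ravel()


def featurize(frases: list[Frase], **kwargs) -> np.ndarray:
    return np.array([interaction_fingerprint(f, **kwargs) for f in frases])


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------


def generate_decoys(
    frases: list[Frase],
    multiplicity: int = 2,
    seed: int = 0,
    random_rotation: bool = False,
) -> list[Frase]:
    """Decoys by shuffling fragments between FRASEs.

    Each true FRASE yields ``multiplicity`` decoys pairing its environment
    with a fragment drawn uniformly from a *different* FRASE; the foreign
    fragment is translated so its centroid matches the native fragment's
    centroid (optionally also randomly rotated about it).
    """
    from rdkit import Chem

    if len(frases) < 2:
        raise DecoyError("need at least 2 FRASEs to shuffle fragments")
    smiles = {Chem.MolToSmiles(Chem.RemoveHs(f.fragment.mol)) for f in frases}
    if len(smiles) < 2:
        raise DecoyError("all fragments identical; decoys would equal truths")
    rng = np.random.default_rng(seed)
    decoys = []
    for i, frase in enumerate(frases):
        native_centroid = frase.fragment.centroid()
        for _ in range(multiplicity):
            j = int(rng.integers(len(frases) - 1))
            if j >= i:
                j += 1
            foreign = frases[j].fragment
            moved = foreign.translate(native_centroid - foreign.centroid())
            if random_rotation:
                from .triplet_screen import transform_fragment

                A = rng.normal(size=(3, 3))
                Q, _ = np.linalg.qr(A)
                if np.linalg.det(Q) < 0:
                    Q[:, 0] *= -1
                c = moved.centroid()
                moved = transform_fragment(moved, Q, c - Q @ c)
            decoys.append(
                Frase(fragment=moved, environment=frase.environment,
                      label="decoy", provenance=f"decoy:{i}<-{j}", frase_id=None)
            )
    return decoys


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    hidden: tuple[int, int] = (32, 16)
    batch_size: int = 50
    epochs: int = 500
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    hard_count: bool = False


@dataclass
class NativenessModel:
    """Trained nativeness classifier with its input standardization."""

    scaler: StandardScaler
    net: MLPClassifier
    config: TrainConfig = field(default_factory=TrainConfig)
    accuracy: float = float("nan")

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        return self.net.predict_proba(self.scaler.transform(X))[:, 1]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "NativenessModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TrainingError(f"{path} does not hold a NativenessModel")
        return model


def train_model(
    true_frases: list[Frase],
    decoys: list[Frase],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> NativenessModel:
    """Train the nativeness network and report held-out accuracy.

    Featurizes both classes, holds out ``val_fraction`` of the pool (split by
    FRASE, seeded), z-scales features on the training part, and fits the
    dense network.  The scaler is stored with the model.
    """
    config = config or TrainConfig()
    if not true_frases or not decoys:
        raise TrainingError("both classes must be non-empty")
    X = featurize(true_frases + decoys, hard_count=config.hard_count)
    y = np.concatenate([np.ones(len(true_frases)), np.zeros(len(decoys))])
    X_train, X_val, y_train, y_val = train_test_split(
        X, y, test_size=config.val_fraction, random_state=seed, stratify=y
    )
    scaler = StandardScaler().fit(X_train)
    net = MLPClassifier(
        hidden_layer_sizes=config.hidden,
        activation="relu",
        solver="adam",
        batch_size=config.batch_size,
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=seed,
        shuffle=True,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at low epoch counts
        net.fit(scaler.transform(X_train), y_train)
    if not np.isfinite(net.loss_):
        raise TrainingError("training diverged (non-finite loss)")
    acc = float(net.score(scaler.transform(X_val), y_val))
    return NativenessModel(scaler=scaler, net=net, config=config, accuracy=acc)


def score(model: NativenessModel, frase: Frase) -> float:
    """Nativeness score in (0,1) for one FRASE."""
    x = interaction_fingerprint(frase, hard_count=model.config.hard_count)
    return float(model.score_matrix(x[None, :])[0])
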