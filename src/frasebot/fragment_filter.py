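"""Post-screening filters: collision, buriedness, and nativeness score.

Seeded fragments are kept only when (i) every fragment heavy atom is at
least 1 A away from every protein heavy atom, (ii) the fragment is buried
(each ligand atom sees on average >=5 protein heavy atoms within 5 A), and
(iii) the nativeness score reaches the threshold (default 0.4).  All bounds
are inclusive; hydrogens never enter the distance counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .complex_io import Complex
from .frase_db import Fragment
from .triplet_screen import SeededFragment

__all__ = [
    "FilterConfig",
    "collision_filter",
    "buriedness_filter",
    "apply_filters",
    "FilterError",
]

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    min_clearance: float = 1.0  # A
    burial_radius: float = 5.0  # A
    min_mean_contacts: float = 5.0  # protein atoms per ligand atom
    score_threshold: float = 0.4

    def __post_init__(self) -> None:
        if min(self.min_clearance, self.burial_radius,
               self.min_mean_contacts, self.score_threshold) < 0:
            raise ValueError("filter parameters must be non-negative")


def _protein_coords(protein: Complex) -> np.ndarray:
    pts = [a.coord for res in protein.protein_residues for a in res.atoms
           if not a.is_hydrogen]
    return np.asarray(pts) if pts else np.empty((0, 3))


def collision_filter(fragment: Fragment, protein: Complex,
                     min_clearance: float = 1.0) -> bool:
    """True iff every fragment heavy atom is >= min_clearance from the protein."""
    ppts = _protein_coords(protein)
    fpts = fragment.heavy_coords()
    if ppts.size == 0 or fpts.size == 0:
        return True
    tree = cKDTree(ppts)
    dmin, _ = tree.query(fpts, k=1)
    return bool(np.min(dmin) >= min_clearance)


def buriedness_filter(fragment: Fragment, protein: Complex,
                      burial_radius: float = 5.0,
                      min_mean_contacts: float = 5.0) -> bool:
    """True iff the mean protein-contact count per fragment atom reaches the bound.

    The criterion is the average over fragment heavy atoms of the number of
    protein heavy atoms within ``burial_radius`` -- an average, not a
    per-atom minimum, so a deeply buried atom can compensate an exposed one.
    """
    fpts = fragment.heavy_coords()
    if fpts.size == 0:
        raise FilterError("fragment has no heavy atoms")
    ppts = _protein_coords(protein)
    if ppts.size == 0:
        return min_mean_contacts <= 0
    tree = cKDTree(ppts)
    counts = [len(tree.query_ball_point(p, burial_radius)) for p in fpts]
    return bool(np.mean(counts) >= min_mean_contacts)


def apply_filters(
    seeded: list[SeededFragment],
    protein: Complex,
    config: FilterConfig | None = None,
) -> tuple[list[SeededFragment], dict[str, int]]:
    """Sequential collision -> buriedness -> score filtering.

    The predicates are independent, but they are applied in this order so the
    logged per-stage survivor counts describe the same funnel a screening run
    reports.  Fragments with no score are dropped at the score stage.
    Returns (survivors, per-stage counts).
    """
    config = config or FilterConfig()
    counts = {"input": len(seeded)}
    stage = [s for s in seeded
             if collision_filter(s.fragment, protein, config.min_clearance)]
    counts["collision"] = len(stage)
    stage = [s for s in stage
             if buriedness_filter(s.fragment, protein, config.burial_radius,
                                  config.min_mean_contacts)]
    counts["buriedness"] = len(stage)
    stage = [s for s in stage
             if s.score is not None and s.score >= config.score_threshold]
    counts["score"] = len(stage)
    logger.info("filter funnel: %s", counts)
    return stage, counts
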