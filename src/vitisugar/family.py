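"""Subfamily assignment against a labelled reference panel, and distance trees.

Sugar-transporter proteins split into the sucrose-transporter family
(SUC/SUT) and seven monosaccharide-transporter subfamilies (I STP/HT,
II TMT, III PMT, IV ERD6-like, V VGT, VI INT, VII pGlcT/SGB1).  A query
protein is assigned to the subfamily of its most similar reference
sequence (best hit by percent similarity), with an explicit "unassigned"
outcome below a similarity floor and an "ambiguous" outcome on exact
cross-subfamily ties.

The family tree is a neighbor-joining tree on d = (100 - similarity)/100,
an illustrative distance-based stand-in, not an evolutionary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .alignment import ScoringScheme, SimilarityMatrix, pair_similarity, similarity_matrix
from .io import SequenceRecord

__all__ = [
    "Family",
    "Subfamily",
    "ReferencePanel",
    "FamilyAssignment",
    "assign_subfamily",
    "nj_tree",
]


class Family(str, Enum):
    SUC = "SUC"
    MST = "MST"


class Subfamily(str, Enum):
    SUC = "SUC"
    I_STP = "I_STP"
    II_TMT = "II_TMT"
    III_PMT = "III_PMT"
    IV_ERD6 = "IV_ERD6"
    V_VGT = "V_VGT"
    VI_INT = "VI_INT"
    VII_pGlcT_SGB1 = "VII_pGlcT_SGB1"

    @property
    def family(self) -> Family:
        return Family.SUC if self is Subfamily.SUC else Family.MST


@dataclass(frozen=True)
class PanelEntry:
    record: SequenceRecord
    subfamily: Subfamily

    @property
    def family(self) -> Family:
        return self.subfamily.family


@dataclass
class ReferencePanel:
    """Labelled reference proteins, one or more per subfamily used."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference panel must be non-empty")
        ids = [e.record.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in reference panel")

    @property
    def ids(self) -> list[str]:
        return [e.record.id for e in self.entries]

    def subfamily_of(self, ref_id: str) -> Subfamily:
        for e in self.entries:
            if e.record.id == ref_id:
                return e.subfamily
        raise KeyError(ref_id)


#: default similarity floor, below the lowest intra-family similarity
#: observed among grapevine transporters (36.2% within the ERD6-like set).
DEFAULT_MIN_SIMILARITY = 30.0


@dataclass(frozen=True)
class FamilyAssignment:
    """Best-hit subfamily call for one query protein.

    ``subfamily`` is None when unassigned (best hit below the floor) or
    ambiguous (exact tie across subfamilies); ``margin`` is the gap in
    percent similarity to the best hit in any other subfamily (None when
    the panel has a single subfamily).
    """

    query_id: str
    subfamily: Subfamily | None
    best_reference: str
    best_similarity: float
    margin: float | None
    status: str = "assigned"  # assigned | unassigned | ambiguous
    tied_subfamilies: tuple[Subfamily, ...] = ()


def assign_subfamily(
    query: SequenceRecord,
    panel: ReferencePanel,
    s: ScoringScheme | None = None,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> FamilyAssignment:
    """Assign a query to the subfamily of its most similar panel member."""
    s = s or ScoringScheme()
    sims = [(e, pair_similarity(query, e.record, s)) for e in panel.entries]
    best_entry, best_sim = max(sims, key=lambda t: t[1])
    other = [sim for e, sim in sims if e.subfamily is not best_entry.subfamily]
    margin = best_sim - max(other) if other else None
    ties = {e.subfamily for e, sim in sims if sim == best_sim}
    if best_sim < min_similarity:
        return FamilyAssignment(query.id, None, best_entry.record.id, best_sim,
                                margin, status="unassigned")
    if len(ties) > 1:
        return FamilyAssignment(query.id, None, best_entry.record.id, best_sim,
                                0.0, status="ambiguous",
                                tied_subfamilies=tuple(sorted(ties)))
    return FamilyAssignment(query.id, best_entry.subfamily, best_entry.record.id,
                            best_sim, margin)


def assign_all(
    queries: list[SequenceRecord],
    panel: ReferencePanel,
    s: ScoringScheme | None = None,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> list[FamilyAssignment]:
    return [assign_subfamily(q, panel, s, min_similarity) for q in queries]


def nj_tree(m: SimilarityMatrix) -> TreeNode:
    """Neighbor-joining tree on d = (100 - similarity) / 100.

    Negative branch lengths produced by NJ are clamped to zero; for
    additive distances, tip-to-tip path lengths reproduce the input
    exactly.
    """
    if len(m.labels) < 3:
        raise ValueError("need at least 3 labels to build a tree")
    dm = DistanceMatrix(m.to_distances(), m.labels)
    return nj_from_distances(dm)


def nj_from_distances(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining on a pre-built distance matrix."""
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return _skbio_nj(dm, neg_as_zero=True)
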