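"""Pairwise global alignment and percent similarity for transporter proteins.

Percent similarity follows the classic convention used by desktop
alignment suites: the number of aligned residue pairs that are identical
or fall within one "strong" conservation group, divided by the length of
the shorter input sequence.  Alignment itself is optimal global alignment
with affine gap costs, computed by :class:`Bio.Align.PairwiseAligner`
over a three-level substitution matrix (identity / similar-group /
mismatch) derived from the conservation groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import PROTEIN_LETTERS, SequenceRecord

__all__ = [
    "STRONG_GROUPS",
    "ScoringScheme",
    "PairwiseAlignment",
    "SimilarityMatrix",
    "align_global",
    "percent_similarity",
    "similarity_matrix",
]

#: Classic strongly conserved amino-acid classes.
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for the three-level substitution model with affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    match_score: float = 1.0
    similar_score: float = 0.5
    mismatch_score: float = 0.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    similarity_groups: tuple[frozenset[str], ...] = STRONG_GROUPS

    def __post_init__(self) -> None:
        if not (self.match_score >= self.similar_score >= self.mismatch_score):
            raise ValueError("require match_score >= similar_score >= mismatch_score")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")

    def similar(self, a: str, b: str) -> bool:
        """True iff residues are identical or share a conservation group."""
        if a == b:
            return True
        return any(a in g and b in g for g in self.similarity_groups)

    def pair_score(self, a: str, b: str) -> float:
        if a == b:
            return self.match_score
        if self.similar(a, b):
            return self.similar_score
        return self.mismatch_score


from functools import lru_cache


@lru_cache(maxsize=8)
def _substitution_matrix(s: ScoringScheme) -> substitution_matrices.Array:
    letters = "".join(sorted(PROTEIN_LETTERS))
    m = substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            m[a, b] = s.pair_score(a, b)
    return m


@lru_cache(maxsize=8)
def _aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _substitution_matrix(s)
    al.open_gap_score = s.gap_open
    al.extend_gap_score = s.gap_extend
    return al


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences; equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap/gap column in alignment")

    @property
    def sequence_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def sequence_b(self) -> str:
        return self.aligned_b.replace(GAP, "")


def align_global(a: SequenceRecord, b: SequenceRecord, s: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two protein records under ``s``.

    Deterministic: among co-optimal alignments the aligner's canonical
    traceback order is used, so the same inputs always give the same
    alignment.
    """
    s = s or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(s).align(a.residues, b.residues)
    best = aln[0]
    return PairwiseAlignment(aligned_a=best[0], aligned_b=best[1], score=aln.score)


def percent_similarity(aln: PairwiseAlignment, s: ScoringScheme | None = None) -> float:
    """Percent of similar columns relative to the shorter input sequence.

    Only residue/residue columns can count toward the numerator, so the
    value is always in [0, 100]; 100 requires every residue of the
    shorter sequence to be matched by an identical-or-similar residue.
    """
    s = s or ScoringScheme()
    num = sum(
        1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if ca != GAP and cb != GAP and s.similar(ca, cb)
    )
    denom = min(len(aln.sequence_a), len(aln.sequence_b))
    return 100.0 * num / denom


def pair_similarity(a: SequenceRecord, b: SequenceRecord, s: ScoringScheme | None = None) -> float:
    """Align two records and return their percent similarity."""
    s = s or ScoringScheme()
    return percent_similarity(align_global(a, b, s), s)


@dataclass
class SimilarityMatrix:
    """Symmetric percent-similarity matrix with 100s on the diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity values must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_distances(self) -> np.ndarray:
        """d = (100 - similarity) / 100, the tree-building transform."""
        return (100.0 - self.values) / 100.0


def similarity_matrix(seqs: list[SequenceRecord], s: ScoringScheme | None = None) -> SimilarityMatrix:
    """All-against-all percent similarity; each unordered pair aligned once."""
    s = s or ScoringScheme()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    v = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            sim = pair_similarity(seqs[i], seqs[j], s)
            v[i, j] = v[j, i] = sim
    return SimilarityMatrix(labels=ids, values=v)
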