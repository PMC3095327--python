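"""Promoter extraction: the region upstream of the start codon.

The promoter of a gene is the up-to-2-kb stretch immediately 5' of the
first base of its start codon, truncated when another annotated feature
lies closer than that — the same rule that produces short promoters for
genes with a neighbouring upstream ORF (e.g. 623 bp instead of 2 kb).
The returned sequence always reads 5'->3' toward the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AnnotationRecord, SequenceRecord

__all__ = ["PromoterRecord", "extract_promoter", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, ambiguity codes included."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """An extracted promoter sequence with its truncation status."""

    gene_id: str
    residues: str
    truncated: bool
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"promoter of {self.gene_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


def extract_promoter(
    gene: AnnotationRecord,
    genome: SequenceRecord,
    others: list[AnnotationRecord] | None = None,
    max_len: int = 2000,
) -> PromoterRecord:
    """Extract the ``max_len`` bases upstream of the start codon.

    On '+', bases ``[cds_start - max_len, cds_start - 1]`` clipped to the
    chromosome start and to the end of the nearest upstream feature
    (exclusive); on '-', bases ``[cds_start + 1, cds_start + max_len]``
    clipped analogously and reverse-complemented.  The ``truncated``
    flag records whether the full ``max_len`` was available.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    others = [o for o in (others or []) if o.gene_id != gene.gene_id and o.seq_id == gene.seq_id]
    chrom_len = len(genome.residues)
    if gene.strand == "+":
        start = max(1, gene.cds_start - max_len)
        end = gene.cds_start - 1
        upstream_ends = [o.feature_bounds[1] for o in others if o.feature_bounds[1] < gene.cds_start]
        if upstream_ends:
            start = max(start, max(upstream_ends) + 1)
        if end < start:
            raise ValueError(
                f"gene {gene.gene_id!r}: no promoter sequence upstream of cds_start"
            )
        seq = genome.residues[start - 1:end]
    else:
        start = gene.cds_start + 1
        end = min(chrom_len, gene.cds_start + max_len)
        upstream_starts = [o.feature_bounds[0] for o in others if o.feature_bounds[0] > gene.cds_start]
        if upstream_starts:
            end = min(end, min(upstream_starts) - 1)
        if end < start:
            raise ValueError(
                f"gene {gene.gene_id!r}: no promoter sequence upstream of cds_start"
            )
        seq = reverse_complement(genome.residues[start - 1:end])
    return PromoterRecord(
        gene_id=gene.gene_id,
        residues=seq,
        truncated=len(seq) < max_len,
        family=None,
    )
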