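"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through :mod:`Bio.SeqIO`, GFF3 through :mod:`gffutils`, Newick
through :class:`skbio.TreeNode`, and tables through :mod:`pandas`.  All
coordinates are 1-based inclusive (GFF3 convention); tables are
tab-separated UTF-8 with ``.`` as the decimal mark.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from skbio import TreeNode

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "AnnotationRecord",
    "SpotRow",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_spot_table",
    "write_spot_table",
    "read_newick",
    "write_newick",
]

# IUPAC nucleotide codes (incl. ambiguity) and the 20 amino acids plus X.
DNA_LETTERS = frozenset("ACGTRYSWKMBDHVN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Alphabet(str, Enum):
    dna = "dna"
    protein = "protein"

    @property
    def letters(self) -> frozenset[str]:
        return DNA_LETTERS if self is Alphabet.dna else PROTEIN_LETTERS


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or protein sequence.

    Residues are stored upper-cased; validation is against the IUPAC
    nucleotide codes (dna) or the 20 amino acids plus X (protein).
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.dna
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        allowed = self.alphabet.letters
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"sequence {self.id!r}: residue {ch!r} at position {pos} "
                    f"not in the {self.alphabet.value} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene annotation: where the feature lies and where translation starts.

    ``cds_start`` is the first base of the start codon on the biological
    sense strand, 1-based; ``feature_bounds`` is a 1-based inclusive
    ``(start, end)`` interval on the forward strand.
    """

    gene_id: str
    seq_id: str
    strand: str
    cds_start: int
    feature_bounds: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        lo, hi = self.feature_bounds
        if not (1 <= lo <= hi):
            raise ValueError(f"gene {self.gene_id!r}: invalid bounds {self.feature_bounds}")
        if not (lo <= self.cds_start <= hi):
            raise ValueError(
                f"gene {self.gene_id!r}: cds_start {self.cds_start} outside "
                f"feature bounds {self.feature_bounds}"
            )


@dataclass(frozen=True)
class SpotRow:
    """One quantified macroarray spot."""

    gene_id: str
    membrane_id: str
    spot_index: int
    raw_signal: float
    background: float
    condition: str

    def __post_init__(self) -> None:
        if self.spot_index < 1:
            raise ValueError(f"spot_index must be >= 1, got {self.spot_index}")
        if self.raw_signal < 0:
            raise ValueError(
                f"gene {self.gene_id!r} spot {self.spot_index}: negative raw_signal"
            )
        if self.background < 0:
            raise ValueError(
                f"gene {self.gene_id!r} spot {self.spot_index}: negative background"
            )


def read_fasta(path: str | Path, alphabet: Alphabet | str = Alphabet.dna) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are concatenated across wrapped lines and upper-cased; input
    order is preserved.  Duplicate ids and out-of-alphabet residues raise
    ``ValueError``.
    """
    alphabet = Alphabet(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet,
                           description=desc)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read gene annotations from GFF3.

    One record per ``gene`` feature.  ``cds_start`` is taken from the
    gene's CDS children when present (lowest start on '+', highest end on
    '-'), otherwise from the gene bounds themselves.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out: list[AnnotationRecord] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS"))
        if gene.strand == "+":
            cds_start = min(c.start for c in cds) if cds else gene.start
        else:
            cds_start = max(c.end for c in cds) if cds else gene.end
        out.append(
            AnnotationRecord(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                cds_start=cds_start,
                feature_bounds=(gene.start, gene.end),
            )
        )
    return out


SPOT_COLUMNS = ["gene_id", "membrane_id", "spot_index", "raw_signal", "background", "condition"]


def read_spot_table(path: str | Path) -> list[SpotRow]:
    """Read a TSV of quantified spots (one row per spot, strict numeric parsing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} missing column(s): {', '.join(missing)}")
    rows: list[SpotRow] = []
    for _, r in df.iterrows():
        rows.append(
            SpotRow(
                gene_id=str(r["gene_id"]),
                membrane_id=str(r["membrane_id"]),
                spot_index=int(r["spot_index"]),
                raw_signal=float(r["raw_signal"]),
                background=float(r["background"]),
                condition=str(r["condition"]),
            )
        )
    return rows


def write_spot_table(rows: Sequence[SpotRow], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in rows], columns=SPOT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (";"-terminated).

    Every leaf must carry a non-empty label and every non-root node a
    branch length; the output round-trips through :func:`read_newick`.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 leaves")
    for tip in tips:
        if not tip.name:
            raise ValueError("every leaf must carry a non-empty label")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("every branch must carry a length")
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_stdio.StringIO(text), format="newick")
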