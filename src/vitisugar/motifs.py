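"""IUPAC-degenerate cis-element scanning and the occurrence-based reports.

A cis-regulatory element is represented as an IUPAC consensus word
(e.g. ``GRWAAW``: R = A/G, W = A/T).  Scanning reports every window of a
promoter matching the word — overlapping matches included — on the
forward strand by default, optionally on both strands.  From the
promoter x motif copy-count table the module derives the reports a
family-wide promoter survey needs:

* common elements  — present in (almost) every promoter, with the
  maximum copy number observed in any single promoter;
* unique elements  — present in exactly one promoter;
* family-restricted elements — present only in promoters of a single
  subfamily (at least two of them);
* the sugar-responsive repertory — per gene, how many distinct
  sugar-related motifs occur at least once;
* composite elements — e.g. the gibberellin-response complex (GARC),
  called when every component motif co-occurs in a promoter.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .promoters import PromoterRecord, reverse_complement

__all__ = [
    "IUPAC",
    "Motif",
    "MotifLibrary",
    "MotifHit",
    "OccurrenceTable",
    "compile_motif",
    "scan_motif",
    "occurrence_table",
    "classify_common",
    "classify_unique",
    "family_restricted",
    "sugar_repertory",
    "detect_composite",
    "default_library",
]

#: IUPAC nucleotide ambiguity codes -> allowed concrete bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: what a motif position accepts in the *promoter* string: ambiguity codes
#: in the scanned sequence never satisfy a position except motif-N, which
#: accepts anything.
_ALL_CODES = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class Motif:
    """A named IUPAC-degenerate consensus with its response annotation."""

    name: str
    iupac: str
    response: str = ""
    source: str = "user"  # table1 | table2 | text | user

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("motif name must be non-empty")
        if not self.iupac:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        for ch in self.iupac.upper():
            if ch not in IUPAC:
                raise ValueError(f"motif {self.name!r}: invalid IUPAC symbol {ch!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class CompiledMotif:
    """Position-wise allowed-base sets plus a compiled overlap-aware regex."""

    motif: Motif
    position_sets: tuple[frozenset[str], ...]
    regex: re.Pattern

    def words(self) -> list[str]:
        """Every concrete word the consensus denotes (cartesian product)."""
        out = [""]
        for s in self.position_sets:
            out = [w + b for w in out for b in sorted(s)]
        return out


def compile_motif(motif: Motif | str) -> CompiledMotif:
    """Compile an IUPAC consensus into matchable form.

    A promoter character satisfies a motif position only if it is a
    concrete base allowed at that position; promoter ambiguity codes
    (assembly Ns etc.) match nothing except a motif ``N``.
    """
    if isinstance(motif, str):
        motif = Motif(name=motif, iupac=motif)
    sets = tuple(IUPAC[ch] for ch in motif.iupac)
    classes = []
    for ch, allowed in zip(motif.iupac, sets):
        if ch == "N":
            classes.append(f"[{_ALL_CODES}]")
        else:
            classes.append("[" + "".join(sorted(allowed)) + "]")
    pattern = re.compile("(?=" + "".join(classes) + ")")
    return CompiledMotif(motif=motif, position_sets=sets, regex=pattern)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    gene_id: str
    start: int  # 1-based on the reported strand
    strand: str  # '+' or '-'


def scan_motif(
    p: PromoterRecord,
    m: Motif | CompiledMotif,
    strands: str = "forward",
) -> list[MotifHit]:
    """All (overlapping) occurrences of a motif in a promoter.

    ``strands='forward'`` scans the promoter as given; ``'both'`` also
    scans its reverse complement, reporting those hits with strand '-'
    and a 1-based start on the reverse-complement strand.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    cm = m if isinstance(m, CompiledMotif) else compile_motif(m)
    name = cm.motif.name
    hits = [
        MotifHit(name, p.gene_id, mo.start() + 1, "+")
        for mo in cm.regex.finditer(p.residues)
    ]
    if strands == "both":
        rc = reverse_complement(p.residues)
        hits += [
            MotifHit(name, p.gene_id, mo.start() + 1, "-")
            for mo in cm.regex.finditer(rc)
        ]
    return hits


@dataclass
class MotifLibrary:
    """A named collection of motifs with unique names."""

    motifs: list[Motif]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique within a library")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __getitem__(self, name: str) -> Motif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "MotifLibrary":
        return MotifLibrary([self[n] for n in names])

    @classmethod
    def from_json(cls, path: str | Path) -> "MotifLibrary":
        data = json.loads(Path(path).read_text())
        return cls([Motif(**d) for d in data])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([m.__dict__ for m in self.motifs], indent=1) + "\n"
        )


# ---------------------------------------------------------------------------
# Packaged default library: the elements with printed consensus sequences —
# the 20 common elements, the 9 single-promoter elements, and the S-box.
# Further elements (SURE boxes, sucrose box 3, AMY boxes, pyrimidine-box
# variants, ...) have no printed consensus here and must be user-supplied
# through the JSON library format.
# ---------------------------------------------------------------------------

_TABLE1 = [
    ("ARR1AT", "NGATT", "Cytokinins"),
    ("CIACADIANLELHC", "CAANNNNATC", "Circadian expression"),
    ("DOFCOREZM", "AAAG", "C-metabolism, leaf"),
    ("EBOXBNNAPA", "CANNTG", "Light, ABA, seeds"),
    ("EECCRCAH1", "GANTTNC", "CO2-responsive"),
    ("GATABOX", "GATA", "Light, leaf, shoot"),
    ("GT1CONSENSUS", "GRWAAW", "Light, leaf, shoot"),
    ("GTGANTG10", "GTGA", "Pollen"),
    ("IBOXCORE", "GATAA", "Light, leaf, shoot"),
    ("MYBST1", "GGATA", "Myb trans activator"),
    ("MYCCONSENSUSAT", "CANNTG", "ABA, abiotic stress"),
    ("PYRIMIDINEBOXOSRAMY1A", "CCTTTT", "Sugar repression, seeds"),
    ("POLLEN1LELAT52", "AGAAA", "Pollen"),
    ("RAV1AAT", "CAACA", "Root, rosette leaves"),
    ("ROOTMOTIFTAPOX1", "ATATT", "Root"),
    ("SEF4MOTIFGM7S", "RTTTTTR", "Seed, storage protein"),
    ("WBOXATNPR1", "TTGAC", "Disease resistance"),
    ("WBOXHVISO1", "TGACT", "Sugar, SUSIBA2"),
    ("WBOXNTERF3", "TGACY", "Wounding, ERF3"),
    ("WRKY71OS", "TGAC", "GA repressor, ABA"),
]

_TABLE2 = [
    ("ABREZMRAB28", "CCACGTGG", "Drought, ABA"),
    ("CRTDREHVCBF2", "GTCGAC", "Cold, drought"),
    ("GARE2OSREP1", "TAACGTA", "GA, germination"),
    ("GBOX10NT", "GCCACGTGCC", "Leaf, root, flower, pollen"),
    ("GBOXLERNCS", "MCACGTGGC", "Light, overlap ABA"),
    ("LREBOXIIPCCHS1", "TCCACGTGGC", "Cold, drought, ABA"),
    ("MYBCOREATCYCB1", "AACGG", "Cell cycle, cyclin"),
    ("NONAMERMOTIFATH3H4", "CATCCAACG", "Meristem"),
    ("ZDNAFORMINGATCAB1", "ATACGTGT", "Light, leaf, shoot"),
]


def default_library() -> MotifLibrary:
    """The packaged 30-motif library (common + unique elements + S-box)."""
    motifs = [Motif(n, s, r, "table1") for n, s, r in _TABLE1]
    motifs += [Motif(n, s, r, "table2") for n, s, r in _TABLE2]
    motifs.append(Motif("S_BOX", "CACCTCCA", "Sugar, ABA (G-box associated)", "text"))
    return MotifLibrary(motifs)


# ---------------------------------------------------------------------------
# Occurrence table and the derived reports
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceTable:
    """Promoter x motif copy-count matrix (genes as rows)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in occurrence table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate motif names in occurrence table")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.isfinite(vals).all()):
            raise ValueError("counts must be finite and non-negative")
        self.counts = self.counts.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.counts.columns)


def occurrence_table(
    promoters: Sequence[PromoterRecord],
    lib: MotifLibrary,
    strands: str = "forward",
) -> OccurrenceTable:
    """Count every library motif in every promoter."""
    if not promoters:
        raise ValueError("need at least one promoter")
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids among promoters")
    compiled = [compile_motif(m) for m in lib]
    data = {
        cm.motif.name: [len(scan_motif(p, cm, strands)) for p in promoters]
        for cm in compiled
    }
    df = pd.DataFrame(data, index=ids, columns=[m.name for m in lib])
    return OccurrenceTable(df)


@dataclass(frozen=True)
class CommonElement:
    motif: str
    max_copies: int
    missing_genes: tuple[str, ...]


def classify_common(t: OccurrenceTable, tolerance_missing: int = 0) -> list[CommonElement]:
    """Motifs present (count >= 1) in all but at most ``tolerance_missing`` promoters."""
    out = []
    for motif in t.motifs:
        col = t.counts[motif]
        missing = tuple(col.index[col == 0])
        if len(missing) <= tolerance_missing:
            out.append(CommonElement(motif, int(col.max()), missing))
    return out


@dataclass(frozen=True)
class UniqueElement:
    motif: str
    gene: str
    copies: int


def classify_unique(t: OccurrenceTable) -> list[UniqueElement]:
    """Motifs with a nonzero count in exactly one promoter."""
    if len(t.genes) < 2:
        raise ValueError("uniqueness is undefined for a single promoter")
    out = []
    for motif in t.motifs:
        col = t.counts[motif]
        nz = col[col > 0]
        if len(nz) == 1:
            out.append(UniqueElement(motif, str(nz.index[0]), int(nz.iloc[0])))
    return out


@dataclass(frozen=True)
class RestrictedElement:
    motif: str
    family: str


def family_restricted(t: OccurrenceTable, families: Mapping[str, str]) -> list[RestrictedElement]:
    """Motifs whose occurrences all fall in >= 2 genes of one subfamily."""
    unmapped = [g for g in t.genes if g not in families]
    if unmapped:
        raise ValueError(f"genes without a family label: {', '.join(unmapped)}")
    out = []
    for motif in t.motifs:
        col = t.counts[motif]
        carriers = [str(g) for g in col.index[col > 0]]
        fams = {families[g] for g in carriers}
        if len(carriers) >= 2 and len(fams) == 1:
            out.append(RestrictedElement(motif, fams.pop()))
    return out


def sugar_repertory(t: OccurrenceTable, sugar_motifs: Iterable[str]) -> pd.DataFrame:
    """Per-gene count of distinct sugar-responsive motifs present.

    Returns a frame indexed by gene, sorted by descending
    ``distinct_motifs``, with one copy-count column per sugar motif.
    """
    sugar = list(sugar_motifs)
    unknown = [m for m in sugar if m not in t.motifs]
    if unknown:
        raise ValueError(f"unknown motif name(s): {', '.join(unknown)}")
    sub = t.counts[sugar] if sugar else t.counts.iloc[:, :0]
    distinct = (sub > 0).sum(axis=1) if sugar else pd.Series(0, index=t.counts.index)
    rep = sub.copy()
    rep.insert(0, "distinct_motifs", distinct.astype(int))
    return rep.sort_values("distinct_motifs", ascending=False, kind="mergesort")


def detect_composite(
    t: OccurrenceTable,
    components: Iterable[str],
    rule: str = "all_present",
) -> pd.Series:
    """Per-gene flag for a composite element (all components co-occur)."""
    comps = list(components)
    if not comps:
        raise ValueError("composite needs at least one component motif")
    if rule != "all_present":
        raise ValueError(f"unknown composite rule {rule!r}")
    unknown = [m for m in comps if m not in t.motifs]
    if unknown:
        raise ValueError(f"unknown component name(s): {', '.join(unknown)}")
    return (t.counts[comps] > 0).all(axis=1)
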