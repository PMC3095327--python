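"""Seeded generators for promoter sets, macroarray spot tables and protein
families, each emitting machine-readable ground truth.

Every generator takes a single seed and derives an independent stream
from it, so adding a generator never perturbs another's output.  Ground
truth is emitted in the same schema the corresponding pipeline stage
produces, enabling exact-equality assertions:

* promoters — motif copies planted at non-overlapping positions in a
  synthetic background; on a poly-C background (for motifs requiring a
  non-C base) the planted counts are guaranteed to equal what the
  scanner reports, and the generator verifies this with an internal
  brute-force scan;
* membranes — spot intensities ``exposure x level x lognormal-noise +
  background`` around a known gene x condition expression matrix, with
  reference genes, negative controls, triplicate spots and duplicate
  membranes per condition;
* families — query proteins derived from labelled reference-panel
  members by i.i.d. substitutions at a known rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .family import PanelEntry, ReferencePanel, Subfamily
from .io import Alphabet, SequenceRecord, SpotRow
from .motifs import Motif, compile_motif
from .promoters import PromoterRecord, reverse_complement

__all__ = [
    "GenerationError",
    "PlantedMotif",
    "PromoterSimSpec",
    "gen_promoters",
    "MembraneSimSpec",
    "gen_membranes",
    "FamilySimSpec",
    "gen_family",
    "gen_panel",
    "gen_random_additive_tree",
    "oracle_scan_count",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed per-generator stream keys: adding a generator never shifts others
_STREAMS = {"promoters": 1, "membranes": 2, "families": 3, "panel": 4, "trees": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


class GenerationError(RuntimeError):
    """A simulation spec cannot be realized as stated."""


# ---------------------------------------------------------------------------
# Brute-force scanning oracle (IUPAC expansion + window comparison).
# Deliberately a different algorithm from the regex scanner so it can
# serve as an independent check and as the generator's verifier.
# ---------------------------------------------------------------------------


def oracle_scan_count(sequence: str, motif: Motif | str, strands: str = "forward") -> int:
    """Count motif occurrences by expanding the IUPAC word set and
    comparing every window against it."""
    cm = compile_motif(motif)
    words = set(cm.words())
    k = len(cm.position_sets)

    def count_fwd(seq: str) -> int:
        return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] in words)

    total = count_fwd(sequence)
    if strands == "both":
        total += count_fwd(reverse_complement(sequence))
    return total


# ---------------------------------------------------------------------------
# Promoter sets with planted motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedMotif:
    """Plant ``copies`` realizations of ``motif`` in promoter ``gene_index``."""

    motif: Motif
    gene_index: int
    copies: int
    positions: tuple[int, ...] | None = None  # 1-based starts, optional

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be non-negative")
        if self.positions is not None and len(self.positions) != self.copies:
            raise ValueError("positions, when given, must match copies")


@dataclass
class PromoterSimSpec:
    n_promoters: int
    length: int = 2000
    background: str = "poly_c"  # poly_c | uniform_acgt | fixed_gc
    gc_content: float = 0.5
    plants: list[PlantedMotif] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.length < 1:
            raise ValueError("need n_promoters >= 1 and length >= 1")
        if self.background not in ("poly_c", "uniform_acgt", "fixed_gc"):
            raise ValueError(f"unknown background {self.background!r}")
        for p in self.plants:
            if not (0 <= p.gene_index < self.n_promoters):
                raise ValueError(f"gene_index {p.gene_index} out of range")


def _background(spec: PromoterSimSpec, rng: np.random.Generator) -> str:
    if spec.background == "poly_c":
        return "C" * spec.length
    if spec.background == "uniform_acgt":
        return "".join(rng.choice(list("ACGT"), size=spec.length))
    g = spec.gc_content / 2
    a = (1 - spec.gc_content) / 2
    return "".join(rng.choice(list("ACGT"), size=spec.length, p=[a, g, g, a]))


def _place_words(
    words: list[str], length: int, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Random non-overlapping placements with >= 1 background base between
    planted words (0-based starts)."""
    order = list(rng.permutation(len(words)))
    shuffled = [words[i] for i in order]
    k = len(shuffled)
    needed = sum(len(w) for w in shuffled) + max(k - 1, 0)
    slack = length - needed
    if slack < 0:
        raise GenerationError(
            f"cannot plant {k} copies totalling {needed} bases in a "
            f"{length}-base promoter without overlap"
        )
    # distribute the slack over the k+1 gaps
    extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
    placements = []
    pos = int(extra[0])
    for i, w in enumerate(shuffled):
        placements.append((pos, w))
        pos += len(w) + 1 + int(extra[i + 1])
    return placements


def gen_promoters(
    spec: PromoterSimSpec,
    gene_ids: Sequence[str] | None = None,
    verify: bool | None = None,
) -> tuple[list[PromoterRecord], pd.DataFrame]:
    """Generate promoters with planted motif copies and the truth table.

    Returns ``(promoters, truth)`` where ``truth`` is the planted
    gene x motif copy-count matrix.  With a poly-C background the
    generator verifies, with the brute-force oracle, that the realized
    forward-strand counts equal the planted truth for every planted
    motif, and raises :class:`GenerationError` on any discrepancy
    (cross-matches between planted words are possible in principle and
    must not pass silently).
    """
    rng = _rng(spec.seed, "promoters")
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:02d}" for i in range(spec.n_promoters)]
    if len(gene_ids) != spec.n_promoters:
        raise ValueError("gene_ids length must equal n_promoters")
    if verify is None:
        verify = spec.background == "poly_c"

    motif_names = sorted({p.motif.name for p in spec.plants})
    truth = pd.DataFrame(0, index=list(gene_ids), columns=motif_names, dtype=int)

    promoters: list[PromoterRecord] = []
    for gi, gene in enumerate(gene_ids):
        seq = list(_background(spec, rng))
        plants_here = [p for p in spec.plants if p.gene_index == gi]
        # realize every copy as a concrete word from the consensus
        words: list[str] = []
        fixed: list[tuple[int, str]] = []
        for p in plants_here:
            cm = compile_motif(p.motif)
            vocab = cm.words()
            realized = [vocab[rng.integers(len(vocab))] for _ in range(p.copies)]
            if p.positions is not None:
                fixed += [(pos - 1, w) for pos, w in zip(p.positions, realized)]
            else:
                words += realized
            truth.loc[gene, p.motif.name] += p.copies
        placements = _place_words(words, spec.length, rng) if words else []
        placements += fixed
        occupied: set[int] = set()
        for pos, w in placements:
            span = range(pos, pos + len(w))
            if pos < 0 or pos + len(w) > spec.length or occupied & set(span):
                raise GenerationError(
                    f"planted word at position {pos + 1} in {gene!r} overlaps "
                    "another plant or runs off the promoter"
                )
            occupied.update(span)
            seq[pos:pos + len(w)] = list(w)
        promoters.append(PromoterRecord(gene_id=gene, residues="".join(seq),
                                        truncated=spec.length < 2000))

    if verify:
        motifs = {p.motif.name: p.motif for p in spec.plants}
        for prom in promoters:
            for name, motif in motifs.items():
                realized = oracle_scan_count(prom.residues, motif, "forward")
                expected = int(truth.loc[prom.gene_id, name])
                if realized != expected:
                    raise GenerationError(
                        f"{prom.gene_id!r}/{name}: realized count {realized} != "
                        f"planted {expected} (cross-match between plants)"
                    )
    return promoters, truth


# ---------------------------------------------------------------------------
# Macroarray membranes
# ---------------------------------------------------------------------------


@dataclass
class MembraneSimSpec:
    """Spot-table simulation around a known expression matrix.

    ``truth`` is in relative units (gene level over the reference-gene
    mean); spot level for a gene is ``truth x mean(reference_levels)``,
    so a noise-free run recovers ``truth`` exactly.
    """

    truth: pd.DataFrame  # genes x conditions, relative units
    reference_levels: tuple[float, float, float, float] = (900.0, 1100.0, 1000.0, 1200.0)
    negative_level: float = 40.0
    background_level: float = 25.0
    exposures: dict[str, Sequence[float]] | float = 1.0
    noise_cv: float = 0.0
    spots_per_gene: int = 3
    membranes_per_condition: int = 2
    reference_genes: tuple[str, ...] = ("actin", "EF1a", "EF1g", "GAPDH")
    negative_control: str = "salmon_sperm"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.truth.to_numpy() < 0).any():
            raise ValueError("truth matrix must be non-negative")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must be in [0, 1)")
        if self.negative_level < 0 or self.background_level < 0:
            raise ValueError("levels must be non-negative")
        if len(self.reference_levels) != len(self.reference_genes):
            raise ValueError("one level per reference gene")
        if any(l <= 0 for l in self.reference_levels):
            raise ValueError("reference levels must be positive")

    def exposure(self, condition: str, membrane_index: int) -> float:
        if isinstance(self.exposures, dict):
            e = float(self.exposures[condition][membrane_index])
        else:
            e = float(self.exposures)
        if e <= 0:
            raise ValueError("exposure must be positive")
        return e


def _noise(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative log-normal noise factor with unit mean."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def gen_membranes(spec: MembraneSimSpec) -> tuple[list[SpotRow], pd.DataFrame]:
    """Generate the spot table for every membrane of the design.

    Returns ``(rows, truth)``; ``truth`` is the input expression matrix
    (relative units), which the quantification pipeline recovers exactly
    when ``noise_cv`` is zero (up to presence thresholding).
    """
    rng = _rng(spec.seed, "membranes")
    ref_mean = float(np.mean(spec.reference_levels))
    rows: list[SpotRow] = []
    for condition in spec.truth.columns:
        for mi in range(spec.membranes_per_condition):
            membrane_id = f"{condition}__m{mi + 1}"
            exposure = spec.exposure(condition, mi)
            levels: list[tuple[str, float]] = [
                (g, float(spec.truth.at[g, condition]) * ref_mean)
                for g in spec.truth.index
            ]
            levels += list(zip(spec.reference_genes, spec.reference_levels))
            levels.append((spec.negative_control, spec.negative_level))
            for gene, level in levels:
                for si in range(spec.spots_per_gene):
                    bg = spec.background_level * _noise(rng, spec.noise_cv)
                    signal = exposure * level * _noise(rng, spec.noise_cv)
                    rows.append(
                        SpotRow(
                            gene_id=gene,
                            membrane_id=membrane_id,
                            spot_index=si + 1,
                            raw_signal=signal + bg,
                            background=bg,
                            condition=condition,
                        )
                    )
    return rows, spec.truth.copy()


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_panel(
    members_per_subfamily: int = 3,
    length: int = 150,
    within_divergence: float = 0.1,
    seed: int = 0,
) -> ReferencePanel:
    """A synthetic labelled reference panel.

    Each subfamily descends from its own random ancestor; members
    diverge from it by i.i.d. substitutions at ``within_divergence``.
    Different subfamilies are unrelated random proteins, so
    between-subfamily similarity sits at the random-alignment baseline.
    """
    rng = _rng(seed, "panel")
    entries: list[PanelEntry] = []
    for sub in Subfamily:
        ancestor = _random_protein(length, rng)
        for j in range(members_per_subfamily):
            seq = _mutate(ancestor, within_divergence, rng)
            entries.append(
                PanelEntry(
                    record=SequenceRecord(
                        id=f"{sub.value}_ref{j + 1}",
                        residues=seq,
                        alphabet=Alphabet.protein,
                    ),
                    subfamily=sub,
                )
            )
    return ReferencePanel(entries)


@dataclass
class FamilySimSpec:
    panel: ReferencePanel
    substitutions_per_site: float = 0.1
    n_queries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitutions_per_site <= 0.5):
            raise ValueError(
                "substitutions_per_site must be in [0, 0.5]; beyond that the "
                "source subfamily is unidentifiable"
            )
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")


def gen_family(
    spec: FamilySimSpec,
) -> tuple[list[SequenceRecord], pd.DataFrame, TreeNode]:
    """Simulate query proteins from the panel plus a known additive tree.

    Each query is a uniformly chosen panel member mutated i.i.d. at the
    stated rate.  Returns ``(queries, truth, tree)``: the truth frame
    records each query's source sequence and subfamily; the tree is a
    random additive tree over the panel ids for tree-recovery tests.
    """
    rng = _rng(spec.seed, "families")
    entries = spec.panel.entries
    queries: list[SequenceRecord] = []
    records = []
    for i in range(spec.n_queries):
        src = entries[rng.integers(len(entries))]
        seq = _mutate(src.record.residues, spec.substitutions_per_site, rng)
        qid = f"q{i + 1:04d}"
        queries.append(SequenceRecord(id=qid, residues=seq, alphabet=Alphabet.protein))
        records.append(
            {"query_id": qid, "source_id": src.record.id,
             "subfamily": src.subfamily.value}
        )
    truth = pd.DataFrame(records).set_index("query_id")
    tree, _ = gen_random_additive_tree(
        len(entries), seed=spec.seed, labels=[e.record.id for e in entries]
    )
    return queries, truth, tree


def gen_random_additive_tree(
    n_leaves: int,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> tuple[TreeNode, DistanceMatrix]:
    """A random binary tree with positive branch lengths and its exact
    tip-to-tip distance matrix (additive by construction)."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = _rng(seed, "trees")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.extend([b, a])
        del nodes[j], nodes[i]
        nodes.append(parent)
    root = TreeNode()
    for n in nodes:
        n.length = float(rng.uniform(0.1, 1.0))
        root.append(n)
    dm = root.tip_tip_distances()
    return root, dm
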