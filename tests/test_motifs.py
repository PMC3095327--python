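import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitisugar import (
    AnnotationRecord,
    Motif,
    MotifLibrary,
    OccurrenceTable,
    SequenceRecord,
    classify_common,
    classify_unique,
    compile_motif,
    detect_composite,
    extract_promoter,
    family_restricted,
    occurrence_table,
    scan_motif,
    sugar_repertory,
)
from vitisugar.promoters import PromoterRecord, reverse_complement
from oracles import count_oracle

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


def prom(seq: str, gene="g1") -> PromoterRecord:
    return PromoterRecord(gene_id=gene, residues=seq, truncated=len(seq) < 2000)


class TestCompileMotif:
    def test_degenerate_word_set_size(self):
        cm = compile_motif(Motif("gt1", "GRWAAW"))
        words = cm.words()
        assert len(words) == 8
        assert "GAAAAA" in words and "GGTAAT" in words

    def test_concrete_motif_is_singleton(self):
        assert compile_motif(Motif("gata", "GATA")).words() == ["GATA"]

    def test_invalid_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            Motif("bad", "GAXA")


class TestScanMotif:
    def test_overlapping_tandem_hits(self):
        hits = scan_motif(prom("GATAGATA"), Motif("gata", "GATA"))
        assert [h.start for h in hits] == [1, 5]
        assert all(h.strand == "+" for h in hits)

    def test_degenerate_first_position(self):
        hits = scan_motif(prom("AGATTCGATT"), Motif("arr1", "NGATT"))
        assert [h.start for h in hits] == [1, 6]

    def test_sequence_shorter_than_motif(self):
        assert scan_motif(prom("GAT"), Motif("gata", "GATA")) == []

    def test_overlapping_self_similar_runs(self):
        # AAAA in AAAAAA: starts 1,2,3 (all overlaps counted)
        hits = scan_motif(prom("AAAAAA"), Motif("a4", "AAAA"))
        assert [h.start for h in hits] == [1, 2, 3]

    def test_promoter_ambiguity_only_matches_motif_n(self):
        # R in the promoter must not satisfy motif A or motif R positions
        assert scan_motif(prom("GRTA"), Motif("gata", "GATA")) == []
        assert len(scan_motif(prom("GNTA"), Motif("gnta", "GNTA"))) == 1

    def test_both_strands_reports_reverse_hits(self):
        hits = scan_motif(prom("TATC"), Motif("gata", "GATA"), strands="both")
        assert [(h.start, h.strand) for h in hits] == [(1, "-")]

    @given(dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_both_strand_total_invariant_under_revcomp(self, seq):
        if not seq:
            return
        p1, p2 = prom(seq), prom(reverse_complement(seq))
        for m in (Motif("gt1", "GRWAAW"), Motif("ebox", "CANNTG"), Motif("w", "TGACY")):
            assert len(scan_motif(p1, m, "both")) == len(scan_motif(p2, m, "both"))

    @given(dna, dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_monotone_under_append(self, seq, extra):
        m = Motif("arr1", "NGATT")
        if len(seq) < len(m.iupac):
            return
        before = len(scan_motif(prom(seq), m))
        after = len(scan_motif(prom(seq + extra), m))
        assert after >= before

    def test_agrees_with_expansion_oracle_on_random_sequences(self, library, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 300))
            p = prom(seq)
            for m in library:
                for strands in ("forward", "both"):
                    assert len(scan_motif(p, m, strands)) == count_oracle(
                        seq, m.iupac, strands
                    ), (m.name, strands)


class TestOccurrenceTable:
    def test_poly_c_promoter_yields_zero_rows(self, library):
        t = occurrence_table([prom("C" * 500)], library)
        assert (t.counts.to_numpy() == 0).all()

    def test_equals_per_cell_recomputation(self, library, rng):
        proms = [
            prom("".join(rng.choice(list("ACGT"), 200)), gene=f"g{i}")
            for i in range(3)
        ]
        t = occurrence_table(proms, library)
        for p in proms:
            for m in library:
                assert t.counts.at[p.gene_id, m.name] == len(scan_motif(p, m))

    def test_duplicate_gene_ids_rejected(self, library):
        with pytest.raises(ValueError):
            occurrence_table([prom("ACGT"), prom("TTTT")], library)


def table(data: dict, genes: list) -> OccurrenceTable:
    return OccurrenceTable(pd.DataFrame(data, index=genes))


class TestClassification:
    GENES = ["g1", "g2", "g3", "g4", "g5"]

    def test_common_motif_reports_max_copies(self):
        t = table({"m": [1, 2, 7, 1, 3]}, self.GENES)
        (c,) = classify_common(t)
        assert (c.motif, c.max_copies, c.missing_genes) == ("m", 7, ())

    def test_tolerance_missing_threshold(self):
        t = table({"m": [1, 2, 7, 0, 3]}, self.GENES)
        assert classify_common(t, tolerance_missing=0) == []
        (c,) = classify_common(t, tolerance_missing=1)
        assert c.missing_genes == ("g4",)

    def test_empty_library_gives_empty_report(self):
        t = OccurrenceTable(pd.DataFrame(index=self.GENES))
        assert classify_common(t) == []

    def test_unique_requires_exactly_one_carrier(self):
        t = table({"u": [0, 2, 0, 0, 0], "two": [1, 1, 0, 0, 0],
                   "none": [0, 0, 0, 0, 0]}, self.GENES)
        (u,) = classify_unique(t)
        assert (u.motif, u.gene, u.copies) == ("u", "g2", 2)

    def test_unique_undefined_for_single_promoter(self):
        with pytest.raises(ValueError):
            classify_unique(table({"m": [1]}, ["g1"]))

    def test_family_restricted_needs_two_genes_one_family(self):
        fams = {"g1": "SUC", "g2": "SUC", "g3": "HT", "g4": "HT", "g5": "TMT"}
        t = table({
            "restricted": [1, 3, 0, 0, 0],   # two SUC genes only
            "crossfam": [1, 0, 2, 0, 0],     # spans SUC and HT
            "single": [0, 0, 0, 0, 4],       # unique, not restricted
        }, self.GENES)
        res = family_restricted(t, fams)
        assert [(r.motif, r.family) for r in res] == [("restricted", "SUC")]

    def test_family_restricted_requires_full_mapping(self):
        with pytest.raises(ValueError, match="g2"):
            family_restricted(table({"m": [1, 1]}, ["g1", "g2"]), {"g1": "SUC"})

    def test_sugar_repertory_counts_distinct_motifs(self):
        t = table({"A": [3, 0], "B": [0, 1], "C": [1, 1]}, ["g1", "g2"])
        rep = sugar_repertory(t, ["A", "B", "C"])
        assert rep.at["g1", "distinct_motifs"] == 2
        assert rep.at["g2", "distinct_motifs"] == 2
        empty = sugar_repertory(t, [])
        assert (empty["distinct_motifs"] == 0).all()

    def test_sugar_repertory_rejects_unknown_names(self):
        with pytest.raises(ValueError):
            sugar_repertory(table({"A": [1, 0]}, ["g1", "g2"]), ["A", "missing"])

    def test_composite_requires_every_component(self):
        t = table({"AMYBOX1": [1, 1], "AMYBOX2": [2, 1], "PYR": [1, 0]},
                  ["g1", "g2"])
        flags = detect_composite(t, ["AMYBOX1", "AMYBOX2", "PYR"])
        assert bool(flags["g1"]) and not bool(flags["g2"])

    def test_composite_empty_components_rejected(self):
        with pytest.raises(ValueError):
            detect_composite(table({"A": [1, 1]}, ["g1", "g2"]), [])

    def test_common_unique_restricted_disjoint_on_random_tables(self, rng):
        fams_pool = ["SUC", "HT", "TMT", "PMT"]
        for _ in range(100):
            n_genes = int(rng.integers(2, 9))
            n_motifs = int(rng.integers(1, 7))
            genes = [f"g{i}" for i in range(n_genes)]
            counts = rng.poisson(0.7, size=(n_genes, n_motifs))
            t = OccurrenceTable(pd.DataFrame(
                counts, index=genes, columns=[f"m{j}" for j in range(n_motifs)]))
            fams = {g: fams_pool[i % 2] if i < 2 else fams_pool[int(rng.integers(4))]
                    for i, g in enumerate(genes)}
            common = {c.motif for c in classify_common(t)}
            unique = {u.motif for u in classify_unique(t)}
            restricted = {r.motif for r in family_restricted(t, fams)}
            assert not (common & unique)
            assert not (unique & restricted)
            assert not (common & restricted)


class TestExtractPromoter:
    GENOME = SequenceRecord("chr1", "ACGT" * 1000)  # 4000 bp

    def test_full_length_plus_strand(self):
        gene = AnnotationRecord("g", "chr1", "+", 2001, (2001, 2400))
        p = extract_promoter(gene, self.GENOME)
        assert p.length == 2000
        assert not p.truncated
        assert p.residues == self.GENOME.residues[0:2000]

    def test_truncation_at_upstream_feature(self):
        gene = AnnotationRecord("g", "chr1", "+", 2001, (2001, 2400))
        upstream = AnnotationRecord("u", "chr1", "+", 1000, (1000, 1500))
        p = extract_promoter(gene, self.GENOME, [upstream])
        assert p.length == 500
        assert p.truncated
        assert p.residues == self.GENOME.residues[1500:2000]

    def test_minus_strand_clipped_at_chromosome_end(self):
        genome = SequenceRecord("chr1", "ACGT" * 250)  # 1000 bp
        gene = AnnotationRecord("g", "chr1", "-", 100, (10, 100))
        p = extract_promoter(gene, genome)
        assert p.length == 900
        assert p.truncated
        assert p.residues == reverse_complement(genome.residues[100:1000])

    def test_minus_strand_truncation_at_downstream_coordinates_feature(self):
        gene = AnnotationRecord("g", "chr1", "-", 1000, (500, 1000))
        neighbour = AnnotationRecord("u", "chr1", "+", 1624, (1624, 2000))
        p = extract_promoter(gene, self.GENOME, [neighbour])
        # 623-bp promoter: bases 1001..1623 reverse-complemented
        assert p.length == 623
        assert p.truncated
        assert p.residues == reverse_complement(self.GENOME.residues[1000:1623])

    def test_zero_length_promoter_is_an_error(self):
        gene = AnnotationRecord("g", "chr1", "+", 1, (1, 100))
        with pytest.raises(ValueError):
            extract_promoter(gene, self.GENOME)

    def test_short_max_len(self):
        gene = AnnotationRecord("g", "chr1", "+", 2001, (2001, 2400))
        p = extract_promoter(gene, self.GENOME, max_len=100)
        assert p.length == 100
        assert not p.truncated
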