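# Methods

This note records the models, rules and numerical choices behind
`vitisugar`, and what the synthetic-data validation does and does not
demonstrate.

## Subfamily classification by percent similarity

Queries are classified against a labelled reference panel by best-hit
percent similarity, a reproducible stand-in for the BLAST screens and
desktop alignment suites such surveys traditionally use.  Percent
similarity between two proteins is defined as

    100 · #(aligned residue pairs identical or within one strong group)
        / length of the shorter sequence

computed on one optimal global alignment.  The strong conservation
groups are the classic sets STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF,
HY, FYW.  Because only residue/residue columns count and the
denominator is the shorter sequence, the value lives in [0, 100] and
equals 100 exactly when every residue of the shorter sequence is
matched by an identical-or-similar partner — including the degenerate
case of a short sequence embedded gaplessly in a longer one.  Desktop
packages differ in alignment parameters and rounding, so published
percentages from any particular program are context, not oracles, for
this implementation.

Alignment is optimal global (Needleman–Wunsch) with affine gaps via
Biopython's `PairwiseAligner` over a three-level substitution matrix
(match 1, strong-group 0.5, mismatch 0; gap open −10, extend −0.5,
where a length-L gap costs `open + (L−1)·ext` and end gaps are
penalized like internal ones).  These magnitudes are conventional; all
downstream decisions are threshold-based on the similarity percentage,
not on raw scores.  Among co-optimal alignments the aligner's canonical
traceback is used — deterministic, which is all the pipeline requires,
since co-optimal alignments can differ in similarity only at the
margin.

Assignment takes the subfamily of the most similar panel entry and
reports the margin to the best hit in any other subfamily.  Below a
similarity floor (default 30 %, safely under the lowest intra-family
similarity seen in real transporter families, ~36 %) the result is an
explicit *unassigned*; an exact cross-subfamily tie yields *ambiguous*
with both candidates.  Neither is an error: real surveys contain
partial and misassembled ORFs.

The family tree is neighbor joining (scikit-bio) on
`d = (100 − similarity)/100`, with negative branch lengths clamped to
zero.  No multiple-hit correction is applied: the tree is an
illustrative grouping device, not an evolutionary estimate, and is
documented as such.  For additive inputs NJ reproduces tip-to-tip
distances exactly, which is what the test suite checks.

## Promoter extraction

The promoter is the ≤2 kb immediately 5' of the first base of the
start codon: on '+', bases `[cds_start − 2000, cds_start − 1]`; on '−',
bases `[cds_start + 1, cds_start + 2000]` reverse-complemented.  The
window is clipped at the chromosome edge and at the proximal boundary
of the nearest other annotated feature (exclusive) — the rule that
yields short promoters for genes with a close upstream ORF.  Clipping
uses the neighbouring feature's annotated bounds rather than its stop
codon, since annotation-level bounds are what a GFF3 reliably provides.
A zero-length window is an error rather than an empty promoter.

## Motif scanning and classification

Cis-elements are IUPAC-degenerate words.  Scanning reports every
window match, overlaps included — necessary for short, highly
repetitive elements that legitimately occur tens of times in 2 kb.
Matching is conservative about ambiguity in the *scanned* sequence: an
assembly `N` (or any ambiguity code) in a promoter satisfies only a
motif `N`, never a concrete or degenerate motif position.  The default
is forward-strand-only counting; `strands="both"` also scans the
reverse complement and counts (start, strand) pairs without palindrome
deduplication, so self-complementary patterns like CANNTG count twice
in that mode.  Both-strand totals are invariant under
reverse-complementing the input, a property the suite verifies.

The packaged library is exactly the 30 elements whose consensus strings
the package documents (20 common elements, 9 single-gene elements, and
the S-box CACCTCCA); anything else must be user-supplied as JSON — no
silent external lookups.  Classification rules over the
promoter × motif count table:

* **common** — nonzero in all but at most `tolerance_missing`
  promoters (default 0; real surveys effectively tolerate a short
  promoter missing a few elements, so the tolerance is a flag, not a
  hard-coded exception), reported with the maximum copies per promoter
  and the missing genes;
* **unique** — nonzero in exactly one promoter (undefined for a single
  promoter: error);
* **family-restricted** — all carriers in one subfamily, with at least
  two carriers (a single carrier is *unique*, keeping the two reports
  disjoint);
* **sugar repertory** — per gene, the number of *distinct* elements
  from a user-chosen sugar-responsive set with count ≥ 1, ranked;
* **composite** (e.g. GARC = AMY boxes + pyrimidine box) — flagged
  when every component is present, with no spacing constraint, since
  none is defined for these elements at consensus level.

With ≥2 promoters and tolerance 0 the common, unique and restricted
sets are pairwise disjoint whenever the gene set spans ≥2 families;
the acceptance checks sample 1,000 random tables under those
conditions.

## Macroarray quantification

Per membrane: `corrected = max(raw − background, 0)` (negative
intensities are physically meaningless); a gene is *present* only if
its mean corrected intensity strictly exceeds the negative-control
mean; relative expression divides each spot by the mean over the four
reference genes of their mean corrected intensities.  Normalization is
per membrane, before any cross-membrane averaging, so membrane-level
exposure differences cancel exactly — the pipeline is invariant to
rescaling any membrane's intensities, to 1e-12, and the reference
genes' own normalized mean is 1 by construction.  An absent reference
gene invalidates the membrane (error naming it) rather than silently
degrading the normalizer.

Replicates are pooled at spot level: three spots per membrane × two
membranes = six values, with absent membranes contributing zeros and
presence defined as present-on-≥1-membrane.  Pooling at spot level
rather than membrane level keeps the reported SD an honest spot-level
dispersion; a single-membrane condition is accepted with a warning and
n = 3.  The standard deviation uses ddof = 1.

Condition means average over *all* profiled genes, absent genes
contributing zero — this reproduces the usual "above the organ mean"
red-point denominator.  The high-expression call is strict (`>`).  The
preferential-expression summary quantifies the qualitative bold /
underline conventions of summary figures: *most expressed* = argmax
gene(s) per condition; *preferential* = level ≥ fold × the gene's
cross-condition mean (fold default 2, must exceed 1); *induced over
development* = non-decreasing across the ordered stage series with
final ≥ fold × first.  These thresholds are declared surrogates for
conventions that are typographic in the source figures; they are
parameters, not claims.

The doubled spotting mass of reference versus transporter cDNA is not
corrected for — values are relative units, comparable within the
experiment — but `reference_mass_factor` allows a sensitivity
analysis.  The Northern-blot variant normalizes to a single reference
gene (ratio, reference = 1.0; zero or missing reference is an error).

## Synthetic data

Generators draw from per-stream RNGs keyed by (stream id, seed), so
adding a generator never perturbs another's output and everything is
bit-reproducible for a fixed seed.

* **Promoters**: planted copies of a consensus are realized as concrete
  words drawn from its IUPAC expansion and placed at random
  non-overlapping positions with ≥1 background base between plants
  (slack distributed multinomially).  On a poly-C background — inert
  for every packaged motif, all of which require a non-C base — the
  generator re-scans each promoter with a brute-force
  expansion-and-window oracle (an independent algorithm from the
  production regex scanner) and raises if realized counts deviate from
  the planted truth, so "truth equals scanner output" is
  guaranteed-or-error rather than assumed.  On random backgrounds the
  truth records planted copies only and background matches are
  expected; such runs are for workload realism, not exactness tests.
* **Membranes**: spot intensity = exposure × level × noise +
  background, with unit-mean log-normal noise
  (σ = √ln(1 + cv²)), gene level = truth × mean reference level,
  reference levels (900, 1100, 1000, 1200), negative control 40,
  additive background 25 (arbitrary intensity units of the same order
  as real phosphor-imager quantifications).  Triplicate spots and two
  membranes per condition mirror the design the pipeline assumes.  At
  cv = 0 the pipeline recovers the truth matrix exactly provided every
  entry exceeds the detection level implied by the negative control
  (negative_level / mean reference level ≈ 0.038 relative units at the
  defaults); validation matrices are drawn from U(0.05, 0.6), the
  order of magnitude of real relative-expression values, so every
  entry is detectable in the noise-free check.
* **Families**: a synthetic reference panel with one random ancestor
  per subfamily and members diverged at 10 % substitutions per site;
  queries are panel members mutated i.i.d. at a stated rate (≤0.5;
  beyond that the source is unidentifiable by construction).  Random
  additive trees (uniform branch lengths 0.1–1.0) with their exact
  tip-to-tip distance matrices support the NJ recovery checks.

### What passing tests do and do not show

The synthetic promoters have i.i.d. or constant backgrounds, not real
nucleotide composition, repeats or CpG structure; planted counts test
the *scanner and classifiers*, not any biological enrichment claim.
The membrane simulator has purely multiplicative spot noise and a
uniform background — no spatial gradients, saturation, bleed-over or
print-tip effects, which real membranes have and which this pipeline
(starting from quantified spot tables) does not model.  The family
simulator's subfamilies are unrelated random ancestors, so
between-subfamily similarity sits at the random baseline; real
subfamilies share deep homology and assignment margins will be
narrower.  Accuracy numbers from these simulations are therefore
upper bounds on real-data behaviour, and are presented as validation
of the implementation, not of the biology.

## Problem sizes and numerics

Validation uses 200 random 500-bp sequences for scanner/oracle
equivalence; a 29-promoter planted design with copy numbers spanning
0–45; 1,000 random occurrence tables for disjointness; 24 genes × 6
conditions for expression recovery (Pearson r > 0.95 at cv = 0.1); 500
simulated queries for subfamily recovery (≥99 % at 10 % divergence);
and 20 random additive trees of 5–12 leaves for NJ (RF = 0, path
lengths within 1e-9).  Alignment optimality is checked against
explicit enumeration of every alignment — exhaustive over all ordered
pairs of sequences up to length 3 over a 4-letter alphabet, plus a
seeded sample covering every length combination up to 6 — because full
enumeration beyond that is combinatorially explosive while adding no
new structure.  Floating-point equalities use 1e-12 absolute
tolerances for invariance claims and exact integer equality for counts.
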