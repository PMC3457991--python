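# Methods

`mirindel` analyses how small insertions and deletions (indels) affect
microRNA targeting. The pipeline has five stages — indel classification,
region density profiling, seed-site impact scanning, pathway
summarisation, and LD-based linking to association-study markers — plus a
synthetic-data generator that produces every input with known ground
truth. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Coordinates and variant representation

Internally all intervals are 0-based, half-open. VCF positions are 1-based
anchor-base style (an indel record carries one shared anchor base:
`A → AC` inserts a `C`); BED is native 0-based. Conversions happen only at
the I/O boundary, so off-by-one drift cannot accumulate. Multi-allelic
VCF rows are split and each alternate allele analysed independently.
Mature miRNA sequences are stored as RNA (ACGU) and converted to DNA only
where genome comparisons happen; reported motifs are DNA.

Real dbSNP ingestion would additionally need an allele normaliser for
records given without an anchor base; the readers here assume anchor-base
style throughout.

## Indel classification

Indels fall into three disjoint classes following the size/repeat
taxonomy used in genome-wide indel surveys:

1. **single-base-pair** — any net length-1 indel. Size is tested first,
   so a 1-bp indel adjacent to a homopolymer is still class (1); this
   keeps the classes disjoint and the size class purely size-defined.
2. **repeat expansion** — net length ≥ 2 where the inserted/deleted
   sequence S is a whole number ≥ 1 of copies of a unit u (1 ≤ |u| ≤ |S|)
   *and* the reference immediately adjacent to the variant carries at
   least one further copy of u. Adjacency is checked right of the
   insertion point first, then left; for deletions both sides of the
   deleted span. One full adjacent unit copy suffices — the minimal
   operational reading of "repeated sequences", since no published
   operational rule exists.
3. **other** — everything else with |S| ≥ 2.

The classifier is validated exactly against a brute-force oracle that
enumerates every unit/copy-count decomposition on 1,000 random indels in
random 200-nt contexts.

## Region systems and variant density

Each pre-miRNA (~100 nt hairpin) defines seven labelled regions: the
precursor, the mature arm(s) (~22 nt), the seed sub-interval (mature
positions 2–8 by default, 1-based in mature orientation; configurable via
`seed_span` because the field uses both 2–7 and 2–8 conventions), and two
successive flanks per side, each flank exactly the precursor's length.
On '−'-strand miRNAs the 5′ flanks have the larger coordinates.
Argonaute crosslink footprints (canonically 41 nt) get the analogous
five-region system with flanks of footprint length. Flanks running off a
chromosome end are truncated and the unit flagged.

Density is variants per nt, assigned by the anchor base's point position
(a variant lands in exactly one region; deletions count at their anchor).
Densities are computed **per unit** (one miRNA, one footprint) and then
summarised across units as mean ± SEM — error bars require a per-unit
sample, which pooled counts would not provide. The "average across all
flanking regions" statistic is the per-unit pooled density over the four
flank regions. Overlapping flanks of clustered miRNAs may each count a
shared variant once per unit; unit-level statistics need no deduplication
rule.

Two-group comparisons use Welch's unequal-variance two-sided t-test
(region variances differ by construction; the groups are per-unit
densities). Degenerate comparisons (fewer than 2 units in a group) are
refused with an explicit message rather than returning NaN.

## Seed-site impact scanning

Six canonical seed-site types are scanned by default, each defined by the
mature miRNA positions it pairs (1-based, inclusive) and whether an
adenine faces miRNA position 1:

| type        | miRNA span | 3′ A | motif length |
|-------------|-----------|------|--------------|
| 8mer        | 2–8       | yes  | 8 |
| 7mer-m8     | 2–8       | no   | 7 |
| 7mer-A1     | 2–7       | yes  | 7 |
| 6mer        | 2–7       | no   | 6 |
| offset-6mer | 3–8       | no   | 6 |
| offset-7mer | 3–9       | no   | 7 |

A site motif is the DNA reverse complement of the spanned mature
positions, with `A` appended at the site's 3′ end for the A1-anchored
types. The set is configuration, not a constant, because the offset-type
composition varies between catalogues in the literature.

For each variant a window of `half_width` = 50 nt of flank is taken on
either side of the reference allele span ("100 bp surrounding the
variant"); the mutant window substitutes the alternate allele. Both
windows are scanned for every exact motif occurrence (overlaps included;
`N` never matches). Mutant match offsets strictly right of the variant's
left edge are shifted back by the net length change before the match sets
are compared — without this normalisation every downstream site would
spuriously appear disrupted *and* created. A site present in the
reference but absent (after mapping) from the mutant is **disrupted**;
the converse is **created**. Nested shorter types destroyed along with an
8mer are reported individually. Because the shortest type is 6 nt, the
"6mer or longer" gate holds by construction.

Scanning is on the transcript sense strand: for regions annotated on '−',
the motifs are reverse-complemented and scanned against the plus-strand
genome windows, which is equivalent and keeps a single diff path.

Two scan modes mirror the two kinds of experimental evidence:
footprint scans test every catalogued miRNA (a crosslink footprint
evidences binding but not the binding partner's identity is certain),
while pair scans restrict each gene's UTR variants to its experimentally
supported miRNA partners only.

The engine is verified to agree *exactly* with an independent
scan-both-windows-and-set-subtract oracle on 1,000 random fixtures, and
to recall 100% of generator-planted sites.

## Pathway summary

A gene is flagged if at least one impact call touches any of its UTR
variants — the table counts genes, not sites. SNVs reuse the identical
scan machinery (there is deliberately no separate SNV code path). Rows
report, per pathway, the member-gene count and the number/percentage of
flagged genes for indels and SNVs against the shared pathway denominator,
rounded half-up to 2 decimals; pathways with fewer than `min_genes` = 10
indel-flagged genes are dropped and rows are sorted by that count.
Membership denominators come from the user-supplied membership table.
Enrichment p-values are intentionally not computed — the summary is a
counting table.

## LD blocks and GWAS linking

Pairwise linkage disequilibrium is estimated from unphased 0/1/2
genotypes by the standard two-locus EM (only double heterozygotes carry
phase ambiguity; missing genotypes are dropped pairwise; convergence at
Δ < 1e-9 or 1000 iterations). |D′| = |D|/D_max with the usual
allele-frequency-constrained maximum.

The confidence interval follows the likelihood-grid construction: with
allele frequencies fixed at their MLEs, the multinomial likelihood of the
genotype table is evaluated on a 101-point |D′| grid (sign from the point
estimate), normalised, and (cl, cu) read off as the 5th/95th percentiles
of the cumulative likelihood. Percentiles use **discrete ceiling
quantiles** (the smallest grid value whose cumulative mass reaches the
percentile) rather than linear interpolation: with the likelihood mass
concentrated at the |D′| = 1 boundary, interpolation would yield
cu ≈ 0.9995 < 1 and exclude the MLE from its own interval; the ceiling
convention keeps the MLE inside [cl, cu] and matches how tail mass is
accumulated in the classic desktop implementation.

Blocks follow the confidence-interval rule: a pair is *strong LD* when
cl ≥ 0.7 and cu ≥ 0.98, and shows *strong recombination* when cu < 0.9;
markers with MAF < 0.05 are excluded first. A candidate run of markers
qualifies when its end pair is strong LD and ≥ 95% of its informative
internal pairs (strong ∪ recombination) are strong; non-overlapping
qualifying runs are selected greedily, largest genomic span first, ties
leftmost. The extra distance-dependent rules some implementations apply
to 2- and 3-marker blocks are deliberately **not** replicated — only the
four stated thresholds are used, and that divergence is documented here.

Linking: every indel in a miRNA or a supported target site is tested
against every GWAS marker within 100 kb; blocks are called on the
surrounding panel markers and a link is reported iff indel and marker
fall inside the same block. Indels or markers absent from the genotype
panel are skipped with a log record — pairwise LD needs both as panel
markers.

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs:

* i.i.d. genome at GC 0.41 (human-like), default 400 kb;
* 30 pre-miRNAs (~100 nt, one 22-nt mature arm each, both strands),
  40 UTRs (400–1200 nt), 60 footprints (41 nt) inside UTRs;
* Poisson variant placement per region with suppressed core densities
  (defaults, variants/nt: flanks and UTR 0.012, precursor 0.010, mature
  0.005, footprint 0.004), indels 18% of variants — matching the
  genome-wide share of indels among known variants;
* engineered indel classes in proportions 0.55/0.14/0.31
  (single/repeat/other), the blend reported for miRNA- and UTR-resident
  indels; repeat expansions are built as insertions whose unit is read
  off the reference right of the anchor, so adjacency holds by
  construction (repeat-class deletions are not generated — a simulator
  simplification, not a classifier limitation);
* planted seed sites: a configurable fraction of UTR/footprint indels is
  placed to overlap a motif written into the genome (transcript-sense,
  strand-aware), with the expected disrupted/created status verified at
  generation time by plain substring logic that is independent of the
  scanning module under test;
* genotype panels with two blocks of six markers (two complementary
  founder haplotypes per block → within-block |D′| = 1, free
  recombination between blocks, founder frequency 0.3–0.7 so MAF ≥ 0.05),
  the first block centred on a planted indel, plus a GWAS marker table.

Every output is a pure function of the configuration; sub-seeds derive
from the master seed by stable hashing of component names, and reruns are
byte-identical. Chance motif occurrences are permitted (forbidding all
motifs of all miRNAs would be infeasible and unrealistic); tests handle
them by oracle rescan rather than exact output matching.

What the generator does *not* emulate: mutation-rate heterogeneity,
coalescent genealogies, sequencing error, overlapping genes, clustered
miRNAs sharing flanks, multi-mature hairpins (supported by the data
model, not generated by default), and repeat-class deletions. Passing
tests therefore demonstrate correctness of the pipeline's logic under
controlled conditions, not performance on real population data.

## Problem sizes used in validation

The validation suite runs the seed-engine oracle on 1,000 random
fixtures; class-mix recovery on ~2,600 engineered indels; density-ratio
recovery and significance on a 300-miRNA fixture with mature density half
the flank density; type-I calibration over 250 null fixtures of 60 miRNAs
each; and Gabriel block recovery over 100 simulated two-block panels of
120 individuals. These sizes give comfortable binomial resolution for
every claim while keeping a full run in tens of seconds on one core.

## Known limitations

* Exact seed complementarity only — no thermodynamic or context scoring,
  no conservation filtering.
* The impact diff compares motif match *sets*; a site shifted by exactly
  the indel length cancels, which is the intended reading but means a
  disrupted-and-identically-recreated site produces no call.
* LD is pairwise; no multi-marker phasing, no r², no imputation.
* The pathway table is a counting summary, not an enrichment test.
* Minimal VCF support (CHROM POS ID REF ALT); INFO/FORMAT are ignored.
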