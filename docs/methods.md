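# Methods

## Coordinates and gene models

All coordinates are 1-based inclusive (GFF3 convention); interval length is
`end − start + 1`, so the printed *sd1* locus chr1:40,361,934–40,364,270 is
2337 bp. A `GeneModel` keeps exons and CDS segments in transcription order
(descending genomic coordinates on the − strand); every CDS segment must lie
inside an exon, exons may not overlap. The synthetic models are fully coding
(CDS = exons, phase 0); the I/O layer accepts arbitrary gene/mRNA/exon/CDS
hierarchies.

## Pairwise alignment

`align_global` computes an optimal global alignment with affine gaps
(engine: Biopython's `PairwiseAligner`; a gap of length L costs
`gap_open + (L−1)·gap_extend`). Defaults: match +2, mismatch −6, gap open
−8, gap extend −2.

*Why mismatch −6.* The deletion characterization must keep a single matched
base ("anchor") inside a long deletion block as a match rather than merging
the two surrounding gap runs. Comparing the anchored alignment with the
merged alternative (one fewer gap open, the anchor base paired at a block
edge), the anchored form wins exactly when
`mismatch < match − gap_open + gap_extend = 2 − 8 + 2 = −4`. A shallow
mismatch like −3 would merge the gap and silently absorb the anchor; −6
keeps the anchored structure optimal with a margin of 2 while remaining a
reasonable penalty for near-identical allele comparisons.

*Determinism.* Among co-optimal alignments the package canonicalizes gap
placement by score-neutral leftward sliding (the convention used for indel
normalization in variant calling). This pins the frameshift junction of the
coding-frame scenario at 293/294 — the rightmost placement would slide the
shared junction guanine into the matched prefix and report 294/295 — and
makes every reported block boundary reproducible.

Identity is computed over both-residue columns; coverage of each input is
the percentage of its residues paired with a residue of the other input.

## Deletion characterization

1. Align the two gene-region sequences; classify columns as match, mismatch,
   reference-only or derived-only.
2. A deletion *event* is a maximal run of reference-only columns, allowing
   interruptions of at most `max_anchor_run` (default 2) consecutive matched
   columns; those interruptions are the anchored bases. Net genomic deletion
   = event columns − anchored bases.
3. Align the two CDSs the same way. Reference CDS positions missing from the
   derived CDS are partitioned by projecting each, through the genomic
   alignment, onto the derived gene: positions whose homologue survives
   inside a derived intron count as `intronic_deletion_bp` (coding sequence
   decommissioned, not deleted); the remainder is `cds_deletion_bp`.
   For the semidwarf coding-frame structure this yields 363 missing coding
   columns = 280 deleted + 83 intronized. (Consequently the derived CDS
   *string* is 363 nt shorter than the reference CDS; the 280 figure counts
   DNA actually absent from the derived genome.)
4. `frameshift` ⇔ `cds_deletion_bp mod 3 ≠ 0`. The junction is the number of
   derived CDS bases before the first missing column (the last in-frame
   position); the codon spanning the junction is read off both CDSs and
   compared — "preserved" when both translate to the same amino acid (the
   valine case: the base completing the split codon is the same guanine on
   both sides).

Degenerate inputs: an identical pair produces an all-zero report with
`frameshift_junction = None`; models without CDS annotation raise a model
error; zero alignable identity raises an alignment error.

## Synthetic deletion scenarios

`gen_sd1_pair` realizes a configured block: `deletion_span` aligned columns
starting at `deletion_start` (required to lie inside the reference's first,
coding exon — which keeps the truth arithmetic exact and mirrors where the
real deletion begins), of which the first `derived_intron1_length` columns
survive re-annotated as a novel intron and `anchored_positions` survive as
isolated matched adenines. Derived exon structure is obtained by deleting
the removed positions and compressing the feature labels, which naturally
produces the three-exon semidwarf-style model when an intron is
decommissioned mid-exon.

Truth reports are computed from the configuration (and the constructed
sequences, for the junction codon), never from an alignment. To make the
configured gap structure the unique optimum, the generator adjusts bases by
rejection: no gap run may slide left score-neutrally (run-end base differs
from the base preceding the run, for the runs seen by both the genomic and
the CDS alignment), and the anchor base may not occur inside either adjacent
gap run. The two canned configurations are:

- **anchored scenario** — 2743-bp three-exon reference (exons 981/558/600),
  383-column block at 295 with one anchor at 297 → truth: 382 bp genomic,
  1 anchored base, 383 block columns;
- **coding-frame scenario** — 2063-bp two-exon reference (exons 981/780),
  363-column block at 294 with an 83-bp decommissioned intron → truth:
  280 bp coding loss, 83 bp intronic, frameshift junction 293, preserved
  valine. The derived exon 1 carries 293 coding nt, i.e. 98 amino-acid
  positions (⌈293/3⌉).

What the generator does *not* emulate: sequencing reads and mapping noise,
multi-event structural divergence, UTRs and alternative transcripts,
3000-cultivar scale, and base composition beyond an i.i.d. model. Passing
tests therefore demonstrate correctness of the analytical logic on clean,
unambiguous loci — not robustness to assembly error or annotation noise in
real genomes.

## R-gene evidence and calls

Thresholds (constants in `rgenes`): e-value < 1e−10 strict (the stated
blastp parameter), identity ≥ 70, query coverage ≥ 70; orthologue-free
fallback coverage > 50 ("query" = the cloned R gene / NB-ARC domain);
per-domain e-value < 1e−5 for NLR classification. "The blastn hit was
better" is operationalized as genome-hit bitscore > protein-hit bitscore,
the only comparable score in outfmt-6-like evidence. One rule the three-way
scheme leaves open — a found candidate whose protein support fails the
thresholds — is called `M` here: the gene is evidenced (orthologue or high
coverage) but its protein is not intact; disagreement flags on the call
record which rule fired. Tightening any threshold can only move verdicts
along `+ → M → −`, never the other way (property-tested).

The chi-squared goodness of fit is the uncorrected Pearson statistic with
`df = k − 1` and an upper-tail p-value (scipy); no Yates correction, which
is what reproduces X² = 0.018098 / p = 0.893 for observed (69, 101) against
proportions (90/219, 129/219). The positive-selection filter keeps rows with
FDR strictly below α = 0.05.

The evidence generator plants clean per-class patterns: present = orthologue
plus a hit passing all thresholds and a weaker genome hit; absent = no
orthologue and coverage drawn below 50%; mutated = passing hit plus either a
`truncated` flag or a genome hit drawn 1.1–1.5× the protein bitscore. Class
ranges are configurable but must keep the absent-class coverage below 50%.

## Haplotype analytics

Cell distance treats each call as an unordered allele pair (homozygotes
doubled): distance = 1 − shared/2, giving 0/0.5/1 and reducing to the
mismatch score on the worked rows (reference CGT: Nipponbare CGT → 0,
Parijat C/T,G,T → 0.5). Cultivar-to-cultivar distance is the mean
per-position mismatch over pairwise-complete positions (pairs with no
overlapping data default to distance 1).

Grouping is PAM-style k-medoids: seeded random medoid initialization, 10
restarts, alternating assignment/medoid-update until stable, best restart by
total cost; k ∈ 2..k_max selected by maximal average silhouette width
(sklearn, precomputed distances), ties toward smaller k. The all-singleton
partition k = n, which silhouette cannot score, is defined as 0 — this also
resolves the n = 2 edge case (two distinct cultivars → two singleton
groups). "Informative positions" are those where the group medoids disagree
— the positions a haplotype table prints.

MAF uses het-as-half counting, so counts sum to the non-missing total and
MAF ≤ 50%; major/minor ties break lexicographically for determinism.

The SNP annotator takes forward-strand alleles, locates the CDS coordinate
strand-aware (complementing alleles for − strand models), substitutes within
the codon and compares translations: synonymous ⇔ equal amino acids,
`stop_gained`/`stop_lost` for terminator changes, missense otherwise, with
both `Glu144Lys` and `E144K` labels. Positions inside the locus ± 2000 bp
(the conventional gene-proximal window) but outside the CDS are
`non_coding`; farther positions are out of range. A supplied reference
allele that contradicts the genome raises an error rather than annotating a
fiction.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline on gene-scale
inputs: ~2–3 kb loci for alignment (C-backed dynamic programming), 100
random deletion scenarios for the arithmetic identities, 50 planted evidence
genes, 100-cultivar genotype panels, and the complete 576-case
codon-substitution enumeration — sizes chosen so the whole suite completes
in well under a minute on one CPU while still exercising every rule at the
scale the quantities are defined on. Scores are small floats with exact
integer structure (half-integer mismatches, integer bp counts), so
comparisons are exact except where a tolerance is stated (chi-squared
statistic to 5e−7, p-value to 5e−4 for tail-function differences).

## Known limitations

- `characterize_deletion` expects forward-strand, single-transcript models;
  minus-strand loci should be re-oriented first (CDS extraction and SNP
  annotation are strand-aware).
- Coding loss is measured as net missing reference CDS positions; balanced
  substitution-rich divergence or multiple interleaved indel events are
  reported in aggregate, not per event.
- The +/−/M caller consumes evidence tables; it does not rerun BLAST,
  HMMER or OrthoFinder, and e-values are taken at face value.
- k-medoids silhouette selection assumes groups are separated by at least
  two informative positions; single-position groups may merge (silhouette
  favors k = 2).
- The annotator handles single-base substitutions only — no indels, splice
  sites or multi-nucleotide variants.
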