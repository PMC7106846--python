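# Methods

This note documents the models, rules and numerical choices behind the
pipeline, what the synthetic benchmark does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Sequence model

Transcripts are stored as spliced sense-strand mRNA with the mORF extent in
transcript coordinates; all internal coordinates are 0-based half-open,
GFF3 is read as 1-based inclusive, and emitted catalogues use 1-based
inclusive transcript coordinates.  Codons containing N (or any non-ACGT
base) never match ATG or a stop codon — a conservative reading of
ambiguous bases.  uORFs must have both start and stop codons inside the
5′-UTR; uORFs overlapping the mORF are excluded by design because their
conservation could reflect constraint on the main protein.  The
largest-ORF scan used by the fusion filter considers the three forward
frames only (curated RNAs are sense-oriented) and requires a complete stop
codon; ORFs running off the 3′ end are ignored so that the frame
comparison is always well defined.

## Search engine

The built-in engine is an exact Smith–Waterman local aligner (affine gaps,
BLOSUM62, gap open 11 / extend 1) over six-frame translations, with
Karlin–Altschul E-values `E = K·m·n·exp(−λS)` using ungapped constants
λ = 0.3176, K = 0.134 (nucleotide searches: match/mismatch +2/−3, gap 5/2,
λ = 0.625, K = 0.41).  `n` is the total nucleotide residue count of the
searched database.  These E-values approximate, not reproduce, a
production engine's numbers, which is why every E-value threshold is
configuration rather than a constant, and why a 12-column tabular adapter
(`load_external_hits`) exists for swapping in an external engine at the
search stage.  Stop codons translate to `*` and score through the matrix's
strongly negative `*` column, preventing local alignments from spanning
stops (which would corrupt putative-ORF reconstruction).  One best HSP is
kept per (subject, frame); no HSP chaining.  Nucleotide searches use a
shared-exact-word prefilter (word size 11, configurable, disable with
`word_size=None`) in the spirit of BLAST word seeding; at the 95%-identity
use case the miss probability is negligible.  Protein searches are not
seeded — every frame is scored exactly.

## Fusion filter

"Within the largest ORF" means full containment of the uORF-matching
nucleotide interval; partial overlap counts as separate (the conservative
choice for an ambiguous geometry, configurable in principle via the
classifier).  The uORF match's reading frame is ignored for containment;
the mORF match must lie in the largest ORF's frame.  When several hits
land on one companion RNA the lowest-E-value hit per query is used.  The
decision order is support first: with X+Y < 10 companions the uORF is
discarded as unsupported even if the ratio is also high.  Only
curated-RNA entries participate; EST/TSA evidence is deliberately excluded
from this statistic.

## Homology and contaminants

Putative-uORF reconstruction walks in the hit's frame on the
sense-normalized subject (negative-frame subjects are reverse-complemented
and coordinates remapped; the 5′-most codon on the normalized strand wins
any tie).  Hit pairs whose uORF and mORF matches fall on opposite strands
of one subject are dropped as incoherent.  The uORF–mORF overlap test
reduces to `putative_morf_start < putative_uorf_end`, the only overlap
geometry possible since the mORF extends 3′-ward.

The contaminant screen compares, per species, the number of near-identical
matches (E < 10⁻¹⁰⁰, identity ≥ 95%) against the species' *declared* total
sequence count.  Those totals describe the full public databases the
screen emulates and cannot be derived from a desk-scale database, so the
lineage table carries them as an optional fourth column.  Candidacy is
triggered only by cross-order matches; comparator species need declared
totals ≥ 5000; the hit is contaminant iff its own species' ratio is
strictly below some qualifying comparator's.  Same-order matches never
trigger nor compare.  Only EST/TSA subjects are screened — curated RNAs
are trusted.

## Ka/Ks test

The estimator is Nei–Gojobori (1986) pathway counting: per codon,
synonymous site counts are the fraction of single-base alternatives
preserving the amino acid (changes to stop codons count as nonsynonymous);
differences average over all orderings of the differing positions with
equal weight, excluding orderings that pass through a stop codon unless
all do; Jukes–Cantor correction `d = −3/4·ln(1 − 4p/3)` is applied per
class, with p ≥ 3/4 reported as saturated (undefined).  Codon columns with
a gap or N in either row are skipped pairwise; whole columns are never
removed.  The estimator is deliberately fully specified so it can be
verified against an independent hand-count oracle over all 61×61 codon
pairs; it is pluggable if a different estimator family is preferred.
Note that a single saturating codon pair (e.g. GGT↔GGC alone: one
synonymous difference over one synonymous site) has an undefined distance;
in practice uORFs contribute 15–60 codons and saturation is rare.

Pairing is original-vs-each-homolog, matching the null construction;
all-vs-all is available as an option.  Pairs with ks = 0 or saturated
distances are excluded from the median and counted separately — mapping
them to infinity would make the median undefined exactly when conservation
is strongest.

The null model generates, per homolog, 100 artificial mutants of the
original uORF carrying exactly the homolog's observed nucleotide
difference count at uniformly sampled distinct positions (substituted
bases uniform over the three alternatives, no indels).  This preserves the
mutation load while destroying amino-acid-level constraint, so the null
Ka/Ks distribution sits near 1 regardless of divergence.  100 replicates
per homolog stabilizes the U test at the problem sizes the package
targets; replicate count and the mandatory seed are configuration.  The
per-candidate generator seed derives from the pipeline seed and a CRC of
the uORF id, so runs are reproducible and candidates independent.

The one-sided Mann–Whitney U test (alternative: observed ratios
stochastically smaller than null) enumerates all label assignments exactly
when both samples have ≤ 8 observations and otherwise uses the normal
approximation with tie and continuity corrections.  Benjamini–Hochberg
FDR is applied across candidates; acceptance requires median Ka/Ks < 0.5
and q < 0.05, both strict.  Representative selection floors E-values at
10⁻¹⁸⁰ before geometric means so that an external engine's printed 0 does
not collapse the product.

The built-in protein MSA is a progressive center-star aligner (BLOSUM62,
global pairwise steps, "once a gap always a gap" merging) whose rows
always degap back to their inputs; any multiple-alignment provider
honouring that contract can back the stage.

## Taxonomy

Classification is most-specific-first over NCBI-style clade names with the
NCBI synonyms (eudicots = eudicotyledons, Angiospermae = Magnoliophyta,
Gymnospermae = Acrogymnospermae); "other than" buckets apply only when no
subordinate category matched.  A lineage containing the unranked "rosids"
but neither fabids nor malvids maps to the eudicots bucket (this places
grape/Vitales there, consistent with the reference assignments).  The
conservation profile counts representative orders per category; the query
species' own category is reported separately since it is present by
construction even without a hit.

## Synthetic benchmark

The generator emulates: star-phylogeny gene families across 7 angiosperm
orders (2 species each, one order's entries EST-sourced, every other
family's ESTs reverse-complemented to exercise strand normalization, every
third family gaining a gymnosperm homolog to exercise the angiosperm
restriction); proposal–acceptance codon evolution (proposals at 0.25 per
interior nucleotide per branch, synonymous proposals always accepted,
nonsynonymous with probability ω, stop-creating proposals rejected) with
ω = 0.05 for conserved uORFs, 1.0 for neutral controls and 0.1 for all
mORFs; uORFs of 25 codons and mORFs of 61 within transcripts laid out as
pad–uORF–spacer–mORF–pad, the spacer carrying an in-frame stop upstream of
the mORF as real transcripts almost always do; fusion families whose
curated entries are uORF–mORF fusion isoforms at an exact planted count
(round(0.6 × 12)/12, so the true ratio is deterministic); and contaminant
EST entries that are 99.5% copies of one family member deposited under a
dedicated cross-order species with a small declared total (6000 vs the
default 20000), with the ORF-defining codons spared from copy noise so the
planted contaminant remains a recognizable homolog.

It does **not** emulate: indels (so codon alignments of planted families
are trivially gapless and the MSA stage is exercised mainly by its own
unit tests), codon-usage bias (uniform sense codons), intron evolution,
EST sequencing-error models beyond uniform substitutions, or realistic
database scale.  Passing the benchmark therefore demonstrates the
correctness of the decision rules and statistics under controlled
divergence, not performance on real public databases, where E-value
calibration, alignment quality and annotation errors dominate.

Default problem sizes (20 conserved + 20 neutral + 10 fusion families, 5
contaminants, ≈ 730 database entries of ≈ 300 nt) were chosen so a full
six-stage run takes a few minutes on one CPU while every decision rule
still fires on multiple instances.

## Known limitations

- E-values from the built-in engine are ungapped-regime approximations;
  absolute thresholds tuned for NCBI BLAST (E < 2000 especially) act
  more permissively here because the desk-scale database term `n` is small.
- The center-star MSA is O(k²) pairwise alignments and not benchmarked
  against progressive aligners on divergent peptides; for production use,
  plug in an external MSA.
- HG-style grouping of accepted CPuORFs into peptide families, and
  manual curation steps (alignment trimming, protein-database
  cross-checks), are out of scope; splice variants sharing peptide
  sequence are all reported rather than collapsed.
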