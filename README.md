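# cpuorf

Genome-wide identification of **conserved peptide upstream open reading
frames (CPuORFs)** — uORFs in 5′-UTRs whose *encoded peptide* is under
purifying selection across flowering-plant orders, a strong hint that the
peptide itself is functional (many known examples regulate translation of
the downstream main ORF, e.g. through ribosome stalling).

The package is aimed at plant comparative genomicists who have a genome +
GFF3 annotation for a focal species and a cross-species transcript database
(RefSeq-like curated RNAs plus EST/TSA evidence) and want an automated,
reproducible screen.

## The method

Six stages, each writing a resumable artifact:

1. **Extract** — build spliced transcripts from the genome and annotation;
   scan each 5′-UTR for uORFs (ATG to the nearest in-frame stop, both
   codons inside the UTR; among uORFs sharing a stop, only the longest is
   kept).
2. **Fusion filter** — a uORF that is really the N-terminus of the main
   protein shows up *inside* the largest ORF of related curated RNAs.  For
   each uORF, companion RNAs matching both the uORF and its mORF are
   classified as fusion type (uORF match contained in the largest ORF) or
   separate type; with X and Y the respective counts, uORFs with fusion
   ratio X/(X+Y) ≥ 0.3, or with X+Y < 10 companions, are discarded.
3. **Homology search** — tBLASTn-style search of the uORF peptide against
   all six frames of every database entry (E < 2000, other species only).
   Around each matching region the homologous **putative uORF** is
   reconstructed: nearest downstream in-frame stop, then the 5′-most
   in-frame ATG upstream of it with no intervening stop.
4. **Verification & cleanup** — the subject must also match the original
   mORF (E < 10⁻¹) downstream; subjects whose putative mORF overlaps the
   putative uORF are discarded as fusion transcripts, and EST/TSA subjects
   failing a cross-order near-identity screen (E < 10⁻¹⁰⁰, identity ≥ 95%,
   hit-count/declared-total ratio comparison) are dropped as contaminants.
   Candidates must retain hits in ≥ 2 orders besides the query's own.
5. **Ka/Ks test** — one representative per order (smallest geometric mean
   of uORF/mORF E-values, preferring mORF E < 10⁻²⁰); angiosperm
   representatives are aligned (protein → codon-delimited alignment) and
   pairwise Ka/Ks (original vs each homolog) estimated with the
   Nei–Gojobori (1986) pathway-counting method under a Jukes–Cantor
   correction.  The null replaces each homolog with artificial mutants of
   the original uORF carrying the same number of substitutions at random
   positions; a one-sided Mann–Whitney U test (exact for small samples)
   with Benjamini–Hochberg FDR asks whether the observed ratios are
   stochastically smaller.  Accepted: median Ka/Ks < 0.5 **and** q < 0.05.
6. **Taxonomic range** — each representative's species is classified into
   one of 13 mutually exclusive plant categories (lamiids, other asterids,
   malvids, fabids, other eudicots, commelinids, other monocots, other
   angiosperms, gymnosperms, Polypodiopsida, other Embryophyta, other
   Streptophyta, other Viridiplantae) to report where the peptide is
   conserved.

A synthetic-benchmark generator (`cpuorf.simulate`) produces genomes,
transcript databases and lineage tables with planted conserved, neutral,
spurious-fusion and contaminant families, so the whole pipeline is testable
offline with known truth.

## Worked example

```bash
cpuorf simulate --out demo/data --seed 7 --n-conserved 3 --n-neutral 2 \
    --n-fusion 2 --n-contaminants 1
cat > demo/config.yaml <<EOF
genome: demo/data/genome.fa
gff3: demo/data/annotation.gff3
transcript_db: demo/data/transcripts.fa
lineages: demo/data/lineages.tsv
workdir: demo/work
focal_species: brassicales_ref
seed: 11
EOF
cpuorf report --config demo/config.yaml
# -> 3 accepted CPuORFs -> demo/work/report.tsv
```

The three accepted uORFs are exactly the three planted conserved families.
`demo/work/fusion.tsv` shows both spurious-fusion families discarded with
ratios ≈ 0.58 (`discard_high_ratio`), e.g.:

```
uorf_id      n_fusion  n_separate  ratio     decision
fam001t1.u1  0         12          0.000000  retain
fam006t1.u1  7         5           0.583333  discard_high_ratio
```

and `demo/work/kaks.tsv` carries the per-candidate statistics, e.g.
`fam001t1.u1` with median Ka/Ks 0.033 and q = 0.0028 (accepted) versus a
neutral control at median 0.96, q = 0.35 (rejected).  The final
`report.tsv` adds the per-category order counts of each accepted CPuORF.

Stages are checksum-gated: re-running with unchanged inputs skips
everything; stage subcommands (`cpuorf extract|fusion|search|kaks|taxonomy`)
run prefixes of the pipeline.

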