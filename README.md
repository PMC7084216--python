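# mornaquant

Detection and quantification of miRNAs, complementary (star) miRNAs,
microRNA-offset RNAs (moRNAs), hairpin-loop sRNAs and their sequence
isoforms from Illumina small RNA-seq data.

Given FASTQ reads, a reference genome (FASTA) and a miRBase-dialect GFF3
annotation of precursors and mature miRNAs, the pipeline:

1. **preprocess** — trims the 3' adapter, filters reads by length, mean
   quality and low-quality base count, collapses reads into counted unique
   sequence tags, and removes low-count tags (`MIN_COUNT`, default 10).
2. **genome_filter** — exactly matches tags against both genome strands and
   discards tags hitting more than `MAX_OUTSIDE_LOCI` (default 5) loci
   outside annotated precursors. Genome-unmapped tags are retained: they may
   carry non-templated 3' additions.
3. **hairpin** — builds *extended precursors* (precursor ± 30 nt genomic
   flank), folds them (built-in base-pair-maximization folder, or a
   per-precursor dot-bracket via `FOLD_STRUCTURES` for external folders such
   as RNAfold), and projects the star interval of each annotated mature from
   the pairing topology with the canonical 2-nt 3' overhang.
4. **assign** — aligns tags to extended precursors (≤ 2 mismatches; 2-mm
   alignments kept only when both mismatches are 3'-terminal), clusters
   perfect alignments into non-overlapping blocks, finalizes up to five sRNA
   definitions per precursor (miR-5p/3p incl. predicted star, moR-5p/3p,
   loop), applies the conservative moR sequence filter, and assigns every
   alignment to an sRNA (within `ALLOWED_OVERHANG` of both ends) or to the
   unassigned report.
5. **isoform_quant** — classifies each assigned alignment as canonical or
   one of seven isoform types (`mm1`, `mm2_3p`, `short5p`, `short3p`,
   `long5p`, `long3p`, `len_both`) and emits per-isoform tables, a per-sRNA
   count matrix (loop rows flagged for optional removal) and CPM.

A seeded simulator (`mornaquant.simulate`) generates synthetic genomes,
hairpin precursors, annotations and FASTQ reads with planted truth, and is
the basis of the test suite.

## CLI

```sh
# generate a synthetic dataset with planted truth
mornaquant simulate --seed 1 -o simdir

# validate a configuration
mornaquant validate -c run.conf

# run the pipeline
mornaquant run -c run.conf [--min-count N] [--allowed-overhang N] \
    [--morfilter conservative|permissive] [--threads N] [-o OUTDIR]
```

Configuration is flat `KEY=value` plus a `[samples]` section:

```ini
GENOME=genome.fa
ANNOTATION=annotation.gff3       # miRBase-dialect GFF3
# EXTRA_PRECURSORS=extra.gff3    # optional predicted precursors
# FOLD_STRUCTURES=folds.tsv      # optional external dot-brackets (id<TAB>structure)
ADAPTER=TGGAATTCTCGGGTGCCAAGG    # or NOADAPTER=True
MIN_COUNT=10
MAX_LEN_FILTER=30
MEAN_QUAL_FILTER=30
MIN_MORNA_LEN=16
MORFILTER=conservative
ALLOWED_OVERHANG=3
OUTPUT_DIR=out

[samples]
sample1=sample1.fastq.gz
```

Outputs in `OUTPUT_DIR`: `catalog.gff3` (sRNA catalog with genomic
coordinates and class attribute), `isoforms.tsv` (per-isoform long table),
`counts.tsv` (sRNA × sample matrix with a class column), `unassigned.tsv`
and `run_log.json` (per-stage read accounting and effective parameters).

## Coordinates

All internal intervals are 0-based half-open on the transcribed strand;
GFF3 input/output converts to/from 1-based inclusive genomic coordinates at
the I/O boundary only.
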